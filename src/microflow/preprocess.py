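"""Stabilization and temporal-difference (SAD) imaging of a raw video stack.

The pipeline order is: estimate global tissue motion by block matching
against the first frame, reject frames whose motion velocity exceeds a
threshold (default 0.3 px/s), sum absolute consecutive-frame differences of
the surviving frames into the SAD image, and enhance it with CLAHE. Bright
SAD pixels mark perfused vessels: moving RBCs modulate transmitted light,
so only pixels over flowing blood accumulate differences.

"Motion velocity" is taken as the frame-to-frame change of the estimated
global displacement times the frame rate (px/s); local RBC motion inside
vessels must not count as tissue motion, hence the median over blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage import exposure

from .io import VideoStack


@dataclass
class MotionEstimate:
    """Global per-frame displacement relative to frame 0, and velocities.

    displacement_px[i] is the (drow, dcol) of frame i against frame 0;
    velocity_px_per_s[i] = ||displacement[i] - displacement[i-1]|| * fps.
    Frame 0 has displacement (0, 0) and velocity 0 by construction.
    """

    displacement_px: np.ndarray
    velocity_px_per_s: np.ndarray

    def __post_init__(self) -> None:
        self.displacement_px = np.asarray(self.displacement_px, dtype=float)
        self.velocity_px_per_s = np.asarray(self.velocity_px_per_s, dtype=float)
        if not np.allclose(self.displacement_px[0], 0) or self.velocity_px_per_s[0] != 0:
            raise ValueError("frame 0 must have zero displacement and velocity")


@dataclass
class SADImage:
    """Per-pixel sum of absolute consecutive-frame differences."""

    values: np.ndarray
    n_frames_used: int
    kept_frame_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min() < 0:
            raise ValueError("SAD values must be non-negative")
        if self.kept_frame_indices and len(self.kept_frame_indices) != self.n_frames_used:
            raise ValueError("kept_frame_indices length must equal n_frames_used")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _block_origins(extent: int, block: int, step: int) -> np.ndarray:
    last = extent - block
    return np.unique(np.clip(np.arange(0, last + 1, step), 0, last))


def estimate_motion(
    stack: VideoStack,
    block_size: int = 32,
    search_radius: int = 8,
    block_step: int | None = None,
    max_blocks: int = 36,
) -> MotionEstimate:
    """Block-matching global motion of every frame against frame 0.

    Blocks tile the frame with 50% overlap by default; each block's best
    integer displacement minimizes the mean absolute difference over an
    exhaustive search in +-search_radius, and the frame displacement is
    the per-axis median over blocks (robust to in-vessel RBC motion).
    max_blocks caps the number of blocks actually matched (an evenly
    spaced subset) to bound cost on large frames.
    """
    h, w = stack.frame_shape
    if block_size > min(h, w):
        raise ValueError(f"block_size {block_size} exceeds frame size {(h, w)}")
    step = block_step or max(block_size // 2, 1)
    origins = [(r, c) for r in _block_origins(h, block_size, step)
               for c in _block_origins(w, block_size, step)]
    if len(origins) > max_blocks:
        idx = np.linspace(0, len(origins) - 1, max_blocks).round().astype(int)
        origins = [origins[i] for i in np.unique(idx)]

    ref = stack.frames[0].astype(np.float32)
    pad = search_radius
    ref_padded = np.pad(ref, pad, mode="edge")

    # search neighborhoods around each block in the (padded) reference:
    # windows[k] has shape (2R+1, 2R+1, B, B)
    neighborhoods = []
    for r, c in origins:
        region = ref_padded[r : r + block_size + 2 * pad, c : c + block_size + 2 * pad]
        neighborhoods.append(sliding_window_view(region, (block_size, block_size)))

    n = stack.n_frames
    disp = np.zeros((n, 2))
    for t in range(1, n):
        frame = stack.frames[t].astype(np.float32)
        best = np.empty((len(origins), 2))
        for k, (r, c) in enumerate(origins):
            block = frame[r : r + block_size, c : c + block_size]
            mad = np.abs(neighborhoods[k] - block).mean(axis=(2, 3))
            i, j = np.unravel_index(np.argmin(mad), mad.shape)
            # displacement of the frame content relative to the reference
            best[k] = (pad - i, pad - j)
        disp[t] = np.median(best, axis=0)

    vel = np.zeros(n)
    vel[1:] = np.linalg.norm(np.diff(disp, axis=0), axis=1) * stack.frame_rate_hz
    return MotionEstimate(displacement_px=disp, velocity_px_per_s=vel)


def stabilize(
    stack: VideoStack,
    motion: MotionEstimate,
    velocity_threshold_px_per_s: float = 0.3,
) -> tuple[VideoStack, list[int]]:
    """Drop every frame whose motion velocity exceeds the threshold.

    Frame 0 is always retained. Returns the surviving sub-stack (original
    order) and the kept frame indices.
    """
    if len(motion.velocity_px_per_s) != stack.n_frames:
        raise ValueError("motion estimate does not match the stack")
    keep = np.flatnonzero(motion.velocity_px_per_s <= velocity_threshold_px_per_s)
    if 0 not in keep:
        keep = np.r_[0, keep]
    if len(keep) < 2:
        raise ValueError(
            "fewer than 2 frames survive the velocity gate; "
            "increase velocity_threshold_px_per_s"
        )
    return stack.subset(keep), [int(i) for i in keep]


def compute_sad(stack: VideoStack, kept_frame_indices: list[int] | None = None) -> SADImage:
    """Sum of absolute consecutive-frame differences over the whole stack.

    Computed in float64 so unsigned integer inputs cannot wrap around.
    When frames were dropped by the velocity gate, the difference across a
    splice is taken between the two surviving neighbors.
    """
    if stack.n_frames < 2:
        raise ValueError("SAD needs at least 2 frames")
    frames = stack.frames.astype(np.float64)
    values = np.abs(np.diff(frames, axis=0)).sum(axis=0)
    return SADImage(
        values=values,
        n_frames_used=stack.n_frames,
        kept_frame_indices=kept_frame_indices or list(range(stack.n_frames)),
    )


def enhance_clahe(
    sad: SADImage,
    clip_limit: float = 0.01,
    tile_grid: int = 8,
) -> SADImage:
    """Contrast-limited adaptive histogram equalization of the SAD image.

    The image is rescaled to [0, 1] before equalization; the output stays
    in [0, 1]. A constant image is returned unchanged (as zeros offsetless
    rescale is undefined, it maps to all-zeros).
    """
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    v = sad.values
    vmin, vmax = v.min(), v.max()
    if vmax == vmin:
        out = np.zeros_like(v, dtype=float)
    else:
        unit = (v - vmin) / (vmax - vmin)
        h, w = unit.shape
        kernel = (max(h // tile_grid, 1), max(w // tile_grid, 1))
        out = exposure.equalize_adapthist(unit, kernel_size=kernel, clip_limit=clip_limit)
    return SADImage(
        values=out,
        n_frames_used=sad.n_frames_used,
        kept_frame_indices=list(sad.kept_frame_indices),
    )
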