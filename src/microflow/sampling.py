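"""Reference grid, vessel/line intersections and data-block extraction.

Equidistant horizontal and vertical reference lines are superimposed on
the segmented vessel map; each maximal contiguous run of vessel pixels
along a line is one crossing (the unit that receives a flow decision).
Around every cross-section pixel a 16 x 16 x n_frames intensity block is
cut from the stabilized video — the spatio-temporal input of the flow
classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import IntersectionSample, VideoStack
from .segmentation import BinaryVesselMap

log = logging.getLogger(__name__)


@dataclass
class ReferenceGrid:
    """Equidistant row and column line positions, strictly increasing."""

    row_lines: list[int]
    col_lines: list[int]

    def __post_init__(self) -> None:
        for lines in (self.row_lines, self.col_lines):
            if any(b <= a for a, b in zip(lines, lines[1:])):
                raise ValueError("grid lines must be strictly increasing")


def build_grid(shape: tuple[int, int], n_lines_per_axis: int = 3) -> ReferenceGrid:
    """n equidistant lines per axis at round(k * extent / (n + 1)), k = 1..n.

    Lines are equidistant from each other and from the borders. On tiny
    images rounding can collide; duplicates are nudged up to stay strictly
    increasing (and must remain inside the image).
    """
    if n_lines_per_axis < 1:
        raise ValueError("n_lines_per_axis must be >= 1")
    h, w = shape

    def lines(extent: int) -> list[int]:
        if extent < n_lines_per_axis + 2:
            raise ValueError(f"image extent {extent} too small for {n_lines_per_axis} lines")
        pos = [round((k * extent) / (n_lines_per_axis + 1)) for k in range(1, n_lines_per_axis + 1)]
        out: list[int] = []
        for p in pos:
            while out and p <= out[-1]:
                p += 1
            if p >= extent:
                raise ValueError("grid lines do not fit inside the image")
            out.append(p)
        return out

    return ReferenceGrid(row_lines=lines(h), col_lines=lines(w))


def _runs(values: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) half-open intervals."""
    padded = np.r_[False, values, False]
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def find_intersections(grid: ReferenceGrid, vmap: BinaryVesselMap) -> list[IntersectionSample]:
    """One IntersectionSample per maximal run of mask pixels on each line.

    Runs are disjoint, every mask-true pixel on a line belongs to exactly
    one sample, and the run center is the lower median for even lengths.
    """
    mask = vmap.mask
    samples: list[IntersectionSample] = []
    for line_id, r in enumerate(grid.row_lines):
        for start, stop in _runs(mask[r, :]):
            px = [(r, c) for c in range(start, stop)]
            samples.append(
                IntersectionSample(
                    line_id=line_id,
                    orientation="horizontal",
                    cross_section_pixels=px,
                    center=px[(len(px) - 1) // 2],
                )
            )
    for line_id, c in enumerate(grid.col_lines):
        for start, stop in _runs(mask[:, c]):
            px = [(r, c) for r in range(start, stop)]
            samples.append(
                IntersectionSample(
                    line_id=line_id,
                    orientation="vertical",
                    cross_section_pixels=px,
                    center=px[(len(px) - 1) // 2],
                )
            )
    return samples


def extract_blocks(
    stack: VideoStack,
    sample: IntersectionSample,
    half_window: int = 8,
    n_frames: int = 200,
) -> IntersectionSample:
    """Cut a (2h x 2h x n_frames) block around each cross-section pixel.

    The target pixel sits at offset (half_window, half_window): the window
    spans [p - h, p + h - 1] on both axes (an even window has no center
    pixel, so this convention is fixed for reproducibility). The first
    n_frames frames of the (stabilized) stack are used. Pixels closer
    than half_window to the border are skipped and logged, not padded —
    padding would fabricate temporal signal.
    """
    if stack.n_frames < n_frames:
        raise ValueError(
            f"stack has {stack.n_frames} frames but {n_frames} are required; "
            "reduce n_frames"
        )
    h_img, w_img = stack.frame_shape
    hw = half_window
    blocks: list[np.ndarray] = []
    kept: list[tuple[int, int]] = []
    skipped: list[tuple[int, int]] = []
    for r, c in sample.cross_section_pixels:
        if r - hw < 0 or c - hw < 0 or r + hw > h_img or c + hw > w_img:
            skipped.append((r, c))
            continue
        patch = stack.frames[:n_frames, r - hw : r + hw, c - hw : c + hw]
        blocks.append(np.ascontiguousarray(np.moveaxis(patch, 0, -1)))  # (row, col, t)
        kept.append((r, c))
    if skipped:
        log.info("skipped %d border pixel(s) at %s", len(skipped), skipped)
    if not kept:
        sample.per_pixel_blocks = []
        sample.skipped_pixels = skipped
        return sample
    out = IntersectionSample(
        line_id=sample.line_id,
        orientation=sample.orientation,
        cross_section_pixels=kept,
        center=sample.center,
        label=sample.label,
        per_pixel_blocks=blocks,
        skipped_pixels=skipped,
    )
    return out
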