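"""Reading and writing video stacks, label tables and model artifacts.

The canonical on-disk stack format is a multipage TIFF; a directory of
identically sized single-frame images (PNG/TIFF) is accepted as an
alternative, with frames ordered by natural sort of their filenames
(``frame_2`` before ``frame_10``). All coordinates throughout the package
are 0-based ``(row, col)`` with row 0 at the top.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

DEFAULT_FRAME_RATE_HZ = 32.5
DEFAULT_PIXEL_SIZE_UM = 0.4

_FRAME_SUFFIXES = {".tif", ".tiff", ".png"}


@dataclass
class VideoStack:
    """An ordered grayscale image sequence with acquisition metadata.

    frames is indexed ``(frame, row, col)``; intensities are finite and
    non-negative. frame_rate_hz defaults to 32.5 (the nominal brightfield
    acquisition rate) and pixel_size_um to 0.4 (400x400 um field of view
    imaged at 1000x1000 px).
    """

    frames: np.ndarray
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a 3-D (frame, row, col) array, got ndim={self.frames.ndim}"
            )
        if self.n_frames < 2:
            raise ValueError(f"a video stack needs at least 2 frames, got {self.n_frames}")
        if not np.issubdtype(self.frames.dtype, np.integer):
            if not np.all(np.isfinite(self.frames)):
                raise ValueError("frame intensities must be finite")
        if self.frames.size and self.frames.min() < 0:
            raise ValueError("frame intensities must be non-negative")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def subset(self, indices: Sequence[int]) -> "VideoStack":
        """Sub-stack of the given frame indices, original order preserved."""
        return replace(self, frames=self.frames[np.asarray(indices, dtype=int)])


@dataclass
class IntersectionSample:
    """One crossing between a reference-grid line and the vessel mask.

    cross_section_pixels is the maximal contiguous run of mask-true pixels
    along the line; center is the run midpoint (lower median for even runs).
    """

    line_id: int
    orientation: str  # "horizontal" (a row line) or "vertical" (a column line)
    cross_section_pixels: list[tuple[int, int]]
    center: tuple[int, int]
    label: bool | None = None
    per_pixel_blocks: list[np.ndarray] | None = None
    skipped_pixels: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cross_section_pixels:
            raise ValueError("cross_section_pixels must be non-empty")
        if self.orientation not in ("horizontal", "vertical"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def n_pixels(self) -> int:
        return len(self.cross_section_pixels)


def _natural_key(name: str) -> tuple:
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def _bit_depth_of(dtype: np.dtype) -> int:
    dtype = np.dtype(dtype)
    if np.issubdtype(dtype, np.integer):
        return dtype.itemsize * 8
    return 32


def read_stack(
    path: str | Path,
    frame_rate_hz: float | None = None,
    pixel_size_um: float | None = None,
) -> VideoStack:
    """Read a multipage TIFF or a directory of single-frame images.

    Directory frames are ordered by natural sort of filenames. Metadata is
    taken from TIFF tags when present, else from the arguments / defaults.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")

    meta_rate = None
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES),
            key=lambda p: _natural_key(p.name),
        )
        if len(files) < 2:
            raise ValueError(f"fewer than 2 frames in {path} ({len(files)} found)")
        frames = []
        for f in files:
            img = iio.imread(f)
            if img.ndim == 3:  # collapse RGB written by generic exporters
                img = img[..., 0]
            frames.append(np.asarray(img))
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError(f"frames of mismatched shape in {path}: {sorted(shapes)}")
        arr = np.stack(frames)
    else:
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            meta = tf.shaped_metadata
            if meta and isinstance(meta[0], dict):
                meta_rate = meta[0].get("frame_rate_hz")
                if pixel_size_um is None:
                    pixel_size_um = meta[0].get("pixel_size_um")
        if arr.ndim == 2:
            raise ValueError(f"fewer than 2 frames in {path}")
        if arr.ndim != 3:
            raise ValueError(f"expected a grayscale multipage TIFF, got shape {arr.shape}")

    return VideoStack(
        frames=arr,
        frame_rate_hz=frame_rate_hz or meta_rate or DEFAULT_FRAME_RATE_HZ,
        pixel_size_um=pixel_size_um or DEFAULT_PIXEL_SIZE_UM,
        bit_depth=_bit_depth_of(arr.dtype),
    )


def write_stack(stack: VideoStack, path: str | Path) -> None:
    """Write a stack as a multipage TIFF; lossless round-trip with read_stack."""
    path = Path(path)
    tifffile.imwrite(
        path,
        stack.frames,
        metadata={
            "frame_rate_hz": stack.frame_rate_hz,
            "pixel_size_um": stack.pixel_size_um,
        },
    )


_LABEL_COLUMNS = ["video_id", "row", "col", "line_id", "orientation", "label"]


def write_labels(
    samples: Sequence[IntersectionSample],
    path: str | Path,
    video_id: str = "video0",
) -> None:
    """Write labeled intersections as a UTF-8 CSV (one row per crossing)."""
    rows = []
    for s in samples:
        if s.label is None:
            raise ValueError(
                f"sample at {s.center} has no label; only labeled samples can be written"
            )
        rows.append(
            {
                "video_id": video_id,
                "row": s.center[0],
                "col": s.center[1],
                "line_id": s.line_id,
                "orientation": s.orientation,
                "label": int(s.label),
            }
        )
    pd.DataFrame(rows, columns=_LABEL_COLUMNS).to_csv(path, index=False)


def load_labels(path: str | Path) -> pd.DataFrame:
    """Load a label CSV written by write_labels."""
    df = pd.read_csv(path)
    missing = set(_LABEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"label file {path} is missing columns {sorted(missing)}")
    return df


def write_samples_h5(samples: Sequence[IntersectionSample], path: str | Path) -> None:
    """Store extracted data blocks in an HDF5 container keyed by sample id.

    Each sample group carries its blocks as one (n_pixels, H, W, T) array
    plus center/line metadata; an index table mirrors the layout.
    """
    import h5py

    with h5py.File(path, "w") as fh:
        for i, s in enumerate(samples):
            if s.per_pixel_blocks is None:
                raise ValueError(f"sample {i} has no extracted blocks")
            grp = fh.create_group(f"sample_{i:05d}")
            if s.per_pixel_blocks:
                grp.create_dataset("blocks", data=np.stack(s.per_pixel_blocks))
            grp.attrs["center"] = s.center
            grp.attrs["line_id"] = s.line_id
            grp.attrs["orientation"] = s.orientation
            grp.attrs["pixels"] = np.asarray(s.cross_section_pixels)
            if s.label is not None:
                grp.attrs["label"] = int(s.label)


def read_samples_h5(path: str | Path) -> list[IntersectionSample]:
    """Load samples written by write_samples_h5."""
    import h5py

    samples = []
    with h5py.File(path, "r") as fh:
        for key in sorted(fh.keys()):
            grp = fh[key]
            pixels = [tuple(int(v) for v in p) for p in grp.attrs["pixels"]]
            blocks = list(grp["blocks"][...]) if "blocks" in grp else []
            samples.append(
                IntersectionSample(
                    line_id=int(grp.attrs["line_id"]),
                    orientation=str(grp.attrs["orientation"]),
                    cross_section_pixels=pixels,
                    center=tuple(int(v) for v in grp.attrs["center"]),
                    label=bool(grp.attrs["label"]) if "label" in grp.attrs else None,
                    per_pixel_blocks=blocks,
                )
            )
    return samples


def save_model(model, path: str | Path) -> None:
    """Serialize a trained classifier: weights to .npz + JSON sidecar config.

    ``path`` is a directory; it will contain ``weights.npz`` and
    ``config.json``.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    model.save(path / "weights.npz")
    with open(path / "config.json", "w") as fh:
        json.dump(model.config_dict(), fh, indent=2)


def load_model(path: str | Path):
    """Load a model saved by save_model (CNN or logistic baseline)."""
    from . import flow_classifier

    path = Path(path)
    with open(path / "config.json") as fh:
        cfg = json.load(fh)
    kind = cfg.pop("kind")
    if kind == "cnn3d":
        return flow_classifier.CNNModel.load(path / "weights.npz", cfg)
    if kind == "logistic":
        return flow_classifier.LogisticBaseline.load(path / "weights.npz", cfg)
    raise ValueError(f"unknown model kind {kind!r}")
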