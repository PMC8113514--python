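"""Synthetic intravital-microscopy phantoms with ground-truth perfusion labels.

Transilluminated muscle tissue shows microvessels as dark tubes on a bright
field because red blood cells (RBCs) absorb light. A perfused vessel carries
a column of moving RBCs, so its pixels flicker over time; a non-flowing
vessel holds a stagnant RBC column and stays static. The generator renders
exactly this contrast mechanism: smooth random tube centerlines, a Gaussian
absorption profile across each tube, advected dark blobs inside flowing
tubes, optional global tissue drift and sensor noise — everything the
two-step analysis needs to be exercised end to end without animal data.

It does not attempt physical hemodynamics (no RBC deformation, plasma gaps
driven by bifurcation dynamics, or oxygen-dependent absorbance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import interpolate, ndimage

from .io import IntersectionSample, VideoStack

FULL_SCALE = 65535.0  # 16-bit nominal range; frames are float32 on this scale


@dataclass
class VesselSpec:
    """Geometry and flow state of one synthetic vessel.

    centerline: polyline of (row, col) points, all inside the frame.
    width_px: tube diameter. flowing vessels advect RBC blobs along the
    centerline at rbc_speed_px_per_frame; non-flowing vessels are rendered
    as static dark tubes (stagnant RBC column). rbc_density in (0, 1]
    scales how tightly blobs are packed; contrast in (0, 1] is the peak
    fractional absorption at the tube axis.
    """

    centerline: np.ndarray
    width_px: float
    flowing: bool
    rbc_speed_px_per_frame: float
    rbc_density: float = 0.5
    contrast: float = 0.6

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[0] < 2:
            raise ValueError("centerline needs >= 2 (row, col) points")
        if self.width_px <= 0:
            raise ValueError("width_px must be positive")
        if not self.flowing and self.rbc_speed_px_per_frame != 0:
            raise ValueError("non-flowing vessels must have rbc_speed_px_per_frame == 0")
        if self.rbc_speed_px_per_frame < 0:
            raise ValueError("rbc_speed_px_per_frame must be >= 0")
        if not (0 < self.rbc_density <= 1):
            raise ValueError("rbc_density must lie in (0, 1]")
        if not (0 < self.contrast <= 1):
            raise ValueError("contrast must lie in (0, 1]")


@dataclass
class GeneratorConfig:
    """Study conditions for the phantom generator.

    Desk-scale geometry (256 px, not the instrument's 1000 px) keeps every
    stage testable in seconds; the acquisition frame rate and pixel pitch
    are kept at the instrument's nominal values so velocity thresholds keep
    their physical meaning.
    """

    image_size: tuple[int, int] = (256, 256)
    n_vessels: tuple[int, int] = (6, 10)
    width_px: tuple[float, float] = (3.0, 6.0)
    flowing_fraction: float = 0.7
    rbc_speed_px_per_frame: tuple[float, float] = (0.5, 2.5)
    rbc_density: tuple[float, float] = (0.35, 0.8)
    contrast: tuple[float, float] = (0.4, 0.8)
    rbc_length_px: tuple[float, float] = (2.0, 6.0)
    background_level: float = 0.85  # fraction of FULL_SCALE
    noise_sigma: float = 0.01  # read noise, fraction of FULL_SCALE
    shot_noise_factor: float = 0.01  # intensity-proportional noise fraction
    drift_px_per_frame: tuple[float, float] = (0.0, 0.0)
    frame_rate_hz: float = 32.5
    pixel_size_um: float = 0.4
    n_grid_lines: int = 3

    def __post_init__(self) -> None:
        h, w = self.image_size
        if self.width_px[1] >= min(h, w):
            raise ValueError("vessel width must be smaller than the image")
        if not (0 <= self.flowing_fraction <= 1):
            raise ValueError("flowing_fraction must lie in [0, 1]")


@dataclass
class PhantomGroundTruth:
    """Per-vessel specs plus true flow labels on the reference grid.

    crossings are IntersectionSamples over the *true* rasterized vessel
    mask with label set; crossing_vessel_ids gives the owning vessel of
    each crossing (the vessel covering its center).
    """

    vessels: list[VesselSpec]
    vessel_mask: np.ndarray
    flow_mask: np.ndarray
    crossings: list[IntersectionSample] = field(default_factory=list)
    crossing_vessel_ids: list[int] = field(default_factory=list)


def _smooth_centerline(rng: np.random.Generator, shape: tuple[int, int], margin: float) -> np.ndarray:
    """Random smooth curve through jittered waypoints, clipped inside the frame."""
    h, w = shape
    n_way = rng.integers(3, 6)
    start = rng.uniform([margin, margin], [h - margin, w - margin])
    angle = rng.uniform(0, 2 * np.pi)
    step = rng.uniform(0.25, 0.5) * min(h, w)
    pts = [start]
    for _ in range(n_way - 1):
        angle += rng.normal(0, 0.5)
        pts.append(pts[-1] + step * np.array([np.sin(angle), np.cos(angle)]))
    pts = np.clip(np.array(pts), margin, [h - margin, w - margin])
    # collapse consecutive duplicates created by clipping
    keep = np.r_[True, np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-6]
    pts = pts[keep]
    if len(pts) < 3:
        return np.linspace(pts[0], pts[-1], 32)
    tck, _ = interpolate.splprep(pts.T, s=0, k=min(3, len(pts) - 1))
    u = np.linspace(0, 1, 30 * len(pts))
    curve = np.array(interpolate.splev(u, tck)).T
    return np.clip(curve, margin * 0.5, [h - margin * 0.5, w - margin * 0.5])


def sample_vessel_tree(config: GeneratorConfig, seed: int) -> list[VesselSpec]:
    """Draw a reproducible random set of vessels under the config's conditions."""
    rng = np.random.default_rng(seed)
    lo, hi = config.n_vessels
    n = int(rng.integers(lo, hi + 1))
    vessels = []
    for _ in range(n):
        width = rng.uniform(*config.width_px)
        flowing = bool(rng.random() < config.flowing_fraction)
        speed = float(rng.uniform(*config.rbc_speed_px_per_frame)) if flowing else 0.0
        vessels.append(
            VesselSpec(
                centerline=_smooth_centerline(rng, config.image_size, margin=4 + width),
                width_px=width,
                flowing=flowing,
                rbc_speed_px_per_frame=speed,
                rbc_density=float(rng.uniform(*config.rbc_density)),
                contrast=float(rng.uniform(*config.contrast)),
            )
        )
    return vessels


def _resample_arclength(centerline: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centerline resampled to ~0.5 px spacing, plus cumulative arclength."""
    seg = np.linalg.norm(np.diff(centerline, axis=0), axis=1)
    s = np.r_[0.0, np.cumsum(seg)]
    total = s[-1]
    n = max(int(total / 0.5), 2)
    si = np.linspace(0, total, n)
    rows = np.interp(si, s, centerline[:, 0])
    cols = np.interp(si, s, centerline[:, 1])
    return np.column_stack([rows, cols]), si


def _tube_geometry(vessel: VesselSpec, shape: tuple[int, int]):
    """Tube pixel coordinates, their radial distance and arclength position."""
    dense, s = _resample_arclength(vessel.centerline)
    raster = np.ones(shape, dtype=bool)
    ij = np.round(dense).astype(int)
    ij[:, 0] = np.clip(ij[:, 0], 0, shape[0] - 1)
    ij[:, 1] = np.clip(ij[:, 1], 0, shape[1] - 1)
    raster[ij[:, 0], ij[:, 1]] = False
    dist, nearest = ndimage.distance_transform_edt(raster, return_indices=True)
    tube = dist <= vessel.width_px / 2
    rr, cc = np.nonzero(tube)
    # arclength of each tube pixel = arclength of its nearest centerline pixel
    s_of_raster = np.full(shape, np.nan)
    s_of_raster[ij[:, 0], ij[:, 1]] = s
    px_s = s_of_raster[nearest[0][rr, cc], nearest[1][rr, cc]]
    return rr, cc, dist[rr, cc], px_s, s[-1]


def _blob_positions(rng: np.random.Generator, vessel: VesselSpec, total_len: float,
                    rbc_len: float, pad: float) -> np.ndarray:
    """Initial RBC blob centers along the extended arclength [-pad, L+pad]."""
    mean_gap = rbc_len / vessel.rbc_density
    pos, x = [], -pad
    while x < total_len + pad:
        pos.append(x)
        x += rng.exponential(mean_gap) + rbc_len
    return np.asarray(pos)


def render_video(
    vessels: Sequence[VesselSpec],
    n_frames: int,
    config: GeneratorConfig,
    seed: int,
) -> tuple[VideoStack, PhantomGroundTruth]:
    """Render a phantom video and its ground truth.

    Flowing vessels advect Gaussian-profiled dark blobs along the
    centerline at their RBC speed (a continuous wrapped stream, so every
    tube pixel is swept); non-flowing vessels are static dark tubes. Noise
    is additive Gaussian read noise plus an intensity-proportional term;
    global drift, when configured, is a sub-pixel translation accumulating
    per frame.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    from . import sampling, segmentation  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    h, w = config.image_size
    shape = (h, w)

    background = np.full(shape, config.background_level * FULL_SCALE, dtype=np.float32)
    # static low-frequency illumination field (tissue texture, no temporal signal)
    texture = ndimage.gaussian_filter(rng.normal(0, 1, shape), 12)
    ptp = np.ptp(texture)
    if ptp > 0:
        background *= (1 + 0.05 * (texture - texture.mean()) / ptp).astype(np.float32)

    # absorption[t] accumulates (1 - contrast * profile * occupancy) factors
    transmission = np.ones((n_frames, h, w), dtype=np.float32)
    vessel_mask = np.zeros(shape, dtype=bool)
    flow_mask = np.zeros(shape, dtype=bool)

    for vessel in vessels:
        rr, cc, d, px_s, total_len = _tube_geometry(vessel, shape)
        vessel_mask[rr, cc] = True
        sigma_r = max(vessel.width_px / 4, 0.5)
        profile = np.exp(-(d**2) / (2 * sigma_r**2)).astype(np.float32)
        if not vessel.flowing:
            transmission[:, rr, cc] *= 1 - vessel.contrast * profile
            continue
        flow_mask[rr, cc] = True
        rbc_len = rng.uniform(*config.rbc_length_px)
        sigma_s = rbc_len / 2
        pad = 4 * sigma_s + vessel.rbc_speed_px_per_frame
        span = total_len + 2 * pad
        blobs = _blob_positions(rng, vessel, total_len, rbc_len, pad)
        for t in range(n_frames):
            # wrapped stream: blobs leaving one end re-enter at the other
            pos = (blobs + t * vessel.rbc_speed_px_per_frame + pad) % span - pad
            dmat = px_s[:, None] - pos[None, :]
            occ = np.exp(-(dmat**2) / (2 * sigma_s**2)).sum(axis=1)
            occ = np.clip(occ, 0.0, 1.0).astype(np.float32)
            transmission[t, rr, cc] *= 1 - vessel.contrast * profile * occ

    frames = background[None, :, :] * transmission

    drift = np.asarray(config.drift_px_per_frame, dtype=float)
    if np.any(drift != 0):
        for t in range(1, n_frames):
            frames[t] = ndimage.shift(frames[t], drift * t, order=1, mode="nearest")

    if config.noise_sigma > 0 or config.shot_noise_factor > 0:
        sigma = np.sqrt(
            (config.noise_sigma * FULL_SCALE) ** 2
            + (config.shot_noise_factor * frames) ** 2
        )
        frames = frames + rng.normal(0, 1, frames.shape).astype(np.float32) * sigma
    frames = np.clip(frames, 0, FULL_SCALE).astype(np.float32)

    stack = VideoStack(
        frames=frames,
        frame_rate_hz=config.frame_rate_hz,
        pixel_size_um=config.pixel_size_um,
        bit_depth=16,
    )

    truth = PhantomGroundTruth(
        vessels=list(vessels), vessel_mask=vessel_mask, flow_mask=flow_mask
    )
    grid = sampling.build_grid(shape, config.n_grid_lines)
    true_map = segmentation.BinaryVesselMap(mask=vessel_mask)
    crossings = sampling.find_intersections(grid, true_map)
    for sample in crossings:
        px = np.array(sample.cross_section_pixels)
        frac = flow_mask[px[:, 0], px[:, 1]].mean()
        sample.label = bool(frac >= 0.5)
        owner = _owning_vessel(vessels, shape, sample.center)
        truth.crossings.append(sample)
        truth.crossing_vessel_ids.append(owner)
    return stack, truth


def _owning_vessel(vessels: Sequence[VesselSpec], shape, center: tuple[int, int]) -> int:
    """Vessel whose tube covers the crossing center (nearest centerline wins)."""
    best, best_d = -1, np.inf
    c = np.asarray(center, dtype=float)
    for i, v in enumerate(vessels):
        dense, _ = _resample_arclength(v.centerline)
        d = np.min(np.linalg.norm(dense - c, axis=1)) - v.width_px / 2
        if d < best_d:
            best, best_d = i, d
    return best


def truth_to_dict(truth: PhantomGroundTruth) -> dict:
    """JSON-serializable ground-truth summary (vessels + labeled crossings)."""
    return {
        "vessels": [
            {
                "centerline": v.centerline.tolist(),
                "width_px": v.width_px,
                "flowing": v.flowing,
                "rbc_speed_px_per_frame": v.rbc_speed_px_per_frame,
                "rbc_density": v.rbc_density,
                "contrast": v.contrast,
            }
            for v in truth.vessels
        ],
        "crossings": [
            {
                "center": list(s.center),
                "line_id": s.line_id,
                "orientation": s.orientation,
                "n_pixels": s.n_pixels,
                "label": bool(s.label),
                "vessel_id": vid,
            }
            for s, vid in zip(truth.crossings, truth.crossing_vessel_ids)
        ],
    }
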