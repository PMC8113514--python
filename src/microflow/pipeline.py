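"""End-to-end orchestration: video -> SAD -> mask -> crossings -> decisions.

One PipelineConfig carries every stage's tunables; run_pipeline executes
simulate/load -> stabilize -> SAD -> CLAHE -> segment -> grid/blocks ->
classify -> (optionally) evaluate, writing each intermediate artifact and
a run log with per-stage counters (frames dropped, components pruned,
border pixels skipped). A fixed seed and fixed inputs give byte-identical
decisions across runs on one platform.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, flow_classifier, preprocess, sampling, segmentation
from .io import VideoStack
from .preprocess import SADImage
from .synthetic import PhantomGroundTruth

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every stage's tunables, with the module defaults."""

    # stabilization
    velocity_threshold_px_per_s: float = 0.3
    block_size: int = 32
    search_radius: int = 8
    skip_stabilization: bool = False
    # CLAHE
    clip_limit: float = 0.01
    tile_grid: int = 8
    # segmentation
    expected_width_px: float = 4.0
    low_thresh: float = segmentation.DEFAULT_LOW_THRESH
    high_thresh: float = segmentation.DEFAULT_HIGH_THRESH
    close_radius: int = 1
    min_segment_px: int = 4
    # sampling
    n_grid_lines: int = 3
    half_window: int = 8
    n_block_frames: int = 200
    # classification
    prob_threshold: float = 0.5
    majority: float = 0.5
    # evaluation
    match_radius_px: float = 3.0
    # global
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class CrossingDecision:
    """The pipeline's verdict on one vessel/grid-line crossing."""

    sample_id: int
    center: tuple[int, int]
    n_pixels: int
    flowing_fraction: float
    vessel_flowing: bool


@dataclass
class PipelineResult:
    sad: SADImage
    enhanced: SADImage
    vessel_map: segmentation.BinaryVesselMap
    samples: list
    decisions: list[CrossingDecision]
    counters: dict = field(default_factory=dict)
    detection_rate: float | None = None
    error_rate: float | None = None


def decisions_to_frame(decisions: list[CrossingDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": d.sample_id,
                "row": d.center[0],
                "col": d.center[1],
                "n_pixels": d.n_pixels,
                "flowing_fraction": d.flowing_fraction,
                "vessel_flowing": int(d.vessel_flowing),
            }
            for d in decisions
        ],
        columns=["sample_id", "row", "col", "n_pixels", "flowing_fraction", "vessel_flowing"],
    )


def run_pipeline(
    stack: VideoStack,
    model,
    config: PipelineConfig | None = None,
    truth: PhantomGroundTruth | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage on a stack with a trained model.

    When `truth` (a phantom's ground truth) is given, the end-to-end
    detection and error rates are computed too. When `out_dir` is given,
    intermediates (sad.tif, mask.png, decisions.csv, run.json) are
    written there; the input stack file is never touched.
    """
    if model is None:
        raise ValueError("a trained model is required; train one with `microflow train`")
    config = config or PipelineConfig()
    counters: dict = {}

    if config.skip_stabilization:
        stabilized, kept = stack, list(range(stack.n_frames))
    else:
        motion = preprocess.estimate_motion(
            stack, block_size=config.block_size, search_radius=config.search_radius
        )
        stabilized, kept = preprocess.stabilize(
            stack, motion, config.velocity_threshold_px_per_s
        )
    counters["frames_dropped"] = stack.n_frames - stabilized.n_frames
    log.info("stabilization kept %d/%d frames", stabilized.n_frames, stack.n_frames)

    sad = preprocess.compute_sad(stabilized, kept)
    enhanced = preprocess.enhance_clahe(sad, config.clip_limit, config.tile_grid)

    raw_points = segmentation.steger_detect(
        enhanced,
        sigma=segmentation.sigma_for_width(config.expected_width_px),
        low_thresh=config.low_thresh,
        high_thresh=config.high_thresh,
    )
    raw_map = segmentation.link_and_binarize(raw_points, enhanced.shape)
    vessel_map = segmentation.postprocess_map(
        raw_map, config.close_radius, config.min_segment_px
    )
    counters["components_pruned"] = raw_map.n_components - vessel_map.n_components
    counters["mask_pixels"] = int(vessel_map.mask.sum())
    log.info("segmentation: %d components, %d mask pixels",
             vessel_map.n_components, counters["mask_pixels"])

    grid = sampling.build_grid(enhanced.shape, config.n_grid_lines)
    samples = sampling.find_intersections(grid, vessel_map)
    decisions: list[CrossingDecision] = []
    n_skipped = 0
    for i, sample in enumerate(samples):
        sample = sampling.extract_blocks(
            stabilized, sample, config.half_window, config.n_block_frames
        )
        n_skipped += len(sample.skipped_pixels)
        if not sample.per_pixel_blocks:
            continue
        blocks = np.stack(
            [flow_classifier.normalize_block(b) for b in sample.per_pixel_blocks]
        )
        probs = model.predict_proba(blocks)
        verdict = flow_classifier.decide_vessel(
            probs, config.prob_threshold, config.majority
        )
        decisions.append(
            CrossingDecision(
                sample_id=i,
                center=sample.center,
                n_pixels=sample.n_pixels,
                flowing_fraction=verdict.flowing_fraction,
                vessel_flowing=verdict.vessel_flowing,
            )
        )
    counters["border_pixels_skipped"] = n_skipped
    counters["n_crossings"] = len(decisions)

    result = PipelineResult(
        sad=sad,
        enhanced=enhanced,
        vessel_map=vessel_map,
        samples=samples,
        decisions=decisions,
        counters=counters,
    )
    if truth is not None:
        result.detection_rate, result.error_rate = evaluation.end_to_end_eval(
            decisions, truth.crossings, config.match_radius_px
        )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        import tifffile

        tifffile.imwrite(out / "sad.tif", sad.values.astype(np.float32))
        import imageio.v3 as iio

        iio.imwrite(out / "mask.png", (vessel_map.mask * 255).astype(np.uint8))
        decisions_to_frame(decisions).to_csv(out / "decisions.csv", index=False)
        run_log = {
            "config": dataclasses.asdict(config),
            "counters": counters,
            "detection_rate": result.detection_rate,
            "error_rate": result.error_rate,
        }
        (out / "run.json").write_text(json.dumps(run_log, indent=2))
    return result


def render_assessment(
    sad: SADImage,
    decisions: list[CrossingDecision],
    out: str | Path | None = None,
    n_grid_lines: int = 3,
    marker_half: int = 2,
) -> np.ndarray:
    """Assessment overlay: SAD grayscale, grid lines, green/red markers.

    Green marks a flowing crossing, red a non-flowing one (an artifact or
    stagnant vessel rejected by the classifier). Returns the RGB array;
    writes a PNG when `out` is given.
    """
    v = sad.values
    lo, hi = v.min(), v.max()
    gray = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
    rgb = np.stack([gray] * 3, axis=-1)

    grid = sampling.build_grid(v.shape, n_grid_lines)
    for r in grid.row_lines:
        rgb[r, :, :] = np.maximum(rgb[r, :, :], 0.35)
    for c in grid.col_lines:
        rgb[:, c, :] = np.maximum(rgb[:, c, :], 0.35)

    h, w = v.shape
    for d in decisions:
        r, c = d.center
        r0, r1 = max(r - marker_half, 0), min(r + marker_half + 1, h)
        c0, c1 = max(c - marker_half, 0), min(c + marker_half + 1, w)
        color = (0.0, 1.0, 0.0) if d.vessel_flowing else (1.0, 0.0, 0.0)
        rgb[r0:r1, c0:c1] = color

    img = (rgb * 255).astype(np.uint8)
    if out is not None:
        import imageio.v3 as iio

        iio.imwrite(Path(out), img)
    return img
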