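"""Synthetic parameter-recovery benchmark for the flow classifier.

Real-animal recordings and their manual labels are not redistributable,
so the classifier's end-task behaviour is validated on phantoms: several
ground-truthed videos are rendered under the default study conditions,
their grid crossings become labeled examples, a seed-split train/test
partition is made at the crossing level (never mixing a crossing's pixels
across the split), the 3D-CNN and the logistic baseline are trained on
the same blocks, and both are scored on vessel-level (majority-rule)
accuracy over the held-out crossings. A separate phantom, never used for
training, is pushed through the full two-step pipeline to measure the
end-to-end detection and error rates.

Sizes are desk-scale by design: 256 px frames, 220 rendered frames per
video (200 consumed per data block), ~20 crossings per video. Training
uses at most two pixel-blocks per training crossing and a reduced epoch
count; evaluation uses every cross-section pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import flow_classifier as fc
from . import pipeline as pl
from . import sampling, synthetic
from .evaluation import confusion, metrics

DEFAULT_N_VIDEOS = 15
DEFAULT_EPOCHS = 10
DEFAULT_BLOCKS_PER_CROSSING = 2


@dataclass
class LabeledCrossing:
    """All normalized pixel-blocks of one ground-truth crossing + its label."""

    blocks: np.ndarray  # (n_pixels, 16, 16, block_frames)
    label: bool
    video_id: int


def crossing_dataset(
    n_videos: int,
    seed: int,
    config: synthetic.GeneratorConfig | None = None,
    n_frames: int = 220,
    block_frames: int = 200,
) -> list[LabeledCrossing]:
    """Ground-truth labeled crossings from `n_videos` rendered phantoms."""
    config = config or synthetic.GeneratorConfig()
    out: list[LabeledCrossing] = []
    for v in range(n_videos):
        vessels = synthetic.sample_vessel_tree(config, seed + 7 * v)
        stack, truth = synthetic.render_video(vessels, n_frames, config, seed + 7 * v + 3)
        for s in truth.crossings:
            s = sampling.extract_blocks(stack, s, half_window=8, n_frames=block_frames)
            if not s.per_pixel_blocks:
                continue
            blocks = np.stack([fc.normalize_block(b) for b in s.per_pixel_blocks])
            out.append(LabeledCrossing(blocks=blocks, label=bool(s.label), video_id=v))
    return out


def _training_blocks(
    crossings: list[LabeledCrossing],
    indices: np.ndarray,
    per_crossing: int,
) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for i in indices:
        c = crossings[i]
        k = min(per_crossing, len(c.blocks))
        pick = np.unique(np.linspace(0, len(c.blocks) - 1, k).round().astype(int))
        for j in pick:
            xs.append(c.blocks[j])
            ys.append(int(c.label))
    return np.stack(xs), np.asarray(ys)


def _vessel_predictions(model, crossings, indices) -> list[int]:
    preds = []
    for i in indices:
        d = fc.decide_vessel(model.predict_proba(crossings[i].blocks))
        preds.append(int(d.vessel_flowing))
    return preds


def parameter_recovery(
    seed: int,
    n_videos: int = DEFAULT_N_VIDEOS,
    epochs: int = DEFAULT_EPOCHS,
    blocks_per_crossing: int = DEFAULT_BLOCKS_PER_CROSSING,
    train_fraction: float = 0.7,
    block_frames: int = 200,
) -> dict:
    """Train CNN + baseline on a crossing-level split; score vessel accuracy.

    Returns a dict with both vessel-level accuracies, their confusion
    counts, the trained CNN model and the split sizes.
    """
    crossings = crossing_dataset(n_videos, seed=seed, block_frames=block_frames)
    rng = np.random.default_rng(seed + 1)
    order = rng.permutation(len(crossings))
    n_train = int(train_fraction * len(crossings))
    train_idx, test_idx = order[:n_train], order[n_train:]

    x_train, y_train = _training_blocks(crossings, train_idx, blocks_per_crossing)
    config = fc.CNNConfig(
        input_shape=x_train.shape[1:], max_epochs=epochs, seed=seed % (2**31)
    )
    cnn, history = fc.train_cnn(x_train, y_train, config)
    baseline = fc.train_logistic_baseline(x_train, y_train, seed=seed % (2**31))

    truth = [int(crossings[i].label) for i in test_idx]
    cnn_pred = _vessel_predictions(cnn, crossings, test_idx)
    base_pred = _vessel_predictions(baseline, crossings, test_idx)
    cnn_m = metrics(confusion(cnn_pred, truth))
    base_m = metrics(confusion(base_pred, truth))
    return {
        "n_crossings": len(crossings),
        "n_train_blocks": len(x_train),
        "n_test_crossings": len(test_idx),
        "epochs_run": len(history.loss),
        "cnn_vessel_accuracy": cnn_m.accuracy,
        "baseline_vessel_accuracy": base_m.accuracy,
        "cnn_model": cnn,
        "baseline_model": baseline,
        "history": history,
    }


def end_to_end(
    model,
    seed: int,
    config: synthetic.GeneratorConfig | None = None,
    n_frames: int = 220,
    pipeline_config: pl.PipelineConfig | None = None,
) -> dict:
    """Full two-step pipeline on a fresh phantom, scored against its truth."""
    config = config or synthetic.GeneratorConfig()
    vessels = synthetic.sample_vessel_tree(config, seed)
    stack, truth = synthetic.render_video(vessels, n_frames, config, seed + 1)
    pcfg = pipeline_config or pl.PipelineConfig()
    result = pl.run_pipeline(stack, model, pcfg, truth=truth)
    return {
        "detection_rate": result.detection_rate,
        "error_rate": result.error_rate,
        "n_decisions": len(result.decisions),
        "n_true_crossings": len(truth.crossings),
        "counters": result.counters,
    }
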