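"""Confusion-matrix metrics and the end-to-end detection/error protocol.

Positive means flowing. Metrics follow the standard confusion-matrix
derivations: accuracy (TP+TN)/n, positive precision TP/(TP+FP),
sensitivity TP/(TP+FN), F1 2TP/(2TP+FP+FN), and negative precision
TN/(TN+FN). A metric with a zero denominator is reported as undefined
(None), never silently coerced to 0 or 1.

The end-to-end protocol scores a full pipeline run against phantom ground
truth: the detection rate is the fraction of truly flowing crossings the
pipeline marks flowing, and the error rate is the fraction of
pipeline-flowing calls that are truly non-flowing or artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must count at least one item")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricSet:
    """The five table metrics; None marks an undefined (0/0) value."""

    accuracy: float | None
    positive_precision: float | None
    sensitivity: float | None
    f1: float | None
    negative_precision: float | None

    def rounded(self, ndigits: int = 2) -> dict:
        """Presentation form: 2-decimal rounding, as metric tables print."""
        return {
            k: (None if v is None else round(v, ndigits))
            for k, v in self.__dict__.items()
        }


def confusion(pred: Sequence[int], truth: Sequence[int]) -> ConfusionMatrix:
    """Count TP/TN/FP/FN with positive = flowing."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("pred and truth must be equal-length 1-D sequences")
    if pred.size < 1:
        raise ValueError("empty input")
    return ConfusionMatrix(
        tp=int(np.sum(pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """All five confusion-matrix derivations, full precision."""
    return MetricSet(
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
        positive_precision=_ratio(cm.tp, cm.tp + cm.fp),
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        f1=_ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn),
        negative_precision=_ratio(cm.tn, cm.tn + cm.fn),
    )


def end_to_end_eval(
    decisions: Sequence,
    truth_crossings: Sequence,
    match_radius_px: float = 3.0,
) -> tuple[float | None, float | None]:
    """Detection rate and error rate of a pipeline run against ground truth.

    decisions: objects with .center (row, col) and .vessel_flowing;
    truth_crossings: objects with .center and .label (true flow state).
    A decision matches the nearest truth crossing within match_radius_px.

    Returns (detection_rate, error_rate); either is None when its
    denominator is empty (no truly flowing crossings / no positive calls).
    """
    if not truth_crossings:
        raise ValueError("empty ground truth")
    t_centers = np.array([t.center for t in truth_crossings], dtype=float)
    t_labels = np.array([bool(t.label) for t in truth_crossings])

    flowing_calls = [d for d in decisions if d.vessel_flowing]
    detected = np.zeros(len(truth_crossings), dtype=bool)
    false_calls = 0
    for d in flowing_calls:
        dist = np.linalg.norm(t_centers - np.asarray(d.center, dtype=float), axis=1)
        j = int(np.argmin(dist))
        if dist[j] <= match_radius_px and t_labels[j]:
            detected[j] = True
        else:
            false_calls += 1

    n_true_flowing = int(t_labels.sum())
    detection_rate = detected[t_labels].mean() if n_true_flowing else None
    error_rate = false_calls / len(flowing_calls) if flowing_calls else None
    return (
        None if detection_rate is None else float(detection_rate),
        None if error_rate is None else float(error_rate),
    )
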