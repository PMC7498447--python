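"""Data-driven binarization of projection patterns and ROC / f1 evaluation.

Rather than imposing an arbitrary connectivity threshold, each injection's
measured pattern is binarized at a threshold derived from its own value
distribution: ``t = median(values) + std(values)`` (population std).  An
experiment whose median and spread are both tiny can end up with no value
above its threshold; it is then returned as an all-zero pattern and, by
convention, scores 0 for both auROC and f1 so such degenerate experiments
are visible as outliers rather than silently dropped.

The thresholding rule is a replaceable strategy: pass any callable
mapping a value vector to a threshold, or use :func:`quantile_threshold`
for a quantile-based alternative.

``multi_roc`` sweeps a family of external thresholds (quantiles of the
positive measured values) over the measured pattern and reports one ROC
curve per induced truth, showing how the ranking quality of the
continuous predictions depends on where "connected" is cut.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .datamodel import ProjectionMatrix
from .exceptions import ValidationError
from .predict import PredictionResult

__all__ = [
    "median_std_threshold",
    "quantile_threshold",
    "binarize_pattern",
    "auroc",
    "f1_score",
    "multi_roc",
    "MultiRocEntry",
    "evaluate_binary",
    "BinaryMetrics",
]

ThresholdRule = Callable[[np.ndarray], float]


def median_std_threshold(values: np.ndarray) -> float:
    """Default data-driven rule: median plus one population standard deviation."""
    return float(np.median(values) + np.std(values))


def quantile_threshold(q: float) -> ThresholdRule:
    """Build a quantile-based alternative thresholding rule."""

    def rule(values: np.ndarray) -> float:
        return float(np.quantile(values, q))

    return rule


def binarize_pattern(
    values: np.ndarray, rule: ThresholdRule = median_std_threshold
) -> tuple[np.ndarray, float]:
    """Binarize a non-negative pattern at its data-driven threshold.

    Returns ``(binary, threshold)`` with ``binary[i] = 1`` iff
    ``values[i] > threshold``.  When no value exceeds the threshold the
    all-zero vector is returned — the convention for experiments whose
    projection volumes are too low and scattered to threshold.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("cannot binarize an empty vector")
    if np.isnan(values).any():
        raise ValidationError("binarize_pattern requires NaN-free values")
    if values.min() < 0:
        raise ValidationError("binarize_pattern expects raw non-negative values")
    t = float(rule(values))
    return (values > t).astype(int), t


def auroc(truth_binary: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based area under the ROC curve with midrank tie handling.

    Returns 0.0 when the truth contains a single class — the convention
    used to flag degenerate all-zero experiments instead of NaN or 0.5.
    """
    truth = np.asarray(truth_binary, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if truth.shape != scores.shape:
        raise ValidationError("truth and scores must have equal length")
    if np.unique(truth).size < 2:
        return 0.0
    return float(roc_auc_score(truth, scores))


def f1_score(truth_binary: np.ndarray, pred_binary: np.ndarray) -> float:
    """f1 = 2 TP / (2 TP + FP + FN); 0 whenever there are no true positives."""
    truth = np.asarray(truth_binary, dtype=int)
    pred = np.asarray(pred_binary, dtype=int)
    if truth.shape != pred.shape:
        raise ValidationError("truth and prediction must have equal length")
    tp = int(np.sum((truth == 1) & (pred == 1)))
    fp = int(np.sum((truth == 0) & (pred == 1)))
    fn = int(np.sum((truth == 1) & (pred == 0)))
    if tp == 0:
        return 0.0
    return 2.0 * tp / (2.0 * tp + fp + fn)


@dataclass
class MultiRocEntry:
    external_threshold: float
    fpr: Optional[np.ndarray]
    tpr: Optional[np.ndarray]
    auroc: float
    degenerate: bool


def multi_roc(
    values: np.ndarray, scores: np.ndarray, n_thresholds: int = 9
) -> list[MultiRocEntry]:
    """One ROC curve per external threshold applied to the measured pattern.

    Thresholds are the ``n_thresholds`` inner quantiles of the *positive*
    measured values.  Thresholds inducing a single-class truth are flagged
    degenerate and score 0 with no curve.
    """
    values = np.asarray(values, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if values.shape != scores.shape:
        raise ValidationError("values and scores must have equal length")
    positive = values[values > 0]
    if positive.size == 0:
        qs = np.array([0.0])
    else:
        qs = np.quantile(positive, np.linspace(0, 1, n_thresholds + 2)[1:-1])
    out: list[MultiRocEntry] = []
    for t in np.unique(qs):
        truth = (values > t).astype(int)
        if np.unique(truth).size < 2:
            out.append(MultiRocEntry(float(t), None, None, 0.0, True))
            continue
        fpr, tpr, _ = roc_curve(truth, scores)
        out.append(MultiRocEntry(float(t), fpr, tpr, auroc(truth, scores), False))
    return out


@dataclass
class BinaryMetrics:
    injection_id: str
    threshold: float
    auroc: float
    f1: float
    degenerate: bool  # single-class measured truth (all-zero after thresholding)


def evaluate_binary(
    measured: ProjectionMatrix,
    predicted: Union[np.ndarray, PredictionResult],
    rule: ThresholdRule = median_std_threshold,
) -> list[BinaryMetrics]:
    """Binary evaluation of predictions against data-driven measured truths.

    ``measured`` must be on the raw non-negative scale, and ``predicted``
    must already be mapped back to that scale (invert the z-score with the
    stored column statistics, clip negatives, cube — see
    :func:`mesoconn.preprocess.inverse_rescale`).  Per injection, the
    truth is the binarized measured column; auROC scores the continuous
    predictions against it and f1 compares the binarized prediction.
    """
    pred = predicted.predicted if isinstance(predicted, PredictionResult) else predicted
    pred = np.asarray(pred, dtype=float)
    if pred.shape != measured.values.shape:
        raise ValidationError(
            f"prediction shape {pred.shape} != measured shape {measured.values.shape}"
        )
    out: list[BinaryMetrics] = []
    for j, inj in enumerate(measured.injection_ids):
        truth, t = binarize_pattern(measured.values[:, j], rule=rule)
        degenerate = np.unique(truth).size < 2
        a = auroc(truth, pred[:, j])
        pred_binary, _ = binarize_pattern(np.clip(pred[:, j], 0.0, None), rule=rule)
        f = f1_score(truth, pred_binary)
        out.append(BinaryMetrics(inj, t, a, f, degenerate))
    return out
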