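"""End-to-end composition of the analysis stages.

These helpers wire the stages together the way the CLI and the test suite
use them: generate (or load) a dataset, preprocess it, fit every tracing
category, and evaluate continuous and binary performance.  They are thin
orchestration over the per-stage modules and add no new modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .binarize import BinaryMetrics, evaluate_binary
from .datamodel import Dataset
from .predict import HyperGrid, PredictionResult, nested_cv_fit, null_predictions, surrogate_features
from .preprocess import PreprocessResult, inverse_rescale, preprocess_dataset
from .synthetic import GroundTruth, generate_dataset, generate_ground_truth

__all__ = ["PipelineRun", "run_pipeline", "fit_categories", "surrogate_median_r2"]


def _child_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=key).generate_state(1)[0] % (2**31))


@dataclass
class PipelineRun:
    """Everything the downstream analyses need from one end-to-end run."""

    ground_truth: Optional[GroundTruth]
    dataset: Dataset
    preprocessed: PreprocessResult
    results: dict[str, PredictionResult]
    null_results: dict[str, PredictionResult] = field(default_factory=dict)
    binary_metrics: dict[str, list[BinaryMetrics]] = field(default_factory=dict)

    def all_r2(self) -> np.ndarray:
        return np.concatenate([r.r2_values() for r in self.results.values()])

    def median_r2(self) -> float:
        return float(np.median(self.all_r2()))

    def all_auroc(self) -> np.ndarray:
        return np.asarray(
            [m.auroc for ms in self.binary_metrics.values() for m in ms if not m.degenerate]
        )


def fit_categories(
    pre: PreprocessResult,
    grid: Optional[HyperGrid] = None,
    features: Optional[np.ndarray] = None,
    seed: int = 0,
) -> dict[str, PredictionResult]:
    """Nested-CV fit of every tracing category on shared features.

    ``features`` defaults to the rescaled expression grid (genes as
    features); pass a dictionary matrix D to fit on spatial modules
    instead.  Each category gets a deterministic child seed.
    """
    if features is None:
        features = pre.rescaled.expression.values
    out: dict[str, PredictionResult] = {}
    for ci, proj in enumerate(pre.rescaled.projections):
        out[proj.category] = nested_cv_fit(
            features, proj, grid=grid, seed=_child_seed(seed, 10, ci)
        )
    return out


def run_pipeline(
    gt: Optional[GroundTruth] = None,
    seed: int = 0,
    grid: Optional[HyperGrid] = None,
    max_nan_frac: float = 0.8,
    with_null: bool = True,
    with_binary: bool = True,
    **gt_kwargs,
) -> PipelineRun:
    """Synthetic data -> preprocess -> per-category nested-CV fit -> evaluation.

    When ``gt`` is omitted a default-scale ground truth is generated from
    ``seed`` (any ``gt_kwargs`` are forwarded to the generator).
    """
    if gt is None:
        gt = generate_ground_truth(seed=seed, **gt_kwargs)
    dataset = generate_dataset(gt)
    pre = preprocess_dataset(dataset, max_nan_frac=max_nan_frac, seed=_child_seed(seed, 1))
    results = fit_categories(pre, grid=grid, seed=seed)
    run = PipelineRun(ground_truth=gt, dataset=dataset, preprocessed=pre, results=results)
    if with_null:
        for cat, res in results.items():
            run.null_results[cat] = null_predictions(
                pre.rescaled.projection(cat), res.fold_assignment
            )
    if with_binary:
        for cat, res in results.items():
            rescaled = pre.rescaled.projection(cat)
            raw_pred = inverse_rescale(res.predicted, rescaled.col_means, rescaled.col_stds)
            run.binary_metrics[cat] = evaluate_binary(pre.raw.projection(cat), raw_pred)
    return run


def surrogate_median_r2(
    pre: PreprocessResult,
    n_replicates: int = 25,
    grid: Optional[HyperGrid] = None,
    seed: int = 0,
    categories: Optional[list[str]] = None,
) -> tuple[float, np.ndarray]:
    """Median out-of-fold r2 over surrogate-feature replicates.

    Each replicate permutes every gene's expression independently across
    areas and reruns the nested-CV fit; scores are pooled over replicates
    and injections.  Returns the pooled median and the pooled score array.
    """
    X = pre.rescaled.expression.values
    projections = [
        p for p in pre.rescaled.projections if categories is None or p.category in categories
    ]
    scores: list[float] = []
    for rep in range(n_replicates):
        Xs = surrogate_features(X, seed=_child_seed(seed, 20, rep))
        for ci, proj in enumerate(projections):
            res = nested_cv_fit(Xs, proj, grid=grid, seed=_child_seed(seed, 21, rep, ci))
            scores.extend(res.r2_values())
    arr = np.asarray(scores)
    return float(np.median(arr)), arr
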