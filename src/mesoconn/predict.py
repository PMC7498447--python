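"""Multi-output prediction of projection patterns with nested cross-validation.

One model is fitted per tracing category, predicting all of the category's
injections jointly from the shared feature grid (genes or spatial
modules) with a single hyperparameter setting.  Validation is nested
3-fold cross-validation over brain areas: an outer split provides
out-of-fold predictions, and within each outer training set an inner
3-fold grid search picks the hyperparameters maximizing the mean r2 over
all of the category's injections.

Performance is the coefficient of determination

    r2 = 1 - sum_i (y_i - f_i)^2 / sum_i (y_i - mean(y))^2

computed per injection on the concatenated out-of-fold predictions; it is
unbounded below and equals 1 only for a perfect prediction.

Three controls accompany the fits:

* surrogate features — every gene's expression independently permuted
  across areas, destroying spatial correspondence while preserving each
  gene's value distribution exactly;
* null predictions — the training-fold mean of each injection, a
  predictor blind to variability across areas (its out-of-fold r2 is
  typically slightly negative);
* a permutation test comparing each cre-line's median r2 against medians
  of equally sized random subsets of the wild-type scores, probing
  whether cre-line performance differs beyond sampling variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

from .datamodel import ProjectionMatrix
from .exceptions import ConfigError, UndefinedStatisticError, ValidationError

__all__ = [
    "HyperGrid",
    "PredictionResult",
    "r2_score",
    "nested_cv_fit",
    "surrogate_features",
    "null_predictions",
    "wildtype_subset_test",
]


def r2_score(y: np.ndarray, f: np.ndarray) -> float:
    """Fraction of the variance of ``y`` explained by the prediction ``f``."""
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    if y.shape != f.shape or y.ndim != 1:
        raise ValidationError("r2_score expects two equal-length vectors")
    if y.size < 2:
        raise ValidationError("r2_score needs at least 2 observations")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise UndefinedStatisticError("r2 undefined for a constant target")
    sse = float(np.sum((y - f) ** 2))
    return 1.0 - sse / sst


@dataclass
class HyperGrid:
    """Hyperparameter grid for one of the two supported regressors.

    The defaults are conventional desk-scale grids: ridge penalties
    log-spaced over six decades, and a small random-forest lattice.
    """

    method: str = "ridge"
    ridge_alphas: Sequence[float] = field(
        default_factory=lambda: tuple(np.logspace(-3, 3, 7))
    )
    rf_n_trees: Sequence[int] = (100, 300)
    rf_max_depth: Sequence[Optional[int]] = (None, 10)
    rf_min_leaf: Sequence[int] = (1, 5)

    def candidates(self) -> list[dict]:
        if self.method == "ridge":
            out = [{"alpha": float(a)} for a in self.ridge_alphas]
        elif self.method == "random_forest":
            out = [
                {"n_estimators": int(n), "max_depth": d, "min_samples_leaf": int(m)}
                for n in self.rf_n_trees
                for d in self.rf_max_depth
                for m in self.rf_min_leaf
            ]
        else:
            raise ConfigError(f"unknown method {self.method!r}")
        if not out:
            raise ConfigError("empty hyperparameter grid")
        return out

    def build(self, params: dict, seed: int):
        if self.method == "ridge":
            return Ridge(**params)
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)


@dataclass
class PredictionResult:
    """Out-of-fold predictions and per-injection scores for one category."""

    category: str
    area_ids: list[str]
    injection_ids: list[str]
    predicted: np.ndarray  # areas x injections, out-of-fold
    r2_per_injection: dict[str, float]  # NaN for degenerate (constant) targets
    chosen_hyperparameters: Optional[list[dict]]  # one per outer fold
    fold_assignment: np.ndarray  # area index -> outer fold
    degenerate_injections: list[str]
    seed: int

    def r2_values(self) -> np.ndarray:
        """Finite per-injection r2 scores."""
        vals = np.asarray(list(self.r2_per_injection.values()), dtype=float)
        return vals[np.isfinite(vals)]

    def median_r2(self) -> float:
        return float(np.median(self.r2_values()))


def _seed_ints(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


def _mean_r2(y: np.ndarray, f: np.ndarray) -> float:
    """Mean r2 over target columns, skipping constant columns."""
    scores = []
    for j in range(y.shape[1]):
        col = y[:, j]
        if np.ptp(col) == 0:
            continue
        scores.append(r2_score(col, f[:, j]))
    return float(np.mean(scores)) if scores else -np.inf


def nested_cv_fit(
    features: np.ndarray,
    targets: ProjectionMatrix,
    grid: Optional[HyperGrid] = None,
    n_outer: int = 3,
    n_inner: int = 3,
    seed: int = 0,
) -> PredictionResult:
    """Nested cross-validated multi-output fit of one tracing category.

    ``features`` is an areas x p grid sharing the area ordering of
    ``targets``.  The outer split yields out-of-fold predictions for every
    area; the inner grid search selects one hyperparameter setting per
    outer fold for the whole category, scored by mean r2 over injections.
    """
    features = np.asarray(features, dtype=float)
    y = np.asarray(targets.values, dtype=float)
    if features.ndim != 2 or features.shape[1] == 0:
        raise ValidationError("features must be a non-empty areas x p grid")
    if features.shape[0] != y.shape[0]:
        raise ValidationError("features and targets must share the area axis")
    n_areas = y.shape[0]
    if n_areas < n_outer:
        raise ValidationError(f"{n_areas} areas cannot be split into {n_outer} folds")
    if grid is None:
        grid = HyperGrid()
    candidates = grid.candidates()
    seeds = _seed_ints(seed, 2 + n_outer * (1 + len(candidates)))
    outer = KFold(n_splits=n_outer, shuffle=True, random_state=seeds[0])

    predicted = np.full_like(y, np.nan)
    fold_assignment = np.empty(n_areas, dtype=int)
    chosen: list[dict] = []
    si = 2
    for fold, (train_idx, test_idx) in enumerate(outer.split(np.arange(n_areas))):
        fold_assignment[test_idx] = fold
        X_tr, y_tr = features[train_idx], y[train_idx]
        inner = KFold(n_splits=n_inner, shuffle=True, random_state=seeds[1] + fold)
        best_score, best_params = -np.inf, candidates[0]
        for cand in candidates:
            oof = np.full_like(y_tr, np.nan)
            for itr, iva in inner.split(np.arange(len(train_idx))):
                est = grid.build(cand, seed=seeds[si % len(seeds)])
                est.fit(X_tr[itr], y_tr[itr])
                oof[iva] = np.asarray(est.predict(X_tr[iva])).reshape(len(iva), -1)
            score = _mean_r2(y_tr, oof)
            if score > best_score:
                best_score, best_params = score, cand
            si += 1
        est = grid.build(best_params, seed=seeds[si % len(seeds)])
        est.fit(X_tr, y_tr)
        predicted[test_idx] = np.asarray(est.predict(features[test_idx])).reshape(
            len(test_idx), -1
        )
        chosen.append(dict(best_params))

    r2_per_injection: dict[str, float] = {}
    degenerate: list[str] = []
    for j, inj in enumerate(targets.injection_ids):
        if np.ptp(y[:, j]) == 0:
            r2_per_injection[inj] = float("nan")
            degenerate.append(inj)
        else:
            r2_per_injection[inj] = r2_score(y[:, j], predicted[:, j])
    return PredictionResult(
        category=targets.category,
        area_ids=list(targets.area_ids),
        injection_ids=list(targets.injection_ids),
        predicted=predicted,
        r2_per_injection=r2_per_injection,
        chosen_hyperparameters=chosen,
        fold_assignment=fold_assignment,
        degenerate_injections=degenerate,
        seed=seed,
    )


def surrogate_features(X: np.ndarray, seed: int = 0) -> np.ndarray:
    """Independently permute each feature column across areas.

    Destroys the area-to-area correspondence between expression and
    projections while conserving each gene's value multiset exactly.
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValidationError("surrogate_features requires a NaN-free grid")
    rng = np.random.default_rng(seed)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        out[:, j] = X[rng.permutation(X.shape[0]), j]
    return out


def null_predictions(
    targets: ProjectionMatrix, fold_assignment: np.ndarray
) -> PredictionResult:
    """Mean-of-training-areas predictor under the given outer folds.

    For each fold and injection the held-out areas are predicted by the
    mean of the injection's values over the training areas — a predictor
    with no across-area variability, whose out-of-fold r2 is at best ~0.
    """
    y = np.asarray(targets.values, dtype=float)
    fold_assignment = np.asarray(fold_assignment, dtype=int)
    if fold_assignment.shape[0] != y.shape[0]:
        raise ValidationError("fold assignment must cover every area")
    folds = np.unique(fold_assignment)
    if folds.size < 2:
        raise ValidationError("null predictor needs >= 2 folds")
    predicted = np.empty_like(y)
    for f in folds:
        test = fold_assignment == f
        predicted[test] = y[~test].mean(axis=0)[None, :]
    r2_per_injection: dict[str, float] = {}
    degenerate: list[str] = []
    for j, inj in enumerate(targets.injection_ids):
        if np.ptp(y[:, j]) == 0:
            r2_per_injection[inj] = float("nan")
            degenerate.append(inj)
        else:
            r2_per_injection[inj] = r2_score(y[:, j], predicted[:, j])
    return PredictionResult(
        category=targets.category,
        area_ids=list(targets.area_ids),
        injection_ids=list(targets.injection_ids),
        predicted=predicted,
        r2_per_injection=r2_per_injection,
        chosen_hyperparameters=None,
        fold_assignment=fold_assignment,
        degenerate_injections=degenerate,
        seed=0,
    )


def _extract_scores(x) -> np.ndarray:
    if isinstance(x, PredictionResult):
        return x.r2_values()
    arr = np.asarray(x, dtype=float)
    return arr[np.isfinite(arr)]


def wildtype_subset_test(
    wt_result,
    creline_results: Sequence,
    n_perm_per_line: int = 100,
    seed: int = 0,
) -> tuple[float, dict[int, np.ndarray]]:
    """Permutation test of cre-line vs wild-type prediction performance.

    For each cre-line of size n, ``n_perm_per_line`` random size-n subsets
    of the wild-type r2 scores are drawn and the absolute difference of
    each subset median from the full wild-type median forms the null.  The
    observed statistic per line is |median(line) - median(wild-type)|; the
    returned p-value pools exceedance counts over all lines.
    """
    wt = _extract_scores(wt_result)
    lines = [_extract_scores(c) for c in creline_results]
    if not lines:
        raise ConfigError("no cre-line results supplied")
    if max(len(l) for l in lines) > len(wt):
        raise ValidationError("a cre-line has more injections than the wild-type pool")
    if n_perm_per_line < 1:
        raise ConfigError("n_perm_per_line must be >= 1")
    rng = np.random.default_rng(seed)
    wt_median = float(np.median(wt))
    exceed = 0
    total = 0
    null_medians: dict[int, np.ndarray] = {}
    for li, line in enumerate(lines):
        observed = abs(float(np.median(line)) - wt_median)
        nulls = np.empty(n_perm_per_line)
        for p in range(n_perm_per_line):
            subset = rng.choice(wt, size=len(line), replace=False)
            nulls[p] = abs(float(np.median(subset)) - wt_median)
        exceed += int(np.sum(nulls >= observed))
        total += n_perm_per_line
        null_medians[li] = nulls
    return exceed / total, null_medians
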