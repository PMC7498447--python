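"""Dictionary learning and sparse coding (DLSC) of spatial gene modules.

The expression grid ``X`` (areas x genes) is factorized as ``X ~ D @ a``
with a dictionary ``D`` (areas x K) of non-negative *spatial modules* and
non-negative sparse gene loadings ``a`` (K x genes), by alternating
minimization of

    0.5 * ||X - D a||_F^2 + lambda * sum(|a|)
    subject to  D >= 0,  a >= 0,  ||d_k||_2 <= 1.

The l1 term is applied in Lagrangian (penalty) form with weight
``lambda_l1`` per coefficient, the standard sparse-coding formulation.
Each half-step is an exact convex solve, so the recorded objective trace
is non-increasing by construction:

* coefficient step — per gene column, non-negative l1-penalized least
  squares (coordinate-descent lasso with a positivity constraint; plain
  NNLS when ``lambda_l1 == 0``);
* dictionary step — block-coordinate updates of each module column; with
  the other columns fixed the exact minimizer is the Euclidean projection
  of the unconstrained update onto the set {d >= 0, ||d|| <= 1}, i.e.
  clip negatives then scale into the unit ball.

Modules that lose all their coefficient mass ("dead atoms") are re-seeded
from the worst-reconstructed data column during the dictionary step; a
dead atom contributes nothing to the objective, so re-seeding leaves the
trace monotone.

The constrained variant fixes ``a`` to an external cell-types x genes
signature grid and solves only for ``D`` (row-wise NNLS), yielding one
module per cell type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import nnls
from sklearn.linear_model import Lasso

from .datamodel import CellTypeSignatures, ExpressionMatrix
from .exceptions import ConfigError, UndefinedStatisticError, ValidationError

__all__ = [
    "DLSCConfig",
    "SpatialModules",
    "GeneLoadings",
    "fit_dlsc",
    "fit_constrained",
    "reconstruction_error",
    "shift_nonnegative",
    "choose_module_count",
    "select_module_count",
]


@dataclass
class DLSCConfig:
    K: int = 200
    lambda_l1: float = 1.0
    max_iter: int = 100
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ConfigError("K must be >= 1")
        if self.lambda_l1 < 0:
            raise ConfigError("lambda_l1 must be >= 0")
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")


@dataclass
class SpatialModules:
    """Non-negative dictionary D: areas x modules."""

    area_ids: list[str]
    module_ids: list[str]
    D: np.ndarray

    def footprint_coverage(self, eps: float = 1e-6) -> np.ndarray:
        """Per-module fraction of areas with a dictionary entry above eps."""
        return (self.D > eps).mean(axis=0)


@dataclass
class GeneLoadings:
    """Non-negative sparse coefficients a: modules x genes."""

    module_ids: list[str]
    gene_ids: list[str]
    a: np.ndarray

    @property
    def sparsity(self) -> float:
        """Fraction of exactly-zero entries."""
        return float((self.a == 0).mean())


def shift_nonnegative(X: np.ndarray) -> np.ndarray:
    """Shift a (z-scored) grid by its global minimum so all entries are >= 0.

    Preserves ordering and contrasts; used to feed rescaled data to the
    non-negative factorization.
    """
    X = np.asarray(X, dtype=float)
    lo = X.min() if X.size else 0.0
    return X - lo if lo < 0 else X.copy()


def _as_grid(X) -> tuple[np.ndarray, Optional[list[str]], Optional[list[str]]]:
    if isinstance(X, ExpressionMatrix):
        return np.asarray(X.values, dtype=float), X.area_ids, X.gene_ids
    return np.asarray(X, dtype=float), None, None


def _sparse_code_column(D: np.ndarray, x: np.ndarray, lam: float) -> np.ndarray:
    """argmin_{a>=0} 0.5||x - D a||^2 + lam * sum(a)."""
    if lam == 0.0:
        coef, _ = nnls(D, x)
        return coef
    n = D.shape[0]
    # sklearn's lasso objective is (1/2n)||.||^2 + alpha ||a||_1
    model = Lasso(
        alpha=lam / n, positive=True, fit_intercept=False, max_iter=5000, tol=1e-10
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # benign convergence warnings on tiny problems
        model.fit(D, x)
    return np.asarray(model.coef_, dtype=float)


def _objective(X: np.ndarray, D: np.ndarray, a: np.ndarray, lam: float) -> float:
    resid = X - D @ a
    return 0.5 * float(np.sum(resid * resid)) + lam * float(np.sum(np.abs(a)))


def _project_atom(u: np.ndarray) -> np.ndarray:
    """Euclidean projection onto {d >= 0, ||d||_2 <= 1}."""
    d = np.clip(u, 0.0, None)
    norm = np.linalg.norm(d)
    if norm > 1.0:
        d /= norm
    return d


def _worst_column(X: np.ndarray, D: np.ndarray, a: np.ndarray) -> np.ndarray:
    resid = X - D @ a
    j = int(np.argmax(np.sum(resid * resid, axis=0)))
    col = np.clip(X[:, j], 0.0, None)
    norm = np.linalg.norm(col)
    return col / norm if norm > 0 else np.full(X.shape[0], 1.0 / np.sqrt(X.shape[0]))


def fit_dlsc(
    X, config: DLSCConfig
) -> tuple[SpatialModules, GeneLoadings, list[float]]:
    """Alternating-minimization DLSC fit.

    Parameters
    ----------
    X:
        Non-negative areas x genes grid (an :class:`ExpressionMatrix` or a
        plain array).  Callers holding z-scored data shift it first with
        :func:`shift_nonnegative`.
    config:
        Module count, l1 weight, iteration budget and seed.

    Returns
    -------
    (SpatialModules, GeneLoadings, objective_trace)
        The trace holds the penalized objective after every full
        iteration and is non-increasing.
    """
    X, area_ids, gene_ids = _as_grid(X)
    if not np.isfinite(X).all():
        raise ValidationError("DLSC input must be finite (impute NaNs first)")
    if X.min() < 0:
        raise ValidationError("DLSC input must be non-negative; use shift_nonnegative")
    n_areas, n_genes = X.shape
    K = config.K
    if K > min(n_areas, n_genes):
        raise ConfigError(f"K={K} exceeds matrix rank bound {min(n_areas, n_genes)}")
    rng = np.random.default_rng(config.seed)

    # scale-matched start: K distinct data columns, unit-normalized
    cols = rng.choice(n_genes, size=K, replace=False)
    D = np.empty((n_areas, K))
    for k, j in enumerate(cols):
        col = X[:, j]
        norm = np.linalg.norm(col)
        D[:, k] = col / norm if norm > 0 else rng.uniform(0, 1, n_areas)

    a = np.zeros((K, n_genes))
    trace: list[float] = []
    for _ in range(config.max_iter):
        # --- coefficient step: exact per-column solve
        for j in range(n_genes):
            a[:, j] = _sparse_code_column(D, X[:, j], config.lambda_l1)
        # --- dictionary step: block-coordinate projected updates
        A = a @ a.T  # K x K
        B = X @ a.T  # areas x K
        for k in range(K):
            if A[k, k] == 0.0:
                # dead atom: its coefficients are all zero so D[:,k] is free;
                # re-seed from the worst-reconstructed column (objective unchanged)
                D[:, k] = _worst_column(X, D, a)
                continue
            u = D[:, k] + (B[:, k] - D @ A[:, k]) / A[k, k]
            D[:, k] = _project_atom(u)
        trace.append(_objective(X, D, a, config.lambda_l1))
        if len(trace) >= 2 and abs(trace[-2] - trace[-1]) < config.tol:
            break

    # final degeneracy sweep: a module column that converged to exactly zero
    # contributes nothing, so zeroing its coefficients (objective decreases)
    # and re-seeding its column keeps every module non-trivial
    for k in range(K):
        if np.linalg.norm(D[:, k]) == 0.0:
            a[k, :] = 0.0
            D[:, k] = _worst_column(X, D, a)

    module_ids = [f"M{k:03d}" for k in range(K)]
    modules = SpatialModules(
        area_ids=list(area_ids) if area_ids else [f"A{i:04d}" for i in range(n_areas)],
        module_ids=module_ids,
        D=D,
    )
    loadings = GeneLoadings(
        module_ids=module_ids,
        gene_ids=list(gene_ids) if gene_ids else [f"G{i:04d}" for i in range(n_genes)],
        a=a,
    )
    return modules, loadings, trace


def fit_constrained(X, a_fixed: Union[CellTypeSignatures, GeneLoadings]) -> SpatialModules:
    """Solve D = argmin ||X - D a_fixed||_F^2 s.t. D >= 0, with fixed loadings.

    The gene sets of ``X`` and ``a_fixed`` are intersected and identically
    reordered before the solve; genes absent from either side are dropped.
    The solve is row-wise NNLS (one small problem per brain area), and K
    equals the number of cell types / fixed modules.
    """
    X, area_ids, gene_ids = _as_grid(X)
    if isinstance(a_fixed, CellTypeSignatures):
        fixed_ids, fixed_genes, a_grid = a_fixed.celltype_ids, a_fixed.gene_ids, a_fixed.values
    elif isinstance(a_fixed, GeneLoadings):
        fixed_ids, fixed_genes, a_grid = a_fixed.module_ids, a_fixed.gene_ids, a_fixed.a
    else:
        raise TypeError("a_fixed must be CellTypeSignatures or GeneLoadings")
    if np.any(a_grid < 0):
        raise ValidationError("fixed loadings must be non-negative")

    if gene_ids is not None:
        common = [g for g in gene_ids if g in set(fixed_genes)]
        if not common:
            raise ValidationError("empty gene intersection between X and fixed loadings")
        dropped = len(gene_ids) - len(common)
        if dropped:
            warnings.warn(f"dropping {dropped} genes absent from the fixed loadings")
        xi = {g: i for i, g in enumerate(gene_ids)}
        fi = {g: i for i, g in enumerate(fixed_genes)}
        X = X[:, [xi[g] for g in common]]
        a_grid = a_grid[:, [fi[g] for g in common]]
    elif X.shape[1] != a_grid.shape[1]:
        raise ValidationError(
            "plain-array X and fixed loadings must already share a gene axis"
        )

    At = a_grid.T  # genes x K design for each area row
    D = np.empty((X.shape[0], a_grid.shape[0]))
    for i in range(X.shape[0]):
        D[i], _ = nnls(At, X[i])
    return SpatialModules(
        area_ids=list(area_ids) if area_ids else [f"A{i:04d}" for i in range(X.shape[0])],
        module_ids=list(fixed_ids),
        D=D,
    )


def reconstruction_error(X: np.ndarray, D: np.ndarray, a: np.ndarray) -> float:
    """Relative Frobenius reconstruction error ||X - D a||_F / ||X||_F."""
    X = np.asarray(X, dtype=float)
    denom = np.linalg.norm(X)
    if denom == 0:
        raise UndefinedStatisticError("reconstruction error undefined for ||X||_F = 0")
    return float(np.linalg.norm(X - np.asarray(D) @ np.asarray(a)) / denom)


def choose_module_count(scores: dict[int, float], margin: float = 0.01) -> int:
    """Parsimony rule: smallest K whose score is within ``margin`` of the best.

    Encodes the selection logic used to prefer a 200-module dictionary
    scoring 0.51 over a 300-module one scoring 0.52: near-ties within the
    margin are attributed to variability and the smaller dictionary wins.
    """
    if not scores:
        raise ConfigError("no candidate module counts scored")
    best = max(scores.values())
    eligible = [k for k, s in scores.items() if s >= best - margin]
    return min(eligible)


def select_module_count(
    X,
    projections: Sequence,
    candidate_Ks: Sequence[int],
    predictor_config=None,
    seed: int = 0,
    margin: float = 0.01,
    dlsc_kwargs: Optional[dict] = None,
) -> tuple[int, dict[int, dict[str, float]]]:
    """Sweep candidate module counts, scoring each by downstream prediction.

    For each K the expression grid is factorized, the dictionary columns
    are used as features in the nested-CV ridge fit of every projection
    category, and the median and IQR of out-of-fold r2 over all injections
    are recorded.  The chosen K follows :func:`choose_module_count`.
    Candidates exceeding the number of areas are skipped with a warning.
    """
    from .predict import HyperGrid, nested_cv_fit  # local import to avoid a cycle

    if not candidate_Ks:
        raise ConfigError("candidate_Ks must be non-empty")
    X_grid, area_ids, _ = _as_grid(X)
    n_areas = X_grid.shape[0]
    grid = predictor_config if predictor_config is not None else HyperGrid()
    dlsc_kwargs = dict(dlsc_kwargs or {})
    per_k: dict[int, dict[str, float]] = {}
    for K in candidate_Ks:
        if K > n_areas:
            warnings.warn(f"skipping K={K}: exceeds {n_areas} areas")
            continue
        cfg = DLSCConfig(K=K, seed=seed, **dlsc_kwargs)
        modules, _, _ = fit_dlsc(shift_nonnegative(X_grid), cfg)
        r2s: list[float] = []
        for proj in projections:
            res = nested_cv_fit(modules.D, proj, grid, seed=seed)
            r2s.extend(v for v in res.r2_per_injection.values() if np.isfinite(v))
        arr = np.asarray(r2s)
        per_k[K] = {
            "median_r2": float(np.median(arr)),
            "iqr": float(np.percentile(arr, 75) - np.percentile(arr, 25)),
        }
    if not per_k:
        raise ConfigError("every candidate K was skipped")
    chosen = choose_module_count({k: v["median_r2"] for k, v in per_k.items()}, margin)
    return chosen, per_k
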