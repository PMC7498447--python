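"""NaN filtering, imputation and rescaling of both data modalities.

The pipeline order is fixed: filter areas -> impute -> cube-root ->
z-score.  Areas are dropped when their NaN fraction *strictly exceeds* the
threshold (default 0.8) in the expression matrix or in any projection
matrix.  Expression NaNs are replaced by the gene's median over observed
areas.  Projection NaNs are imputed by stratified sampling: each column's
observed values are split into the exact-zero group and the non-zero
group, a group is chosen with probability proportional to its observed
fraction, and a value is drawn uniformly from it (the zero group always
yields exactly 0, preserving the zero-inflation point mass).

The rescale is a cube root (reducing right-skew) followed by a per-column
z-score across areas using the population (ddof=0) standard deviation;
constant columns map to all-zeros.  The column means/stds of the
cube-root values are kept on the returned matrix so predictions can be
mapped back to the raw non-negative scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np

from .datamodel import Dataset, ExpressionMatrix, ProjectionMatrix, assemble_dataset
from .exceptions import EmptyDatasetError, ImputationError, ValidationError

__all__ = [
    "filter_areas",
    "impute_expression",
    "impute_projections",
    "rescale",
    "inverse_rescale",
    "preprocess_dataset",
    "PreprocessResult",
]

Matrix = Union[ExpressionMatrix, ProjectionMatrix]


def _nan_frac_rows(values: np.ndarray) -> np.ndarray:
    if values.shape[1] == 0:
        return np.zeros(values.shape[0])
    return np.isnan(values).mean(axis=1)


def filter_areas(dataset: Dataset, max_nan_frac: float = 0.8) -> tuple[Dataset, list[str]]:
    """Drop areas whose NaN fraction exceeds ``max_nan_frac`` in any modality.

    Removal uses a strict inequality: an area at exactly the threshold is
    kept.  The surviving matrices are re-assembled over the kept areas.

    Returns the filtered dataset and the removed area ids (in the shared
    lexicographic order).
    """
    if not 0.0 <= max_nan_frac <= 1.0:
        raise ValidationError(f"max_nan_frac must lie in [0, 1], got {max_nan_frac}")
    worst = _nan_frac_rows(dataset.expression.values)
    for proj in dataset.projections:
        worst = np.maximum(worst, _nan_frac_rows(proj.values))
    keep = worst <= max_nan_frac
    removed = [a for a, k in zip(dataset.area_ids, keep) if not k]
    if not keep.any():
        raise EmptyDatasetError("area filtering removed every brain area")
    idx = np.flatnonzero(keep)
    filtered = assemble_dataset(
        dataset.expression.take_areas(idx),
        [p.take_areas(idx) for p in dataset.projections],
        dataset.metadata,
        annotations=dataset.annotations,
        celltype_signatures=dataset.celltype_signatures,
    )
    return filtered, removed


def impute_expression(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Replace each NaN with the gene's median over observed areas."""
    values = expr.values.copy()
    all_nan = np.all(np.isnan(values), axis=0)
    if all_nan.any():
        bad = [expr.gene_ids[i] for i in np.flatnonzero(all_nan)[:5]]
        raise ImputationError(f"all-NaN gene columns (should have been filtered): {bad}")
    if np.isnan(values).any():
        medians = np.nanmedian(values, axis=0)
        rows, cols = np.nonzero(np.isnan(values))
        values[rows, cols] = medians[cols]
    return replace(expr, values=values)


def impute_projections(proj: ProjectionMatrix, seed: int = 0) -> ProjectionMatrix:
    """Stratified sampling imputation of projection NaNs, per column.

    Zero in the stratification means exactly 0.0 — the zero-inflation point
    mass of normalized projection volume — not a tolerance band.
    """
    rng = np.random.default_rng(seed)
    values = proj.values.copy()
    for j in range(values.shape[1]):
        col = values[:, j]
        missing = np.isnan(col)
        if not missing.any():
            continue
        observed = col[~missing]
        if observed.size == 0:
            raise ImputationError(
                f"injection {proj.injection_ids[j]!r} has no observed values"
            )
        nonzero = observed[observed != 0.0]
        p_zero = 1.0 - nonzero.size / observed.size
        n_missing = int(missing.sum())
        draws = np.zeros(n_missing)
        pick_nonzero = rng.random(n_missing) >= p_zero
        n_nz = int(pick_nonzero.sum())
        if n_nz > 0:
            # p_zero < 1 here implies the non-zero group is non-empty
            draws[pick_nonzero] = rng.choice(nonzero, size=n_nz, replace=True)
        col[missing] = draws
    return replace(proj, values=values)


def rescale(matrix: Matrix) -> Matrix:
    """Cube-root then per-column z-score across areas (population std).

    Non-degenerate output columns have mean ~0 and std ~1; constant columns
    (which carry no signal) map to all-zeros rather than raising.  The
    cube-root column means/stds are stored on the result for inversion.
    """
    if np.isnan(matrix.values).any():
        raise ValidationError("rescale requires a NaN-free matrix; impute first")
    if matrix.rescaled:
        raise ValidationError("matrix is already rescaled")
    roots = np.cbrt(matrix.values)
    means = roots.mean(axis=0)
    stds = roots.std(axis=0)  # population (ddof=0) convention
    safe = np.where(stds > 0, stds, 1.0)
    z = (roots - means[None, :]) / safe[None, :]
    z[:, stds == 0] = 0.0
    return replace(matrix, values=z, rescaled=True, col_means=means, col_stds=stds)


def inverse_rescale(
    values: np.ndarray, col_means: np.ndarray, col_stds: np.ndarray
) -> np.ndarray:
    """Map z-scored values back to the raw non-negative scale.

    Inverts the z-score with the stored column statistics, clips negatives
    to 0 (the raw scale is non-negative) and cubes.
    """
    roots = values * np.asarray(col_stds)[None, :] + np.asarray(col_means)[None, :]
    return np.clip(roots, 0.0, None) ** 3


@dataclass
class PreprocessResult:
    """Filtered/imputed raw dataset, its rescaled twin, and a report."""

    raw: Dataset  # filtered + imputed, still on the raw non-negative scale
    rescaled: Dataset
    removed_area_ids: list[str]
    report: dict


def preprocess_dataset(
    dataset: Dataset, max_nan_frac: float = 0.8, seed: int = 0
) -> PreprocessResult:
    """Run the full pipeline: filter -> impute -> cube-root -> z-score.

    Projection imputation uses a distinct child seed per category so the
    result is reproducible and insensitive to category order.
    """
    filtered, removed = filter_areas(dataset, max_nan_frac=max_nan_frac)
    n_expr_nan = int(np.isnan(filtered.expression.values).sum())
    expr_raw = impute_expression(filtered.expression)
    projs_raw = []
    n_proj_nan = 0
    for ci, proj in enumerate(filtered.projections):
        n_proj_nan += int(np.isnan(proj.values).sum())
        child = np.random.SeedSequence(seed, spawn_key=(ci,)).generate_state(1)[0] % (2**31)
        projs_raw.append(impute_projections(proj, seed=int(child)))
    raw = Dataset(
        expression=expr_raw,
        projections=projs_raw,
        metadata=filtered.metadata,
        annotations=filtered.annotations,
        celltype_signatures=filtered.celltype_signatures,
    )
    rescaled = Dataset(
        expression=rescale(expr_raw),
        projections=[rescale(p) for p in projs_raw],
        metadata=filtered.metadata,
        annotations=filtered.annotations,
        celltype_signatures=filtered.celltype_signatures,
    )
    report = {
        "n_areas_removed": len(removed),
        "n_areas_kept": len(raw.area_ids),
        "n_expression_nans_imputed": n_expr_nan,
        "n_projection_nans_imputed": n_proj_nan,
    }
    return PreprocessResult(raw=raw, rescaled=rescaled, removed_area_ids=removed, report=report)
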