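"""Relating spatial gene modules to individual projection patterns.

Three analyses connect the dictionary columns (spatial modules) to a
projection pattern:

* Pearson correlation of every module footprint with the pattern, with a
  two-sided t-reference p-value so a significance cut (p > 0.05) can be
  drawn under the correlation histogram;
* prediction of the pattern from its top-3 best-correlated modules by
  out-of-fold ordinary least squares, reporting both r2 and the Pearson r
  between pattern and prediction;
* a six-level *footprint overlap code* per brain area summarizing joint
  presence of the pattern and the three modules:

      1.0  present in the pattern and all three modules
      0.8  present in the pattern and exactly two modules
      0.6  present in the pattern and exactly one module
      0.4  present in the pattern only
      0.2  present in one or more modules but absent from the pattern
      0.0  absent everywhere

"Present" means a value above a small epsilon on the raw non-negative
scale, where zero is meaningful.
"""

from __future__ import annotations

from typing import NamedTuple, Optional, Sequence, Union

import numpy as np
from scipy import stats
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold

from .dlsc import SpatialModules
from .exceptions import ConfigError, UndefinedStatisticError, ValidationError
from .predict import r2_score

__all__ = [
    "pearson_r",
    "correlate_modules",
    "predict_from_top_modules",
    "footprint_code",
    "FOOTPRINT_CODES",
]

FOOTPRINT_CODES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


class PearsonResult(NamedTuple):
    r: float
    p: float


def pearson_r(x: np.ndarray, y: np.ndarray) -> PearsonResult:
    """Product-moment correlation with a two-sided t-reference p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson_r expects two equal-length vectors")
    if x.size < 3:
        raise ValidationError("pearson_r needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for constant input")
    res = stats.pearsonr(x, y)
    return PearsonResult(float(res.statistic), float(res.pvalue))


def correlate_modules(
    modules: Union[SpatialModules, np.ndarray], y: np.ndarray
) -> dict[str, float]:
    """Pearson r of every module footprint with the projection column.

    Constant module columns carry no spatial signal; their entry is NaN
    (a flagged missing value) rather than an error.
    """
    if isinstance(modules, SpatialModules):
        D, ids = modules.D, modules.module_ids
    else:
        D = np.asarray(modules, dtype=float)
        ids = [f"M{k:03d}" for k in range(D.shape[1])]
    y = np.asarray(y, dtype=float)
    if D.shape[0] != y.shape[0]:
        raise ValidationError("modules and projection must share the area axis")
    out: dict[str, float] = {}
    for k, mid in enumerate(ids):
        col = D[:, k]
        if np.ptp(col) == 0 or np.ptp(y) == 0:
            out[mid] = float("nan")
        else:
            out[mid] = pearson_r(col, y).r
    return out


def predict_from_top_modules(
    modules: Union[SpatialModules, np.ndarray],
    y: np.ndarray,
    k: int = 3,
    n_folds: int = 3,
    seed: int = 0,
) -> tuple[float, float, list[str]]:
    """Out-of-fold OLS prediction of a pattern from its top-k modules.

    Modules are ranked by |Pearson r| with the pattern (NaN-correlated,
    i.e. constant, modules excluded; ties broken by module index).  The
    pattern is then predicted out-of-fold under a k-fold split of areas by
    ordinary least squares on the selected module columns.

    Returns ``(r2, pearson_r, selected_module_ids)`` where both scores
    compare the measured pattern with the concatenated out-of-fold
    prediction.
    """
    if isinstance(modules, SpatialModules):
        D, ids = modules.D, modules.module_ids
    else:
        D = np.asarray(modules, dtype=float)
        ids = [f"M{i:03d}" for i in range(D.shape[1])]
    y = np.asarray(y, dtype=float)
    if k < 1 or k > D.shape[1]:
        raise ConfigError(f"k={k} must lie in [1, {D.shape[1]}]")
    corr = correlate_modules(D, y)
    order = sorted(
        range(len(ids)),
        key=lambda i: (-abs(corr[ids[i]]) if np.isfinite(corr[ids[i]]) else np.inf, i),
    )
    usable = [i for i in order if np.isfinite(corr[ids[i]])]
    if len(usable) < k:
        raise ConfigError("fewer than k non-constant modules available")
    sel = sorted(usable[:k])
    X = D[:, sel]

    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
    oof = np.empty_like(y)
    for tr, te in cv.split(np.arange(y.size)):
        model = LinearRegression()
        model.fit(X[tr], y[tr])
        oof[te] = model.predict(X[te])
    r2 = r2_score(y, oof)
    r = pearson_r(y, oof).r if np.ptp(oof) > 0 else float("nan")
    return r2, r, [ids[i] for i in sel]


def footprint_code(
    modules_top3: np.ndarray, y: np.ndarray, presence_eps: float = 1e-6
) -> np.ndarray:
    """Six-level overlap code between a pattern and its three top modules.

    ``modules_top3`` is an areas x 3 grid of module footprints and ``y``
    the projection pattern, both on the raw non-negative scale where a
    value above ``presence_eps`` counts as present.
    """
    M = np.asarray(modules_top3, dtype=float)
    y = np.asarray(y, dtype=float)
    if M.ndim != 2 or M.shape[1] != 3:
        raise ValidationError("footprint coding is defined for exactly 3 modules")
    if M.shape[0] != y.shape[0]:
        raise ValidationError("modules and pattern must share the area axis")
    n_present = (M > presence_eps).sum(axis=1)
    in_pattern = y > presence_eps
    code = np.zeros(y.shape[0])
    code[in_pattern & (n_present == 3)] = 1.0
    code[in_pattern & (n_present == 2)] = 0.8
    code[in_pattern & (n_present == 1)] = 0.6
    code[in_pattern & (n_present == 0)] = 0.4
    code[~in_pattern & (n_present >= 1)] = 0.2
    return code
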