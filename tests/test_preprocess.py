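"""Filtering, imputation and rescaling."""

import numpy as np
import pytest
from scipy import stats

from mesoconn.datamodel import (
    ExpressionMatrix,
    InjectionMetadata,
    ProjectionMatrix,
    assemble_dataset,
)
from mesoconn.exceptions import EmptyDatasetError, ImputationError, ValidationError
from mesoconn.preprocess import (
    filter_areas,
    impute_expression,
    impute_projections,
    inverse_rescale,
    preprocess_dataset,
    rescale,
)


def _dataset(expr_vals, proj_vals):
    n = len(expr_vals)
    areas = [f"A{i}" for i in range(n)]
    expr = ExpressionMatrix(
        area_ids=areas,
        gene_ids=[f"g{j}" for j in range(len(expr_vals[0]))],
        values=np.asarray(expr_vals, float),
    )
    proj = ProjectionMatrix(
        area_ids=areas,
        injection_ids=[f"i{j}" for j in range(len(proj_vals[0]))],
        values=np.asarray(proj_vals, float),
        category="wt",
    )
    meta = [
        InjectionMetadata(f"i{j}", "A0", "wt", "wild-type", "mixed")
        for j in range(len(proj_vals[0]))
    ]
    return assemble_dataset(expr, [proj], meta)


NAN = np.nan


class TestFilterAreas:
    def test_high_nan_expression_area_removed(self):
        # area A1: 90 % NaN in expression, fully observed in projections
        expr = np.ones((3, 10))
        expr[1, :9] = NAN
        ds = _dataset(expr, np.ones((3, 2)))
        filtered, removed = filter_areas(ds, max_nan_frac=0.8)
        assert removed == ["A1"]
        assert filtered.area_ids == ["A0", "A2"]

    def test_boundary_is_strict(self):
        expr = np.ones((2, 5))
        expr[0, :4] = NAN  # exactly 80 %
        ds = _dataset(expr, np.ones((2, 2)))
        _, removed = filter_areas(ds, max_nan_frac=0.8)
        assert removed == []

    def test_planted_fractions_remove_exactly_one(self):
        expr = np.ones((3, 10))
        expr[0, :9] = NAN  # 0.9
        expr[1, :5] = NAN  # 0.5
        ds = _dataset(expr, np.ones((3, 2)))
        _, removed = filter_areas(ds, max_nan_frac=0.8)
        assert removed == ["A0"]

    def test_projection_nans_also_count(self):
        proj = np.ones((3, 10))
        proj[2, :] = NAN
        ds = _dataset(np.ones((3, 4)), proj)
        _, removed = filter_areas(ds, max_nan_frac=0.8)
        assert removed == ["A2"]

    def test_all_removed_is_error(self):
        expr = np.full((2, 4), NAN)
        expr[:, 0] = 1.0  # keep columns imputable but areas 75% NaN
        ds = _dataset(expr, np.ones((2, 2)))
        with pytest.raises(EmptyDatasetError):
            filter_areas(ds, max_nan_frac=0.5)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        expr = np.ones((20, 30))
        expr[rng.random(expr.shape) < 0.5] = NAN
        ds = _dataset(expr, np.ones((20, 3)))
        removed_sets = []
        for thr in (0.2, 0.5, 0.8):
            try:
                _, removed = filter_areas(ds, max_nan_frac=thr)
            except EmptyDatasetError:
                removed = ds.area_ids
            removed_sets.append(set(removed))
        assert removed_sets[0] >= removed_sets[1] >= removed_sets[2]


class TestImputeExpression:
    def _expr(self, col):
        return ExpressionMatrix(
            area_ids=[f"A{i}" for i in range(len(col))],
            gene_ids=["g0"],
            values=np.asarray(col, float).reshape(-1, 1),
        )

    @pytest.mark.parametrize(
        "col,expected",
        [
            ([1, NAN, 3], [1, 2, 3]),
            ([1, 2, 3], [1, 2, 3]),
            ([0, 0, 5, NAN, 7], [0, 0, 5, 2.5, 7]),
        ],
    )
    def test_median_imputation(self, col, expected):
        out = impute_expression(self._expr(col))
        np.testing.assert_allclose(out.values[:, 0], expected)

    def test_all_nan_column_is_error(self):
        with pytest.raises(ImputationError):
            impute_expression(self._expr([NAN, NAN]))


class TestImputeProjections:
    def _proj(self, col):
        return ProjectionMatrix(
            area_ids=[f"A{i}" for i in range(len(col))],
            injection_ids=["i0"],
            values=np.asarray(col, float).reshape(-1, 1),
            category="wt",
        )

    def test_all_zero_column_imputes_zero(self):
        out = impute_projections(self._proj([0, 0, NAN, NAN]), seed=0)
        np.testing.assert_array_equal(out.values[:, 0], [0, 0, 0, 0])

    def test_single_value_group(self):
        out = impute_projections(self._proj([5, 5, NAN]), seed=0)
        assert out.values[2, 0] == 5.0

    def test_observed_values_untouched_and_draws_from_observed(self):
        col = [0.0, 0.0, 1.5, 2.5, NAN, NAN, NAN]
        out = impute_projections(self._proj(col), seed=3)
        np.testing.assert_array_equal(out.values[:4, 0], col[:4])
        assert set(out.values[4:, 0]) <= {0.0, 1.5, 2.5}

    def test_zero_fraction_reproduced(self):
        # 30 zeros / 70 non-zeros observed; 10_000 imputations
        observed = [0.0] * 30 + list(np.linspace(1, 2, 70))
        col = observed + [NAN] * 10_000
        out = impute_projections(self._proj(col), seed=5)
        n_zero = int((out.values[100:, 0] == 0).sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], 10_000, 0.3)
        assert lo <= n_zero <= hi

    def test_deterministic_under_seed(self):
        proj = self._proj([0, 1, 2, NAN, NAN])
        a = impute_projections(proj, seed=9)
        b = impute_projections(proj, seed=9)
        np.testing.assert_array_equal(a.values, b.values)


class TestRescale:
    def _expr(self, vals):
        vals = np.asarray(vals, float)
        return ExpressionMatrix(
            area_ids=[f"A{i}" for i in range(vals.shape[0])],
            gene_ids=[f"g{j}" for j in range(vals.shape[1])],
            values=vals,
        )

    def test_hand_case_cube_root_then_zscore(self):
        out = rescale(self._expr([[0.0], [1.0], [8.0]]))
        np.testing.assert_allclose(out.values[:, 0], [-1.224745, 0.0, 1.224745], atol=1e-6)

    def test_constant_column_maps_to_zeros(self):
        out = rescale(self._expr([[2.0], [2.0], [2.0]]))
        np.testing.assert_array_equal(out.values[:, 0], [0, 0, 0])

    def test_columns_standardized(self):
        rng = np.random.default_rng(1)
        out = rescale(self._expr(rng.gamma(2.0, 1.0, (50, 8))))
        np.testing.assert_allclose(out.values.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(out.values.std(axis=0), 1, atol=1e-10)
        assert out.rescaled

    def test_nan_input_rejected(self):
        with pytest.raises(ValidationError):
            rescale(self._expr([[1.0], [NAN]]))

    def test_commutes_with_column_permutation(self):
        rng = np.random.default_rng(2)
        vals = rng.gamma(2.0, 1.0, (20, 6))
        perm = rng.permutation(6)
        a = rescale(self._expr(vals)).values[:, perm]
        b = rescale(self._expr(vals[:, perm])).values
        np.testing.assert_allclose(a, b)

    def test_inverse_rescale_recovers_raw(self):
        rng = np.random.default_rng(3)
        vals = rng.gamma(2.0, 1.0, (30, 5))
        out = rescale(self._expr(vals))
        back = inverse_rescale(out.values, out.col_means, out.col_stds)
        np.testing.assert_allclose(back, vals, rtol=1e-8)


def test_preprocess_dataset_end_to_end(tiny_dataset):
    pre = preprocess_dataset(tiny_dataset, seed=0)
    assert not np.isnan(pre.raw.expression.values).any()
    assert pre.rescaled.expression.rescaled
    for proj in pre.rescaled.projections:
        assert proj.rescaled and proj.col_means is not None
    assert pre.report["n_expression_nans_imputed"] > 0
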