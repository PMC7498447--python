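"""Containers, TSV/JSON round-trips, and dataset assembly."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mesoconn.datamodel import (
    ExpressionMatrix,
    InjectionMetadata,
    ProjectionMatrix,
    assemble_dataset,
)
from mesoconn.exceptions import AssemblyError, FormatError, ValidationError
from mesoconn.io import load_dataset, read_matrix, save_dataset, write_matrix


def _expr(area_ids, gene_ids, values, **kw):
    return ExpressionMatrix(area_ids=area_ids, gene_ids=gene_ids, values=np.asarray(values, float), **kw)


class TestContainers:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            _expr(["A", "B"], ["g1"], [[1.0], [2.0], [3.0]])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError):
            _expr(["A", "A"], ["g1"], [[1.0], [2.0]])

    def test_negative_raw_values_rejected(self):
        with pytest.raises(ValidationError):
            _expr(["A", "B"], ["g1"], [[1.0], [-2.0]])

    def test_negative_allowed_when_rescaled(self):
        m = _expr(["A", "B"], ["g1"], [[1.0], [-2.0]], rescaled=True)
        assert m.values[1, 0] == -2.0

    def test_projection_requires_category(self):
        with pytest.raises(ValidationError):
            ProjectionMatrix(area_ids=["A"], injection_ids=["i1"], values=[[1.0]], category="")

    def test_unknown_cell_class_rejected(self):
        with pytest.raises(ValidationError):
            InjectionMetadata("i1", "A", "wt", "granule", "L4")


class TestReadWriteMatrix:
    def test_empty_cell_becomes_nan(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("area_id\tg1\tg2\nA\t1.0\t2.0\nB\t\t3.0\nC\t4.0\t5.0\n")
        m = read_matrix(str(path), "expression")
        assert m.shape == (3, 2)
        assert np.isnan(m.values).sum() == 1 and np.isnan(m.values[1, 0])

    def test_ragged_row_is_format_error(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("area_id\tg1\tg2\nA\t1.0\t2.0\t9.0\n")
        with pytest.raises(FormatError):
            read_matrix(str(path), "expression")

    def test_duplicate_column_ids_format_error(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("area_id\tg1\tg1\nA\t1.0\t2.0\n")
        with pytest.raises(FormatError):
            read_matrix(str(path), "expression")

    def test_negative_value_in_raw_mode_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("area_id\tg1\nA\t-1.0\n")
        with pytest.raises(ValidationError):
            read_matrix(str(path), "expression")
        assert read_matrix(str(path), "expression", rescaled=True).values[0, 0] == -1.0

    def test_empty_matrix_roundtrip(self, tmp_path):
        m = _expr([], [], np.empty((0, 0)))
        write_matrix(m, str(tmp_path / "m.tsv"))
        back = read_matrix(str(tmp_path / "m.tsv"), "expression")
        assert back.shape == (0, 0)

    def test_all_nan_column_preserved(self, tmp_path):
        m = _expr(["A", "B"], ["g1", "g2"], [[1.0, np.nan], [2.0, np.nan]])
        write_matrix(m, str(tmp_path / "m.tsv"))
        back = read_matrix(str(tmp_path / "m.tsv"), "expression")
        assert np.isnan(back.values[:, 1]).all()

    def test_large_roundtrip_bitexact(self, tmp_path):
        rng = np.random.default_rng(0)
        vals = rng.gamma(2.0, 1.0, size=(428, 200)) * 10.0 ** rng.integers(-8, 8, (428, 200))
        vals[rng.random(vals.shape) < 0.05] = np.nan
        m = _expr([f"A{i}" for i in range(428)], [f"g{j}" for j in range(200)], vals)
        write_matrix(m, str(tmp_path / "m.tsv"))
        back = read_matrix(str(tmp_path / "m.tsv"), "expression")
        np.testing.assert_array_equal(back.values, m.values)
        assert back.area_ids == m.area_ids and back.gene_ids == m.gene_ids

    @given(
        values=arrays(
            np.float64,
            (4, 3),
            elements=st.floats(
                min_value=0, max_value=1e12, allow_nan=False, width=64
            ),
        ),
        nan_cells=st.sets(st.integers(0, 11), max_size=6),
    )
    def test_roundtrip_property(self, values, nan_cells, tmp_path):
        vals = values.copy()
        for cell in nan_cells:
            vals[cell // 3, cell % 3] = np.nan
        m = _expr([f"A{i}" for i in range(4)], [f"g{j}" for j in range(3)], vals)
        path = tmp_path / "roundtrip.tsv"
        write_matrix(m, str(path))
        back = read_matrix(str(path), "expression")
        np.testing.assert_array_equal(back.values, vals)


class TestAssemble:
    def _meta(self, inj, cat="wt"):
        return InjectionMetadata(inj, "B", cat, "wild-type", "mixed")

    def test_area_intersection(self):
        expr = _expr(["A", "B", "C"], ["g1"], [[1.0], [2.0], [3.0]])
        proj = ProjectionMatrix(
            area_ids=["B", "C", "D"], injection_ids=["i1"], values=[[1.0], [2.0], [3.0]],
            category="wt",
        )
        ds = assemble_dataset(expr, [proj], [self._meta("i1")])
        assert ds.area_ids == ["B", "C"]
        assert ds.expression.values[:, 0].tolist() == [2.0, 3.0]
        assert ds.projections[0].values[:, 0].tolist() == [1.0, 2.0]

    def test_aligned_inputs_pass_through(self):
        expr = _expr(["A", "B"], ["g1"], [[1.0], [2.0]])
        proj = ProjectionMatrix(
            area_ids=["A", "B"], injection_ids=["i1"], values=[[1.0], [2.0]], category="wt"
        )
        ds = assemble_dataset(expr, [proj], [self._meta("i1")])
        np.testing.assert_array_equal(ds.expression.values, expr.values)

    def test_missing_metadata_rejected(self):
        expr = _expr(["A"], ["g1"], [[1.0]])
        proj = ProjectionMatrix(
            area_ids=["A"], injection_ids=["i1"], values=[[1.0]], category="wt"
        )
        with pytest.raises(AssemblyError):
            assemble_dataset(expr, [proj], [])

    def test_empty_intersection_rejected(self):
        expr = _expr(["A"], ["g1"], [[1.0]])
        proj = ProjectionMatrix(
            area_ids=["B"], injection_ids=["i1"], values=[[1.0]], category="wt"
        )
        with pytest.raises(AssemblyError):
            assemble_dataset(expr, [proj], [self._meta("i1")])

    def test_assembly_idempotent(self, tiny_dataset):
        again = assemble_dataset(
            tiny_dataset.expression, tiny_dataset.projections, tiny_dataset.metadata
        )
        assert again.area_ids == tiny_dataset.area_ids
        np.testing.assert_array_equal(
            again.expression.values, tiny_dataset.expression.values
        )
        for p1, p2 in zip(again.projections, tiny_dataset.projections):
            np.testing.assert_array_equal(p1.values, p2.values)


def test_dataset_bundle_roundtrip(tmp_path, tiny_dataset):
    save_dataset(tiny_dataset, str(tmp_path / "ds"))
    back = load_dataset(str(tmp_path / "ds"))
    assert back.area_ids == tiny_dataset.area_ids
    np.testing.assert_array_equal(back.expression.values, tiny_dataset.expression.values)
    assert back.categories == tiny_dataset.categories
    assert {m.injection_id for m in back.metadata} == {
        m.injection_id for m in tiny_dataset.metadata
    }
    assert back.annotations is not None
    assert set(back.annotations.term_ids()) == set(tiny_dataset.annotations.term_ids())
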