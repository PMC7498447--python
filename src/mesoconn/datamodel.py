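"""Core data containers shared by every stage of the workflow.

The two measured modalities are kept as thin, validated wrappers around a
2-D float array with explicit row (brain area) and column (gene or
injection) identifiers:

* :class:`ExpressionMatrix` — unionized *expression energy* per (area, gene):
  the summed in-situ-hybridization intensity of an area divided by the
  number of pixels in that area.  Non-negative by construction until the
  cube-root / z-score rescale is applied, after which ``rescaled`` is set
  and values are real-valued z-scores.
* :class:`ProjectionMatrix` — unionized *normalized projection volume* per
  (area, injection) for one tract-tracing category: detected projection
  pixels in a target area divided by the area's pixel count, normalized by
  injection size.  Exact zeros are meaningful (no detected projection).

Both carry NaNs for areas where the upstream unionization produced no
value; preprocessing removes or imputes them.

:func:`assemble_dataset` reconciles all matrices onto a single shared,
lexicographically ordered brain-area axis and attaches injection metadata,
so every downstream operation can rely on aligned rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .exceptions import AssemblyError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "ProjectionMatrix",
    "InjectionMetadata",
    "AnnotationTerm",
    "AnnotationTable",
    "CellTypeSignatures",
    "Dataset",
    "assemble_dataset",
]

CELL_CLASSES = ("IT", "PT", "CT", "wild-type")


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate {what} ids: {dupes[:5]}")
    return ids


def _check_grid(values, n_rows: int, n_cols: int, rescaled: bool, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape != (n_rows, n_cols):
        raise ValidationError(
            f"{what}: values shape {values.shape} does not match id lists "
            f"({n_rows} rows x {n_cols} cols)"
        )
    if not rescaled and np.any(values[np.isfinite(values)] < 0):
        raise ValidationError(f"{what}: negative values in raw (non-rescaled) matrix")
    return values


@dataclass
class ExpressionMatrix:
    """Areas x genes grid of expression energies (or z-scores once rescaled)."""

    area_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    rescaled: bool = False
    #: per-column mean/std of the cube-root values, kept after :func:`rescale`
    #: so predictions can be mapped back to the raw scale; None until then.
    col_means: Optional[np.ndarray] = None
    col_stds: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.area_ids = _check_ids(self.area_ids, "area")
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.values = _check_grid(
            self.values, len(self.area_ids), len(self.gene_ids), self.rescaled, "expression"
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def take_areas(self, indices: Sequence[int]) -> "ExpressionMatrix":
        """Return a copy restricted to the given area row indices (in order)."""
        return replace(
            self,
            area_ids=[self.area_ids[i] for i in indices],
            values=self.values[np.asarray(indices, dtype=int), :].copy(),
        )


@dataclass
class ProjectionMatrix:
    """Areas x injections grid of normalized projection volumes for one category."""

    area_ids: list[str]
    injection_ids: list[str]
    values: np.ndarray
    category: str = ""
    rescaled: bool = False
    col_means: Optional[np.ndarray] = None
    col_stds: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not self.category:
            raise ValidationError("projection matrix requires a non-empty category label")
        self.area_ids = _check_ids(self.area_ids, "area")
        self.injection_ids = _check_ids(self.injection_ids, "injection")
        self.values = _check_grid(
            self.values,
            len(self.area_ids),
            len(self.injection_ids),
            self.rescaled,
            f"projection[{self.category}]",
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def take_areas(self, indices: Sequence[int]) -> "ProjectionMatrix":
        return replace(
            self,
            area_ids=[self.area_ids[i] for i in indices],
            values=self.values[np.asarray(indices, dtype=int), :].copy(),
        )


@dataclass(frozen=True)
class InjectionMetadata:
    """Descriptors of a single tracer injection.

    ``cell_class`` is one of IT / PT / CT for cre-line experiments (the
    excitatory projection classes labeled by the line) or "wild-type" for
    pan-neuronal experiments.  ``layer_profile`` is the dominant cortical
    layer of labeled somata (e.g. "L2/3", "L5", or "mixed").  Injection
    coordinates, when known, travel as opaque optional metadata.
    """

    injection_id: str
    source_area: str
    category: str
    cell_class: str
    layer_profile: str
    coordinates: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.cell_class not in CELL_CLASSES:
            raise ValidationError(
                f"unknown cell class {self.cell_class!r}; expected one of {CELL_CLASSES}"
            )


@dataclass(frozen=True)
class AnnotationTerm:
    term_id: str
    term_name: str
    gene_set: frozenset[str]


@dataclass
class AnnotationTable:
    """Annotation terms (gene sets) plus the background gene universe."""

    terms: list[AnnotationTerm]
    background: frozenset[str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for term in self.terms:
            if term.term_id in seen:
                raise ValidationError(f"duplicate annotation term id {term.term_id!r}")
            seen.add(term.term_id)
            stray = term.gene_set - self.background
            if stray:
                raise ValidationError(
                    f"term {term.term_id!r} contains genes outside the background: "
                    f"{sorted(stray)[:5]}"
                )

    def term_ids(self) -> list[str]:
        return [t.term_id for t in self.terms]

    def gene_set(self, term_id: str) -> frozenset[str]:
        for t in self.terms:
            if t.term_id == term_id:
                return t.gene_set
        raise KeyError(term_id)


@dataclass
class CellTypeSignatures:
    """Cell-types x genes non-negative expression signatures (constrained loadings)."""

    celltype_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.celltype_ids = _check_ids(self.celltype_ids, "celltype")
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.values = _check_grid(
            self.values, len(self.celltype_ids), len(self.gene_ids), False, "signatures"
        )


@dataclass
class Dataset:
    """One aggregate structure: expression + per-category projections + metadata."""

    expression: ExpressionMatrix
    projections: list[ProjectionMatrix]
    metadata: list[InjectionMetadata]
    annotations: Optional[AnnotationTable] = None
    celltype_signatures: Optional[CellTypeSignatures] = None

    @property
    def area_ids(self) -> list[str]:
        return self.expression.area_ids

    @property
    def categories(self) -> list[str]:
        return [p.category for p in self.projections]

    def projection(self, category: str) -> ProjectionMatrix:
        for p in self.projections:
            if p.category == category:
                return p
        raise KeyError(category)

    def metadata_by_id(self) -> dict[str, InjectionMetadata]:
        return {m.injection_id: m for m in self.metadata}

    @property
    def n_injections(self) -> int:
        return sum(len(p.injection_ids) for p in self.projections)


def assemble_dataset(
    expression: ExpressionMatrix,
    projections: Sequence[ProjectionMatrix],
    metadata: Sequence[InjectionMetadata],
    annotations: Optional[AnnotationTable] = None,
    celltype_signatures: Optional[CellTypeSignatures] = None,
) -> Dataset:
    """Reconcile all matrices onto a shared area axis and attach metadata.

    The area axis of the result is the *intersection* of the area sets of the
    expression matrix and every projection matrix, ordered lexicographically
    by acronym so assembly is deterministic regardless of input ordering.

    Raises
    ------
    AssemblyError
        If the area intersection is empty, an injection has no metadata
        record, or a metadata record disagrees with its matrix's category.
    """
    projections = list(projections)
    common = set(expression.area_ids)
    for proj in projections:
        common &= set(proj.area_ids)
    if not common:
        raise AssemblyError("empty intersection of area ids across matrices")
    order = sorted(common)

    def _reindex_expr(m: ExpressionMatrix) -> ExpressionMatrix:
        idx = {a: i for i, a in enumerate(m.area_ids)}
        return m.take_areas([idx[a] for a in order])

    def _reindex_proj(m: ProjectionMatrix) -> ProjectionMatrix:
        idx = {a: i for i, a in enumerate(m.area_ids)}
        return m.take_areas([idx[a] for a in order])

    meta_by_id = {m.injection_id: m for m in metadata}
    if len(meta_by_id) != len(metadata):
        raise AssemblyError("duplicate injection_id in metadata")
    for proj in projections:
        for inj in proj.injection_ids:
            rec = meta_by_id.get(inj)
            if rec is None:
                raise AssemblyError(f"injection {inj!r} has no metadata record")
            if rec.category != proj.category:
                raise AssemblyError(
                    f"injection {inj!r}: metadata category {rec.category!r} "
                    f"!= matrix category {proj.category!r}"
                )

    return Dataset(
        expression=_reindex_expr(expression),
        projections=[_reindex_proj(p) for p in projections],
        metadata=list(metadata),
        annotations=annotations,
        celltype_signatures=celltype_signatures,
    )
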