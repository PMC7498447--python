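"""Readers and writers for the on-disk formats.

Matrices are tab-separated text with one header row of column ids and one
leading column of area ids; empty cells, ``NaN`` and ``nan`` denote missing
values.  Floats are written with 17 significant digits so a write/read
roundtrip is bit-exact.  Injection metadata is a JSON array of records;
annotations are a two-column TSV of (term_id, gene_id) pairs plus an
optional term-name map in JSON.
"""

from __future__ import annotations

import json
import os
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .datamodel import (
    AnnotationTable,
    AnnotationTerm,
    CellTypeSignatures,
    ExpressionMatrix,
    InjectionMetadata,
    ProjectionMatrix,
)
from .exceptions import FormatError

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_metadata",
    "write_metadata",
    "read_annotations",
    "write_annotations",
    "save_dataset",
    "load_dataset",
]

NAN_TOKENS = ("", "NaN", "nan")
_FLOAT_FMT = "%.17g"

Matrix = Union[ExpressionMatrix, ProjectionMatrix]


def _check_rectangular(path: str) -> None:
    """Raise FormatError when any data row disagrees with the header width."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise FormatError(f"{path}: empty file")
        width = header.rstrip("\n").count("\t")
        for lineno, line in enumerate(fh, start=2):
            if line.rstrip("\n").count("\t") != width:
                raise FormatError(
                    f"{path}:{lineno}: row has a different number of cells than the header"
                )


def _parse_table(path: str) -> pd.DataFrame:
    _check_rectangular(path)
    with open(path, "r", encoding="utf-8") as fh:
        header_cols = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header_cols)) != len(header_cols):
        # checked on the raw tokens: pandas would silently mangle duplicates
        raise FormatError(f"{path}: duplicate column ids")
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            na_values=list(NAN_TOKENS),
            keep_default_na=False,
            dtype=str,
        )
    except Exception as exc:  # pandas raises several parser error types
        raise FormatError(f"{path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell: {exc}") from exc
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate row ids")
    if df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate column ids")
    return df


def read_matrix(
    path: str,
    kind: str,
    category: Optional[str] = None,
    rescaled: bool = False,
) -> Matrix:
    """Parse a TSV matrix file into an Expression- or ProjectionMatrix.

    Parameters
    ----------
    kind:
        ``"expression"`` or ``"projection"``.
    category:
        Tracing-category label, required for projections.
    rescaled:
        Assert that the file holds z-scored values; suspends the
        non-negativity check.
    """
    df = _parse_table(path)
    if kind == "expression":
        return ExpressionMatrix(
            area_ids=list(df.index),
            gene_ids=list(df.columns),
            values=df.to_numpy(dtype=float),
            rescaled=rescaled,
        )
    if kind == "projection":
        if not category:
            raise ValueError("category is required for kind='projection'")
        return ProjectionMatrix(
            area_ids=list(df.index),
            injection_ids=list(df.columns),
            values=df.to_numpy(dtype=float),
            category=category,
            rescaled=rescaled,
        )
    raise ValueError(f"unknown matrix kind {kind!r}")


def read_signatures(path: str) -> CellTypeSignatures:
    """Parse a cell-types x genes signature TSV (rows are cell types)."""
    df = _parse_table(path)
    return CellTypeSignatures(
        celltype_ids=list(df.index),
        gene_ids=list(df.columns),
        values=df.to_numpy(dtype=float),
    )


def write_matrix(matrix, path: str) -> None:
    """Write a matrix (or CellTypeSignatures) to TSV, re-readable bit-exactly."""
    if isinstance(matrix, ExpressionMatrix):
        cols, index_label = matrix.gene_ids, "area_id"
        rows = matrix.area_ids
    elif isinstance(matrix, ProjectionMatrix):
        cols, index_label = matrix.injection_ids, "area_id"
        rows = matrix.area_ids
    elif isinstance(matrix, CellTypeSignatures):
        cols, index_label = matrix.gene_ids, "celltype_id"
        rows = matrix.celltype_ids
    else:
        raise TypeError(f"cannot write object of type {type(matrix).__name__}")
    df = pd.DataFrame(matrix.values, index=rows, columns=cols)
    df.to_csv(path, sep="\t", na_rep="NaN", float_format=_FLOAT_FMT, index_label=index_label)


def write_metadata(metadata: Sequence[InjectionMetadata], path: str) -> None:
    records = []
    for m in metadata:
        rec = {
            "injection_id": m.injection_id,
            "source_area": m.source_area,
            "category": m.category,
            "cell_class": m.cell_class,
            "layer_profile": m.layer_profile,
        }
        if m.coordinates is not None:
            rec["coordinates"] = list(m.coordinates)
        records.append(rec)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(records, fh, indent=1)


def read_metadata(path: str) -> list[InjectionMetadata]:
    with open(path, "r", encoding="utf-8") as fh:
        records = json.load(fh)
    if not isinstance(records, list):
        raise FormatError(f"{path}: expected a JSON array of records")
    out = []
    for rec in records:
        coords = rec.get("coordinates")
        out.append(
            InjectionMetadata(
                injection_id=rec["injection_id"],
                source_area=rec["source_area"],
                category=rec["category"],
                cell_class=rec["cell_class"],
                layer_profile=rec["layer_profile"],
                coordinates=tuple(coords) if coords is not None else None,
            )
        )
    return out


def write_annotations(table: AnnotationTable, pairs_path: str, names_path: Optional[str] = None) -> None:
    """Write term membership as (term_id, gene_id) TSV pairs.

    Background genes that belong to no term are written as a pair with an
    empty gene column suppressed — instead the full background is stored in
    the names JSON so the universe survives a roundtrip.
    """
    with open(pairs_path, "w", encoding="utf-8") as fh:
        fh.write("term_id\tgene_id\n")
        for term in table.terms:
            for gene in sorted(term.gene_set):
                fh.write(f"{term.term_id}\t{gene}\n")
    if names_path is not None:
        payload = {
            "term_names": {t.term_id: t.term_name for t in table.terms},
            "background": sorted(table.background),
        }
        with open(names_path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def read_annotations(
    pairs_path: str,
    names_path: Optional[str] = None,
    background: Optional[Sequence[str]] = None,
) -> AnnotationTable:
    """Read (term_id, gene_id) pairs back into an AnnotationTable.

    The background defaults to whatever the names JSON recorded, falling
    back to the union of all term gene sets.
    """
    pairs = pd.read_csv(pairs_path, sep="\t", dtype=str)
    if list(pairs.columns) != ["term_id", "gene_id"]:
        raise FormatError(f"{pairs_path}: expected columns term_id, gene_id")
    names: dict[str, str] = {}
    bg: Optional[set[str]] = set(map(str, background)) if background is not None else None
    if names_path is not None and os.path.exists(names_path):
        with open(names_path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        names = payload.get("term_names", {})
        if bg is None and "background" in payload:
            bg = set(payload["background"])
    grouped = pairs.groupby("term_id", sort=True)["gene_id"].apply(set)
    if bg is None:
        bg = set(pairs["gene_id"])
    terms = [
        AnnotationTerm(term_id=tid, term_name=names.get(tid, tid), gene_set=frozenset(genes))
        for tid, genes in grouped.items()
    ]
    return AnnotationTable(terms=terms, background=frozenset(bg))


# ---------------------------------------------------------------------------
# Directory-level bundles (the CLI's on-disk dataset layout)

def _safe(name: str) -> str:
    return "".join(c if c.isalnum() or c in "-_." else "_" for c in name)


def save_dataset(dataset, out_dir: str) -> None:
    """Write a Dataset as the CLI's directory bundle of TSV/JSON files."""
    from .datamodel import Dataset  # local to avoid import-time cycles

    assert isinstance(dataset, Dataset)
    os.makedirs(out_dir, exist_ok=True)
    write_matrix(dataset.expression, os.path.join(out_dir, "expression.tsv"))
    categories = {}
    for proj in dataset.projections:
        fname = f"projection_{_safe(proj.category)}.tsv"
        categories[proj.category] = fname
        write_matrix(proj, os.path.join(out_dir, fname))
    write_metadata(dataset.metadata, os.path.join(out_dir, "metadata.json"))
    manifest = {
        "categories": categories,
        "rescaled": dataset.expression.rescaled,
        "has_annotations": dataset.annotations is not None,
    }
    if dataset.annotations is not None:
        write_annotations(
            dataset.annotations,
            os.path.join(out_dir, "annotations.tsv"),
            os.path.join(out_dir, "annotation_names.json"),
        )
    if dataset.celltype_signatures is not None:
        write_matrix(
            dataset.celltype_signatures, os.path.join(out_dir, "celltype_signatures.tsv")
        )
        manifest["has_signatures"] = True
    with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)


def load_dataset(in_dir: str):
    """Read a Dataset bundle written by :func:`save_dataset` and assemble it."""
    from .datamodel import assemble_dataset

    with open(os.path.join(in_dir, "manifest.json"), "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    rescaled = bool(manifest.get("rescaled", False))
    expression = read_matrix(
        os.path.join(in_dir, "expression.tsv"), "expression", rescaled=rescaled
    )
    projections = [
        read_matrix(os.path.join(in_dir, fname), "projection", category=cat, rescaled=rescaled)
        for cat, fname in manifest["categories"].items()
    ]
    metadata = read_metadata(os.path.join(in_dir, "metadata.json"))
    annotations = None
    if manifest.get("has_annotations"):
        annotations = read_annotations(
            os.path.join(in_dir, "annotations.tsv"),
            os.path.join(in_dir, "annotation_names.json"),
        )
    signatures = None
    if manifest.get("has_signatures"):
        signatures = read_signatures(os.path.join(in_dir, "celltype_signatures.tsv"))
    return assemble_dataset(
        expression, projections, metadata, annotations=annotations,
        celltype_signatures=signatures,
    )
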