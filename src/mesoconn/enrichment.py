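"""Hypergeometric enrichment of predictive and module gene sets.

Two kinds of query gene sets are tested against an annotation table:

* per injection, the *most predictive* genes — those whose absolute model
  coefficient strictly exceeds the 99th percentile of the absolute
  coefficient distribution;
* per spatial module, all genes with a non-zero loading.

Each (query, term) pair gets an exact upper-tail hypergeometric p-value —
the probability of drawing at least the observed overlap when sampling
``query_size`` genes without replacement from a background of
``background_size`` genes of which ``term_size`` belong to the term.
Significance is declared at p <= alpha (default 0.05) without multiple-
testing correction; Benjamini-Hochberg adjustment is available as an
option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Union

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import AnnotationTable
from .dlsc import GeneLoadings
from .exceptions import ValidationError

__all__ = [
    "EnrichmentResult",
    "top_model_genes",
    "module_gene_set",
    "hypergeom_p",
    "enrich",
    "n_significant",
]


@dataclass
class EnrichmentResult:
    query_id: str
    term_id: str
    overlap: int
    query_size: int
    term_size: int
    background_size: int
    p_value: float
    significant: bool


def top_model_genes(
    coefficients: Union[Mapping[str, float], "np.ndarray"],
    gene_ids: Iterable[str] = None,
    percentile: float = 99.0,
    absolute: bool = True,
) -> set[str]:
    """Genes whose |coefficient| strictly exceeds the given percentile.

    Ridge coefficients are signed; "most predictive" is read as magnitude,
    so the percentile is taken over absolute values by default (set
    ``absolute=False`` to rank signed values instead).
    """
    if isinstance(coefficients, Mapping):
        genes = list(coefficients)
        values = np.asarray([coefficients[g] for g in genes], dtype=float)
    else:
        values = np.asarray(coefficients, dtype=float)
        if gene_ids is None:
            raise ValidationError("gene_ids required when coefficients is an array")
        genes = list(gene_ids)
        if len(genes) != values.size:
            raise ValidationError("gene_ids and coefficients disagree in length")
    if values.size == 0:
        raise ValidationError("empty coefficient vector")
    ranked = np.abs(values) if absolute else values
    if not np.any(ranked != 0):
        warnings.warn("all coefficients are zero; returning an empty gene set")
        return set()
    threshold = np.percentile(ranked, percentile)
    return {g for g, v in zip(genes, ranked) if v > threshold}


def module_gene_set(loadings: GeneLoadings, module_id: str, tol: float = 1e-12) -> set[str]:
    """All genes with loading above ``tol`` in the module's row."""
    try:
        k = loadings.module_ids.index(module_id)
    except ValueError:
        raise KeyError(f"unknown module {module_id!r}") from None
    row = loadings.a[k]
    return {g for g, v in zip(loadings.gene_ids, row) if v > tol}


def hypergeom_p(overlap: int, query_size: int, term_size: int, background_size: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= overlap)."""
    if not (0 <= overlap <= min(query_size, term_size)):
        raise ValidationError(
            f"overlap {overlap} inconsistent with query {query_size} / term {term_size}"
        )
    if max(query_size, term_size) > background_size:
        raise ValidationError("query/term size cannot exceed the background")
    return float(stats.hypergeom.sf(overlap - 1, background_size, term_size, query_size))


def enrich(
    query: Iterable[str],
    annotations: AnnotationTable,
    alpha: float = 0.05,
    query_id: str = "query",
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """Test one query gene set against every annotation term.

    Query genes outside the background are dropped with a warning.  One
    result per term, sorted by p-value; ``significant`` marks p <= alpha
    (after Benjamini-Hochberg adjustment when ``bh_correct``).
    """
    if not annotations.background:
        raise ValidationError("annotation background is empty")
    query = set(query)
    stray = query - annotations.background
    if stray:
        warnings.warn(f"dropping {len(stray)} query genes outside the background")
        query &= annotations.background
    bg = len(annotations.background)
    results = []
    for term in annotations.terms:
        overlap = len(query & term.gene_set)
        p = hypergeom_p(overlap, len(query), len(term.gene_set), bg)
        results.append(
            EnrichmentResult(
                query_id=query_id,
                term_id=term.term_id,
                overlap=overlap,
                query_size=len(query),
                term_size=len(term.gene_set),
                background_size=bg,
                p_value=p,
                significant=False,
            )
        )
    pvals = np.array([r.p_value for r in results])
    if bh_correct and len(results):
        reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        for r, rej in zip(results, reject):
            r.significant = bool(rej)
    else:
        for r in results:
            r.significant = bool(r.p_value <= alpha)
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def n_significant(results: Iterable[EnrichmentResult]) -> int:
    """How many terms a query was significantly associated with."""
    return sum(1 for r in results if r.significant)
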