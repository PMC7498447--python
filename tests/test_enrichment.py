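"""Hypergeometric enrichment: exactness, calibration, planted sensitivity."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from mesoconn.datamodel import AnnotationTable, AnnotationTerm
from mesoconn.dlsc import GeneLoadings
from mesoconn.enrichment import (
    enrich,
    hypergeom_p,
    module_gene_set,
    n_significant,
    top_model_genes,
)
from mesoconn.exceptions import ValidationError
from mesoconn.synthetic import generate_annotations, generate_ground_truth


class TestTopModelGenes:
    def test_single_dominant_coefficient(self):
        coefs = {f"g{i}": 0.01 for i in range(99)}
        coefs["gBig"] = 50.0
        assert top_model_genes(coefs) == {"gBig"}

    def test_percentile_zero_keeps_all_nonzero(self):
        coefs = {"g0": 0.0, "g1": -2.0, "g2": 1.0}
        assert top_model_genes(coefs, percentile=0) == {"g1", "g2"}

    def test_order_statistics_count(self):
        rng = np.random.default_rng(0)
        coefs = dict(zip((f"g{i}" for i in range(1000)), rng.normal(size=1000)))
        n = len(top_model_genes(coefs, percentile=99))
        assert 4 <= n <= 16  # ~10 expected, binomial slack

    def test_all_zero_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert top_model_genes({"g0": 0.0, "g1": 0.0}) == set()


class TestModuleGeneSet:
    def _loadings(self, rows):
        rows = np.asarray(rows, float)
        return GeneLoadings(
            module_ids=[f"M{k}" for k in range(rows.shape[0])],
            gene_ids=[f"g{j}" for j in range(rows.shape[1])],
            a=rows,
        )

    def test_zero_row_gives_empty_set(self):
        assert module_gene_set(self._loadings([[0.0, 0.0]]), "M0") == set()

    def test_sparse_row_counts_positives(self):
        rng = np.random.default_rng(1)
        row = np.zeros(100)
        row[rng.choice(100, 50, replace=False)] = 1.0
        assert len(module_gene_set(self._loadings([row]), "M0")) == 50

    def test_tolerance_boundary_excluded(self):
        assert module_gene_set(self._loadings([[1e-12, 1e-11]]), "M0") == {"g1"}

    def test_unknown_module_rejected(self):
        with pytest.raises(KeyError):
            module_gene_set(self._loadings([[1.0]]), "M9")


class TestHypergeomP:
    def test_zero_overlap_is_certain(self):
        assert hypergeom_p(0, 5, 5, 20) == 1.0

    def test_hand_combinatorial_case(self):
        # C(5,3)/C(10,3) = 10/120
        assert hypergeom_p(3, 3, 5, 10) == pytest.approx(10 / 120, abs=1e-12)

    def test_full_universe_overlap_forced(self):
        assert hypergeom_p(4, 4, 4, 4) == 1.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_p(5, 3, 5, 10)
        with pytest.raises(ValidationError):
            hypergeom_p(1, 3, 20, 10)

    def test_matches_exact_combinatorics_for_small_backgrounds(self):
        """Upper-tail probability agrees with an exact integer-arithmetic
        oracle for every configuration with background <= 15."""
        for M in range(1, 16):
            for n_term in range(0, M + 1):
                for n_query in range(0, M + 1):
                    for k in range(0, min(n_term, n_query) + 1):
                        exact = sum(
                            Fraction(math.comb(n_term, i) * math.comb(M - n_term, n_query - i),
                                     math.comb(M, n_query))
                            for i in range(k, min(n_term, n_query) + 1)
                            if n_query - i <= M - n_term
                        )
                        assert hypergeom_p(k, n_query, n_term, M) == pytest.approx(
                            float(exact), abs=1e-12
                        )

    def test_matches_subset_enumeration(self):
        """Brute-force enumeration of all query draws from a small universe."""
        M, n_term, n_query = 8, 3, 4
        term = set(range(n_term))
        draws = list(itertools.combinations(range(M), n_query))
        for k in range(0, min(n_term, n_query) + 1):
            frac = sum(1 for d in draws if len(term & set(d)) >= k) / len(draws)
            assert hypergeom_p(k, n_query, n_term, M) == pytest.approx(frac, abs=1e-12)

    def test_monotone_decreasing_in_overlap(self):
        ps = [hypergeom_p(k, 10, 20, 100) for k in range(0, 11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


@pytest.fixture(scope="module")
def planted_annotations():
    gt = generate_ground_truth(n_areas=40, n_genes=500, k_true=5,
                               category_sizes={"wild-type": 4}, seed=13)
    table = generate_annotations(gt, n_terms=40, term_size_range=(15, 25), n_enriched=5)
    return gt, table


class TestEnrich:
    def test_planted_term_has_minimal_p(self, planted_annotations):
        gt, table = planted_annotations
        tid = gt.enriched_terms[0]
        results = enrich(table.gene_set(tid), table, query_id=tid)
        assert results[0].term_id == tid
        assert results[0].significant

    def test_empty_query_finds_nothing(self, planted_annotations):
        _, table = planted_annotations
        results = enrich(set(), table)
        assert all(r.overlap == 0 and not r.significant for r in results)
        assert n_significant(results) == 0

    def test_stray_genes_dropped_with_warning(self, planted_annotations):
        _, table = planted_annotations
        with pytest.warns(UserWarning, match="outside the background"):
            results = enrich({"NOT_A_GENE", "G0000"}, table)
        assert results[0].query_size == 1

    def test_null_calibration(self, planted_annotations):
        """Uniform random queries: the per-(query, term) rejection rate is
        bounded by alpha (the discrete test is conservative) and is not
        degenerate."""
        gt, table = planted_annotations
        rng = np.random.default_rng(0)
        genes = np.asarray(gt.gene_ids)
        n_sig = n_pairs = 0
        for _ in range(200):
            query = set(rng.choice(genes, size=20, replace=False))
            results = enrich(query, table)
            n_sig += n_significant(results)
            n_pairs += len(results)
        rate = n_sig / n_pairs
        upper = 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_pairs)
        assert 0.001 <= rate <= upper

    def test_planted_sensitivity(self):
        """>= 90 % of planted-enriched terms are detected when querying with
        their source module's gene set."""
        detected = total = 0
        for seed in range(10):
            gt = generate_ground_truth(n_areas=40, n_genes=500, k_true=5,
                                       category_sizes={"wild-type": 4}, seed=100 + seed)
            table = generate_annotations(gt, n_terms=40, term_size_range=(15, 25),
                                         n_enriched=5)
            genes = np.asarray(gt.gene_ids)
            for tid in gt.enriched_terms:
                module = gt.enriched_term_modules[tid]
                query = set(genes[gt.module_gene_indices(module)])
                results = {r.term_id: r for r in enrich(query, table)}
                total += 1
                detected += results[tid].significant
        assert detected / total >= 0.9

    def test_bh_correction_is_not_more_liberal(self, planted_annotations):
        gt, table = planted_annotations
        query = table.gene_set(gt.enriched_terms[0])
        raw = enrich(query, table)
        bh = enrich(query, table, bh_correct=True)
        assert n_significant(bh) <= n_significant(raw)


def test_annotation_table_rejects_stray_term_genes():
    with pytest.raises(ValidationError):
        AnnotationTable(
            terms=[AnnotationTerm("T0", "t", frozenset({"gX"}))],
            background=frozenset({"g0"}),
        )
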