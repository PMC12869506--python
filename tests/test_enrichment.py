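"""Hypergeometric tests, ORA with BH FDR, category tables, term overlap."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from comodmap import (
    GeneSetCollection,
    HypergeomQuery,
    category_enrichment,
    hypergeom_upper_tail,
    load_module26_categories,
    ora,
    read_category_table,
    term_overlap_test,
)
from comodmap.enrichment import bh_adjust
from comodmap.errors import DataError, FormatError, ParameterError
from conftest import hypergeom_tail_oracle


class TestHypergeomUpperTail:
    def test_published_module_enrichment_probability(self):
        """13 disease genes among 26 drawn from 320 with 53 positives."""
        p = hypergeom_upper_tail(HypergeomQuery(N=320, K=53, n=26, k=13))
        assert p == pytest.approx(3.45e-5, rel=0.005)

    def test_zero_observed_gives_one(self):
        assert hypergeom_upper_tail(HypergeomQuery(N=50, K=10, n=5, k=0)) == 1.0

    def test_matches_literal_enumeration_of_draws(self):
        """Enumerate all C(10,4) = 210 draws of 4 from a 10-item population
        with 5 marked items and count those with >= 2 marked."""
        population = [1] * 5 + [0] * 5
        draws = list(combinations(range(10), 4))
        assert len(draws) == 210
        hits = sum(1 for d in draws if sum(population[i] for i in d) >= 2)
        expected = hits / len(draws)
        p = hypergeom_upper_tail(HypergeomQuery(N=10, K=5, n=4, k=2))
        assert p == pytest.approx(expected, abs=1e-12)

    def test_decreasing_in_k(self):
        ps = [
            hypergeom_upper_tail(HypergeomQuery(N=40, K=15, n=10, k=k))
            for k in range(0, 11)
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_symmetric_in_K_and_n(self):
        a = hypergeom_upper_tail(HypergeomQuery(N=100, K=20, n=30, k=9))
        b = hypergeom_upper_tail(HypergeomQuery(N=100, K=30, n=20, k=9))
        assert a == pytest.approx(b, rel=1e-12)

    @pytest.mark.parametrize(
        "kwargs", [dict(N=10, K=11, n=3, k=1), dict(N=10, K=5, n=11, k=1),
                   dict(N=10, K=5, n=4, k=5)]
    )
    def test_invalid_counts_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            HypergeomQuery(**kwargs)


class TestCategoryEnrichment:
    def test_published_module_vs_network(self):
        """26-gene module with 13 positives against the 320-gene network with
        53: p = 3.45e-5 and roughly threefold enrichment."""
        module = [f"m{i}" for i in range(26)]
        background = module + [f"b{i}" for i in range(294)]
        cats = {g: "none" for g in background}
        for g in module[:13]:
            cats[g] = "epilepsy"
        for g in background[26:66]:
            cats[g] = "epilepsy_related"
        from comodmap import GeneCategoryTable

        res = category_enrichment(module, background, GeneCategoryTable(cats))
        assert res.k == 13 and res.K == 53 and res.n == 26 and res.N == 320
        assert res.p == pytest.approx(3.45e-5, rel=0.005)
        assert res.fold == pytest.approx(3.0, abs=0.05)
        assert res.percent_module == 50

    def test_module_equal_background_is_null(self):
        from comodmap import GeneCategoryTable

        genes = [f"g{i}" for i in range(20)]
        cats = GeneCategoryTable({g: "epilepsy" if i < 4 else "none"
                                  for i, g in enumerate(genes)})
        res = category_enrichment(genes, genes, cats)
        assert res.fold == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_matches_enumeration_oracle_on_random_instance(self):
        from comodmap import GeneCategoryTable

        rng = np.random.default_rng(8)
        background = [f"g{i}" for i in range(12)]
        positives = set(rng.choice(background, size=5, replace=False))
        module = list(rng.choice(background, size=4, replace=False))
        cats = GeneCategoryTable(
            {g: "epilepsy" if g in positives else "none" for g in background}
        )
        res = category_enrichment(module, background, cats)
        k = len(set(module) & positives)
        assert res.p == pytest.approx(hypergeom_tail_oracle(12, 5, 4, k), abs=1e-12)

    def test_module_outside_background_rejected(self):
        from comodmap import GeneCategoryTable

        with pytest.raises(ParameterError):
            category_enrichment(["x"], ["a"], GeneCategoryTable({"a": "none"}))


class TestCategoryTable:
    def test_packaged_module_table_counts(self):
        """The conserved 26-gene module carries 7 epilepsy + 6 related genes."""
        table = load_module26_categories()
        assert len(table) == 26
        assert len(table.positives({"epilepsy"})) == 7
        assert len(table.positives({"epilepsy_related"})) == 6
        assert table.percent_positive() == 50

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert len(read_category_table(path)) == 0

    def test_wrong_case_label_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene\tcategory\nG1\tEpilepsy\n")
        with pytest.raises(FormatError):
            read_category_table(path)

    def test_conflicting_duplicate_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("gene\tcategory\nG1\tepilepsy\nG1\tnone\n")
        with pytest.raises(DataError):
            read_category_table(path)

    def test_integer_rounding_of_percentages(self):
        """53 positives of 320 genes is 16.56%, printed as 17% after rounding."""
        from comodmap import GeneCategoryTable

        genes = {f"g{i}": "epilepsy" if i < 53 else "none" for i in range(320)}
        assert GeneCategoryTable(genes).percent_positive() == 17


class TestOra:
    def collection(self):
        universe = {f"u{i}" for i in range(200)}
        sets = {
            "hit": ("d", frozenset(f"u{i}" for i in range(20))),
            "miss": ("d", frozenset(f"u{i}" for i in range(100, 140))),
            "part": ("d", frozenset(f"u{i}" for i in range(10, 60))),
        }
        return GeneSetCollection(sets, frozenset(universe))

    def test_results_sorted_and_flagged(self):
        res = ora({f"u{i}" for i in range(20)}, self.collection())
        assert list(res.p_raw) == sorted(res.p_raw)
        assert res.iloc[0]["term_id"] == "hit"
        assert bool(res.iloc[0]["significant"])

    def test_disjoint_term_has_unit_p_and_zero_fold(self):
        res = ora({f"u{i}" for i in range(20)}, self.collection())
        row = res[res.term_id == "miss"].iloc[0]
        assert row.k == 0 and row.p_raw == 1.0 and row.fold == 0.0

    def test_fdr_dominates_raw_p(self):
        res = ora({f"u{i}" for i in range(15)}, self.collection())
        assert (res.fdr >= res.p_raw - 1e-15).all()
        assert (res.fdr <= 1.0).all()

    def test_full_universe_query_gives_unit_fold(self):
        coll = self.collection()
        res = ora(set(coll.universe), coll)
        assert np.allclose(res.fold, 1.0)

    def test_query_outside_universe_warns_and_empty_errors(self):
        coll = self.collection()
        with pytest.warns(UserWarning, match="outside"):
            ora({"u0", "zzz"}, coll)
        with pytest.warns(UserWarning, match="outside"):
            with pytest.raises(DataError):
                ora({"zzz"}, coll)

    def test_gmt_roundtrip(self, tmp_path):
        coll = self.collection()
        path = tmp_path / "c.gmt"
        coll.write_gmt(path)
        back = GeneSetCollection.read_gmt(path, universe=coll.universe)
        assert back.sets == coll.sets


class TestBhAdjust:
    def test_worked_example_all_equal_largest(self):
        """p = (0.01, 0.02, 0.03, 0.04): p_(i) * m / i = 0.04 for every rank,
        and monotone enforcement leaves them all at 0.04."""
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_adjusted_dominate_raw_and_preserve_order(self, ps):
        adj = bh_adjust(ps)
        ps = np.asarray(ps)
        assert np.all(adj >= ps - 1e-15)
        assert np.all(adj <= 1.0 + 1e-15)
        order = np.argsort(ps, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestTermOverlap:
    def test_published_go_overlap_is_significant(self):
        """155 shared terms between lists of 449 and 367 in a universe of
        27,047 annotatable terms is far beyond chance."""
        p = term_overlap_test(449, 367, 155, 27047)
        assert p < 0.001

    def test_zero_overlap_small_sets_near_one(self):
        assert term_overlap_test(5, 6, 0, 100000) == pytest.approx(1.0, abs=1e-3)

    def test_matches_enumeration_oracle(self):
        p = term_overlap_test(5, 6, 3, 12)
        assert p == pytest.approx(hypergeom_tail_oracle(12, 5, 6, 3), abs=1e-12)

    def test_symmetric_in_lists(self):
        assert term_overlap_test(449, 367, 155, 27047) == pytest.approx(
            term_overlap_test(367, 449, 155, 27047), rel=1e-9
        )

    def test_consistent_with_terms_as_genes_reformulation(self):
        """The overlap test equals category enrichment when terms are recast
        as genes: universe = all terms, positives = list A, module = list B."""
        from comodmap import GeneCategoryTable

        N, a, b, k = 60, 12, 9, 4
        terms = [f"t{i}" for i in range(N)]
        cats = GeneCategoryTable(
            {t: "epilepsy" if i < a else "none" for i, t in enumerate(terms)}
        )
        module = terms[a - k : a - k + b]  # b terms, k of them positive
        res = category_enrichment(module, terms, cats, positive={"epilepsy"})
        assert res.k == k
        assert term_overlap_test(a, b, k, N) == pytest.approx(res.p, rel=1e-12)

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ParameterError):
            term_overlap_test(5, 6, 6, 100)
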