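"""Spearman correlation, 1-r clustering, module extraction."""

import warnings

import numpy as np
import pytest

from comodmap import (
    CorrelationMatrix,
    ExpressionMatrix,
    extract_modules,
    hierarchical_cluster,
    log2_transform,
    module_stats,
    spearman_matrix,
)
from comodmap.errors import DataError, ParameterError
from conftest import linkage_oracle, spearman_oracle


def mat_from(values, gene_ids=None):
    values = np.asarray(values, dtype=float)
    g, c = values.shape
    return ExpressionMatrix(
        values,
        gene_ids or [f"g{i}" for i in range(g)],
        [f"c{i}" for i in range(c)],
        ["t"] * c,
    )


def cor_from(r_matrix, gene_ids):
    return CorrelationMatrix(np.asarray(r_matrix, float), gene_ids)


class TestLog2Transform:
    def test_values(self):
        mat = mat_from([[0.0, 7.0, 3.0]])
        out = log2_transform(mat, pseudocount=1)
        assert out.counts[0, 0] == 0.0
        assert out.counts[0, 1] == pytest.approx(3.0)  # log2(8)

    def test_zero_pseudocount_with_zeros_rejected(self):
        with pytest.raises(ParameterError):
            log2_transform(mat_from([[0.0, 1.0]]), pseudocount=0)

    def test_spearman_invariant_under_transform(self, small_matrix):
        """log2 is strictly increasing, so the rank correlation is unchanged."""
        a = spearman_matrix(small_matrix)
        b = spearman_matrix(log2_transform(small_matrix))
        assert np.allclose(a.values, b.values, atol=1e-12)


class TestSpearmanMatrix:
    def test_increasing_function_gives_unit_correlation(self):
        x = np.arange(1.0, 11.0)
        mat = mat_from(np.vstack([x, x**3 + 2]))
        cor = spearman_matrix(mat)
        assert cor.values[0, 1] == pytest.approx(1.0)

    def test_hand_computed_example(self):
        """x=(1,2,3,4), y=(1,3,2,4): sum d^2 = 2, r = 1 - 12/60 = 0.8."""
        mat = mat_from([[1, 2, 3, 4], [1, 3, 2, 4]])
        cor = spearman_matrix(mat)
        assert cor.values[0, 1] == pytest.approx(0.8, abs=1e-12)

    def test_agrees_with_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(12)
        counts = rng.poisson(4, size=(20, 200)).astype(float)
        mat = mat_from(counts)
        cor = spearman_matrix(mat)
        for i, j in [(0, 1), (3, 17), (5, 5), (10, 19), (2, 8)]:
            expected = spearman_oracle(counts[i], counts[j])
            assert cor.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_constant_gene_reported_missing(self):
        counts = np.vstack([np.full(10, 3.0), np.arange(10.0), np.arange(10.0)[::-1]])
        with pytest.warns(UserWarning, match="constant"):
            cor = spearman_matrix(mat_from(counts))
        assert cor.missing_genes == ["g0"]
        assert np.isnan(cor.values[0, 1])
        assert cor.values[1, 2] == pytest.approx(-1.0)

    def test_too_few_cells_rejected(self):
        with pytest.raises(DataError):
            spearman_matrix(mat_from([[1, 2], [2, 1]]))

    def test_gene_permutation_changes_labels_only(self, small_matrix):
        cor = spearman_matrix(small_matrix)
        perm = np.random.default_rng(5).permutation(small_matrix.n_genes)
        shuffled = ExpressionMatrix(
            small_matrix.counts[perm],
            [small_matrix.gene_ids[i] for i in perm],
            small_matrix.cell_ids,
            small_matrix.cell_types,
        )
        cor_p = spearman_matrix(shuffled)
        assert np.allclose(cor_p.values, cor.values[np.ix_(perm, perm)], atol=1e-12)


class TestHierarchicalCluster:
    def test_three_gene_hand_agglomeration(self):
        """r(A,B)=0.9, r(A,C)=0.2, r(B,C)=0.1: merge {A,B} at 0.1, then C at
        complete-linkage height max(0.8, 0.9) = 0.9."""
        r = [[1.0, 0.9, 0.2], [0.9, 1.0, 0.1], [0.2, 0.1, 1.0]]
        dendro = hierarchical_cluster(cor_from(r, ["A", "B", "C"]))
        assert dendro.merge_heights == pytest.approx([0.1, 0.9])
        first = dendro.linkage_matrix[0, :2]
        assert set(first.astype(int)) == {0, 1}

    def test_identical_genes_merge_at_zero(self):
        x = np.arange(12.0)
        mat = mat_from(np.vstack([x, x, x[::-1]]))
        cor = spearman_matrix(mat)
        dendro = hierarchical_cluster(cor)
        assert dendro.merge_heights[0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("method", ["complete", "average", "single"])
    def test_matches_bruteforce_agglomeration(self, method):
        rng = np.random.default_rng(21)
        pts = rng.normal(size=(15, 60))
        r = np.corrcoef(pts)
        cor = cor_from(r, [f"g{i}" for i in range(15)])
        dendro = hierarchical_cluster(cor, method)
        expected = linkage_oracle(1.0 - r, method)
        assert sorted(dendro.merge_heights) == pytest.approx(expected, abs=1e-12)

    def test_complete_linkage_heights_nondecreasing(self, planted_sim):
        mat, _ = planted_sim
        cor = spearman_matrix(mat)
        dendro = hierarchical_cluster(cor)
        assert np.all(np.diff(dendro.merge_heights) >= -1e-12)

    def test_missing_correlations_rejected(self):
        values = np.eye(3)
        values[0, 1] = values[1, 0] = np.nan
        values[0, 2] = values[2, 0] = 0.5
        values[1, 2] = values[2, 1] = 0.5
        cor = CorrelationMatrix(values, ["a", "b", "c"], missing_genes=[])
        with pytest.raises(DataError, match="missing"):
            hierarchical_cluster(cor)

    def test_newick_export_parses(self, small_matrix):
        cor = spearman_matrix(small_matrix)
        nwk = hierarchical_cluster(cor).to_newick()
        assert nwk.endswith(";")
        for g in cor.gene_ids:
            assert g in nwk


class TestExtractModules:
    def test_maximal_cut_gives_single_cluster(self, small_matrix):
        cor = spearman_matrix(small_matrix)
        dendro = hierarchical_cluster(cor)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mods = extract_modules(dendro, cor, cut_height=2.0, min_size=2,
                                   min_mean_intra_r=-1.0)
        assert len(mods) == 1
        assert sorted(mods.modules[0].genes) == sorted(cor.gene_ids)

    def test_planted_module_recovered(self, planted_sim):
        mat, truth = planted_sim
        cor = spearman_matrix(log2_transform(mat))
        dendro = hierarchical_cluster(cor)
        mods = extract_modules(dendro, cor, cut_height=1.0)
        truth_genes = truth.module_memberships["module_1"]
        top = set(mods.modules[0].genes)
        jaccard = len(top & truth_genes) / len(top | truth_genes)
        assert jaccard >= 0.9

    def test_no_qualifying_cluster_warns_not_raises(self, small_matrix):
        cor = spearman_matrix(small_matrix)
        dendro = hierarchical_cluster(cor)
        with pytest.warns(UserWarning, match="no cluster"):
            mods = extract_modules(dendro, cor, cut_height=0.01, min_size=5)
        assert len(mods) == 0

    def test_exactly_one_cut_parameter_required(self, small_matrix):
        cor = spearman_matrix(small_matrix)
        dendro = hierarchical_cluster(cor)
        with pytest.raises(ParameterError):
            extract_modules(dendro, cor)
        with pytest.raises(ParameterError):
            extract_modules(dendro, cor, cut_height=1.0, n_clusters=2)


class TestModuleStats:
    def test_two_genes_single_pair(self):
        r = [[1.0, 0.5], [0.5, 1.0]]
        cor = cor_from(r, ["a", "b"])
        st = module_stats(["a", "b"], cor)
        assert st["intra_min"] == st["intra_mean"] == st["intra_max"] == 0.5

    def test_matches_bruteforce_pair_enumeration(self):
        from itertools import combinations

        rng = np.random.default_rng(2)
        pts = rng.normal(size=(8, 30))
        r = np.corrcoef(pts)
        cor = cor_from(r, [f"g{i}" for i in range(8)])
        genes = ["g0", "g2", "g3", "g5", "g6", "g7"]
        idx = [int(g[1]) for g in genes]
        pairs = [r[i, j] for i, j in combinations(idx, 2)]
        st = module_stats(genes, cor)
        assert st["intra_min"] == pytest.approx(min(pairs))
        assert st["intra_mean"] == pytest.approx(np.mean(pairs))
        assert st["intra_max"] == pytest.approx(max(pairs))

    def test_cross_set_statistics_and_disjointness(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 30))
        r = np.corrcoef(pts)
        cor = cor_from(r, [f"g{i}" for i in range(6)])
        st = module_stats(["g0", "g1"], cor, other=["g4", "g5"])
        block = r[np.ix_([0, 1], [4, 5])]
        assert st["cross_mean"] == pytest.approx(block.mean())
        with pytest.raises(ParameterError, match="disjoint"):
            module_stats(["g0", "g1"], cor, other=["g1", "g2"])

    def test_singleton_intra_is_missing(self):
        cor = cor_from([[1.0, 0.2], [0.2, 1.0]], ["a", "b"])
        st = module_stats(["a"], cor)
        assert np.isnan(st["intra_mean"])
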