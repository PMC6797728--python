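import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from tcellpipe import (binomial_markers, cd4_cd8_ratio, collapse_umis,
                       dropout_scores, resolve_swaps, select_hvgs,
                       simulate_dataset, spearman_knn_louvain)
from tcellpipe.simulate import CellType, SampleSpec, SimConfig

from conftest import matrix_from_counts


class TestDropoutScores:
    def test_equation_arithmetic(self):
        # f == f_max gives zero; |0.1 - 0.4| / sqrt(0.4) otherwise
        assert abs(0.1 - 0.4) / np.sqrt(0.4) == pytest.approx(0.47434, abs=1e-4)
        rng = np.random.default_rng(0)
        counts = rng.poisson(1.0, size=(50, 30))
        mm = matrix_from_counts(counts)
        tab = dropout_scores(mm, window=5).table
        equal = tab[tab["f"] == tab["f_max"]]
        assert (equal["ds"] == 0).all()

    def test_matches_explicit_loop_oracle(self):
        rng = np.random.default_rng(1)
        counts = rng.negative_binomial(2, 0.3, size=(80, 200))
        mm = matrix_from_counts(counts)
        res = dropout_scores(mm, window=25).table

        # independent explicit-loop implementation
        lib = counts.sum(axis=1, keepdims=True).astype(float)
        norm = counts / lib
        mean_norm = norm.mean(axis=0)
        f = (counts > 0).mean(axis=0)
        genes = np.array([f"g{i}" for i in range(200)])
        order = np.lexsort((genes, -mean_norm))
        for pos, gi in enumerate(order):
            lo, hi = max(0, pos - 12), min(200, pos + 13)
            fmax = max(f[order[j]] for j in range(lo, hi))
            ds = abs(f[gi] - fmax) / np.sqrt(fmax) if fmax > 0 else 0.0
            assert res.loc[genes[gi], "ds"] == pytest.approx(ds)

    def test_invariant_to_scaling_one_cell(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(2.0, size=(40, 60))
        a = dropout_scores(matrix_from_counts(counts)).table
        counts2 = counts.copy()
        counts2[0] *= 7  # detection and sum-to-one ordering are unchanged
        b = dropout_scores(matrix_from_counts(counts2)).table
        pd.testing.assert_series_equal(a["ds"], b["ds"])

    def test_window_shrinks_when_few_genes(self):
        counts = np.random.default_rng(3).poisson(1.0, size=(30, 10))
        tab = dropout_scores(matrix_from_counts(counts), window=25).table
        assert len(tab) == 10  # no error, window truncated


class TestHvgSelection:
    def test_absolute_threshold(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(1.0, size=(100, 50))
        counts[:50, 0] = 10  # bimodal: on in half the cells
        counts[50:, 0] = 0
        scores = dropout_scores(matrix_from_counts(counts))
        hvgs = select_hvgs(scores)
        assert "g0" in hvgs

    def test_empty_selection_is_an_error(self):
        counts = np.ones((30, 20), dtype=int)  # all genes always detected
        scores = dropout_scores(matrix_from_counts(counts))
        with pytest.raises(ValueError, match="review"):
            select_hvgs(scores)


class TestClustering:
    def test_two_duplicated_blocks_yield_two_clusters(self):
        rng = np.random.default_rng(5)
        a = rng.poisson(3.0, size=40)
        b = np.roll(a, 17)
        counts = np.vstack([np.tile(a, (30, 1)) + rng.poisson(0.2, (30, 40)),
                            np.tile(b, (30, 1)) + rng.poisson(0.2, (30, 40))])
        mm = matrix_from_counts(counts)
        labels = spearman_knn_louvain(mm, mm.genes, k=10, seed=0)
        assert len(labels.cluster_ids()) == 2
        assert len(set(labels.labels[:30])) == 1
        assert len(set(labels.labels[30:])) == 1

    def test_planted_four_types_recovered(self):
        types = [CellType(f"T{i}", "CD4", 0.25, 300.0,
                          {f"T{i}_M{j:02d}": 12.0 for j in range(12)})
                 for i in range(4)]
        genes = [f"T{i}_M{j:02d}" for i in range(4) for j in range(12)]
        genes += [f"G{i:03d}" for i in range(150)]
        ann = pd.DataFrame({"biotype": "protein_coding", "is_mito": False},
                           index=pd.Index(genes, name="gene"))
        cfg = SimConfig(
            samples=[SampleSpec("s1", "blood", 10.0, activated_fraction=0.0)],
            cell_types=types, cells_per_sample=600, n_genes=len(genes),
            seed=8, swap_rate=0, chimera_rate=0, multiplet_rate=0,
            dead_fraction=0, high_intron_fraction=0, gene_names=genes,
            gene_annotation=ann,
            exclusive_genes=frozenset(g for g in genes if "_M" in g))
        addresses, truth = simulate_dataset(cfg)
        mm = collapse_umis(resolve_swaps(addresses),
                           gene_index=pd.Index(genes))
        hvgs = select_hvgs(dropout_scores(mm))
        labels = spearman_knn_louvain(mm, hvgs, k=15, seed=0)
        truth_types = truth.cells.loc[labels.labels.index, "cell_type"]
        ari = adjusted_rand_score(truth_types, labels.labels)
        assert ari >= 0.9

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(2.0, size=(80, 30))
        mm = matrix_from_counts(counts)
        a = spearman_knn_louvain(mm, mm.genes, k=10, seed=42)
        b = spearman_knn_louvain(mm, mm.genes, k=10, seed=42)
        assert (a.labels == b.labels).all()

    def test_k_too_large_is_an_error(self):
        mm = matrix_from_counts(np.ones((5, 4), dtype=int))
        with pytest.raises(ValueError):
            spearman_knn_louvain(mm, mm.genes, k=5, seed=0)

    def test_min_cluster_size_reassigns_small_clusters(self):
        rng = np.random.default_rng(7)
        a = rng.poisson(3.0, size=40)
        counts = np.vstack([
            np.tile(a, (50, 1)) + rng.poisson(0.2, (50, 40)),
            np.tile(np.roll(a, 19), (50, 1)) + rng.poisson(0.2, (50, 40)),
            rng.poisson(3.0, size=(4, 40)),  # a few stray cells
        ])
        mm = matrix_from_counts(counts)
        labels = spearman_knn_louvain(mm, mm.genes, k=8, seed=0,
                                      min_cluster_size=20)
        sizes = labels.labels.value_counts()
        assert (sizes >= 20).all()


class TestClusterStatistics:
    def _mm_with_lineage_genes(self, cd4, cd8a):
        counts = np.zeros((len(cd4), 6), dtype=int)
        counts[:, 0] = cd4
        counts[:, 1] = cd8a
        counts[:, 2:] = 3  # padding so libraries are nonzero
        return matrix_from_counts(
            counts, genes=["CD4", "CD8A", "g2", "g3", "g4", "g5"])

    def test_cd4_cd8_ratio_values(self):
        # cluster 0: equal statistics -> 0; cluster 1: CD4 stat 2x -> 1
        cd4 = np.array([3, 3, 3, 3, 15, 15, 15, 15])
        cd8a = np.array([3, 3, 3, 3, 3, 3, 3, 3])
        mm = self._mm_with_lineage_genes(cd4, cd8a)
        labels = pd.Series([0, 0, 0, 0, 1, 1, 1, 1], index=mm.cells)
        from tcellpipe.cluster import ClusterLabeling
        cl = ClusterLabeling(labels=labels,
                             cluster_info=pd.DataFrame(index=[0, 1]))
        sf = np.ones(8)
        ratios = cd4_cd8_ratio(mm, sf, cl)
        g4 = np.log2(cd4 + 1)
        g8 = np.log2(cd8a + 1)
        for cid, sel in ((0, slice(0, 4)), (1, slice(4, 8))):
            expect = np.log2((g4[sel].mean() / g4.mean())
                             / (g8[sel].mean() / g8.mean()))
            assert ratios.loc[cid] == pytest.approx(expect)

    def test_binomial_markers_extremes_and_oracle(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 2, size=(60, 20))
        counts[:, 5] = 1  # equal detection in and out: never a marker
        counts[:10, 0] = 1  # perfect marker of cluster 0
        counts[10:, 0] = 0
        mm = matrix_from_counts(counts)
        from tcellpipe.cluster import ClusterLabeling
        labels = pd.Series([0] * 10 + [1] * 50, index=mm.cells)
        cl = ClusterLabeling(labels=labels,
                             cluster_info=pd.DataFrame(index=[0, 1]))
        table = binomial_markers(mm, cl)
        hit = table[(table["gene"] == "g0") & (table["cluster"] == 0)]
        assert len(hit) == 1 and hit["p"].iloc[0] < 1e-10
        assert "g5" not in set(table["gene"])
        # p-values equal an independent binomial tail computation
        det = counts > 0
        for _, row in table.iterrows():
            sel = (labels == row["cluster"]).to_numpy()
            gi = mm.genes.get_loc(row["gene"])
            k_in, n_in = det[sel, gi].sum(), sel.sum()
            f_out = det[~sel, gi].mean()
            null = min(f_out + 1 / 60, 1.0)
            expect = stats.binom.sf(k_in - 1, n_in, null)
            assert row["p"] == pytest.approx(expect)
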