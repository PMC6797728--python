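
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tcellpipe import (derive_signature, flag_blood_outliers, gate_ccl5,
                       pairwise_de, preranked_gsea, signature_score)

from conftest import matrix_from_counts


class TestCcl5Gate:
    def test_bimodal_rpm_gates_high_confidence_cells(self):
        import scipy.sparse as sp

        from tcellpipe import MoleculeMatrix
        rng = np.random.default_rng(0)
        n = 400
        counts = np.ones((n, 2), dtype=int)
        counts[:200, 0] = 1  # genuine CCL5
        rpm = np.ones((n, 2)) * 8.0
        rpm[:200, 0] = rng.lognormal(np.log(12), 0.2, 200)
        rpm[200:350, 0] = rng.lognormal(np.log(1.4), 0.2, 150)  # chimeric
        counts[350:, 0] = 0
        rpm[350:, 0] = 0
        cells = pd.Index([f"s1|b{i:03d}" for i in range(n)])
        mm = MoleculeMatrix(sp.csr_matrix(counts), sp.csr_matrix(rpm), cells,
                            pd.Index(["CCL5", "pad"]), np.array(["s1"] * n),
                            sample_rpm={"s1": 8.0})
        positive = set(gate_ccl5(mm))
        genuine = set(cells[:200])
        chimeric = set(cells[200:350])
        assert len(positive & genuine) >= 0.95 * len(genuine)
        assert len(positive & chimeric) <= 0.05 * len(chimeric)
        assert not positive & set(cells[350:])  # no detection, never positive


class TestPairwiseDe:
    def test_identical_groups_are_null(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(3.0, size=(60, 25))
        mm = matrix_from_counts(counts)
        de = pairwise_de(mm, np.ones(60), mm.cells[:30], mm.cells[30:])
        assert (de["p_adj"] > 0.2).all()
        assert np.abs(de["log2_fc"]).max() < 0.5

    def test_tenfold_gene_is_called(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(2.0, size=(200, 30))
        counts[:100, 0] = rng.poisson(20.0, 100)
        counts[100:, 0] = rng.poisson(2.0, 100)
        mm = matrix_from_counts(counts)
        de = pairwise_de(mm, np.ones(200), mm.cells[:100], mm.cells[100:])
        assert de.loc["g0", "p_adj"] < 0.05
        assert de.loc["g0", "fold_change"] > 2

    def test_matches_per_gene_scipy_oracle(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(2.0, size=(40, 20))
        mm = matrix_from_counts(counts)
        a, b = mm.cells[:20], mm.cells[20:]
        de = pairwise_de(mm, np.ones(40), a, b)
        for gi, gene in enumerate(mm.genes):
            _, p = stats.ranksums(counts[:20, gi], counts[20:, gi])
            assert de.loc[gene, "p"] == pytest.approx(p)

    def test_blacklist_excluded_and_small_groups_refused(self):
        counts = np.random.default_rng(4).poisson(2.0, size=(40, 10))
        mm = matrix_from_counts(counts)
        de = pairwise_de(mm, np.ones(40), mm.cells[:20], mm.cells[20:],
                         exclude_genes=pd.Index(["g0"]))
        assert "g0" not in de.index
        with pytest.raises(ValueError):
            pairwise_de(mm, np.ones(40), mm.cells[:5], mm.cells[5:])


def fake_de(genes, hits, p=1e-4, fc=5.0):
    df = pd.DataFrame({"p_adj": 1.0, "fold_change": 1.0},
                      index=pd.Index(genes, name="gene"))
    df.loc[hits, "p_adj"] = p
    df.loc[hits, "fold_change"] = fc
    return df


class TestDeriveSignature:
    genes = [f"g{i}" for i in range(10)]

    def test_all_comparisons_rule(self):
        tables = [fake_de(self.genes, ["g1", "g2"]),
                  fake_de(self.genes, ["g1", "g2"]),
                  fake_de(self.genes, ["g1", "g2"]),
                  fake_de(self.genes, ["g1"])]  # g2 passes only 3/4
        sigs = derive_signature({"lung": tables})
        assert list(sigs["lung"]) == ["g1"]
        assert list(sigs["combined"]) == ["g1"]

    def test_missing_comparison_is_an_error(self):
        with pytest.raises(ValueError):
            derive_signature({"lung": [fake_de(self.genes, ["g1"]), None]})

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(5)
        tables = [pd.DataFrame({
            "p_adj": rng.uniform(0, 0.2, 10),
            "fold_change": rng.uniform(1, 6, 10)},
            index=pd.Index(self.genes, name="gene")) for _ in range(4)]
        loose = set(derive_signature({"t": tables}, fc_min=2, p_max=0.05)["t"])
        tight_fc = set(derive_signature({"t": tables}, fc_min=4,
                                        p_max=0.05)["t"])
        tight_p = set(derive_signature({"t": tables}, fc_min=2,
                                       p_max=0.01)["t"])
        assert tight_fc <= loose and tight_p <= loose


class TestSignatureScore:
    def test_uniform_value_gives_log2(self):
        counts = np.full((5, 4), 7)
        mm = matrix_from_counts(counts)
        score = signature_score(mm, np.ones(5), pd.Index(["g0", "g1"]))
        assert score.tolist() == pytest.approx([np.log2(8)] * 5)

    def test_zero_signature_genes_score_zero(self):
        counts = np.zeros((4, 3), dtype=int)
        counts[:, 2] = 5
        mm = matrix_from_counts(counts)
        score = signature_score(mm, np.ones(4), pd.Index(["g0", "g1"]))
        assert (score == 0).all()

    def test_empty_signature_is_an_error(self):
        mm = matrix_from_counts(np.ones((4, 3), dtype=int))
        with pytest.raises(ValueError):
            signature_score(mm, np.ones(4), pd.Index(["absent"]))


class TestBloodOutliers:
    def test_threshold_is_one_sd_below_tissue_mean(self):
        tissue = pd.Series([2.0, 2.0, 4.0, 4.0], index=list("abcd"))
        thr = tissue.mean() - tissue.std(ddof=0)  # 3 - 1 = 2
        blood = pd.Series([3.0, 2.0, 1.9, 0.5],
                          index=["w", "x", "y", "z"])
        out = set(flag_blood_outliers(blood, tissue))
        assert out == {"w", "x"}
        assert blood.loc["y"] < thr


class TestPrerankedGsea:
    def test_top_block_reaches_closed_form_maximum(self):
        universe = pd.Index([f"g{i}" for i in range(50)])
        gene_set = universe[:5]
        res = preranked_gsea(universe, gene_set, n_perm=200, seed=0)
        assert res.es == pytest.approx(1.0)  # running sum peaks after hit 5
        assert res.p <= 0.05

    def test_matches_exhaustive_running_sum_oracle(self):
        universe = pd.Index([f"g{i}" for i in range(10)])
        gene_set = ["g1", "g4", "g9"]
        res = preranked_gsea(universe, gene_set, n_perm=10, seed=0)
        hits = {1, 4, 9}
        running, best = 0.0, 0.0
        for i in range(10):
            running += 1 / 3 if i in hits else -1 / 7
            if abs(running) > abs(best):
                best = running
        assert res.es == pytest.approx(best)

    def test_random_sets_give_unremarkable_p(self):
        rng = np.random.default_rng(7)
        universe = pd.Index([f"g{i}" for i in range(200)])
        ps = []
        for _ in range(20):
            genes = rng.choice(200, size=15, replace=False)
            res = preranked_gsea(universe, universe[genes], n_perm=300,
                                 seed=int(rng.integers(1000)))
            ps.append(res.p)
        # roughly uniform: mean near 0.5, not piled at the extremes
        assert 0.25 < np.mean(ps) < 0.75

    def test_empty_intersection_is_an_error(self):
        with pytest.raises(ValueError):
            preranked_gsea(pd.Index(["a", "b"]), ["zz"], n_perm=10)

    def test_negative_es_for_bottom_block(self):
        universe = pd.Index([f"g{i}" for i in range(50)])
        res = preranked_gsea(universe, universe[-5:], n_perm=200, seed=1)
        assert res.es < 0
        assert res.p <= 0.05
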