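import itertools
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tcellpipe import (FactorModel, cd4_cd8_bias, cluster_factor_modules,
                       ensemble_reconstruction, factorize,
                       filter_genes_for_factorization, k_overlap,
                       overlap_pvalue, select_k_from_pvalues)

from conftest import matrix_from_counts


def model_from_scores(gene_scores, sample="s", n_unfiltered=None):
    genes = pd.Index([f"g{i}" for i in range(gene_scores.shape[0])])
    k = gene_scores.shape[1]
    cells = pd.Index([f"{sample}|c{i}" for i in range(3)])
    return FactorModel(sample=sample, k=k,
                       gene_scores=pd.DataFrame(
                           gene_scores, index=genes,
                           columns=[f"F{i}" for i in range(k)]),
                       cell_scores=pd.DataFrame(
                           np.ones((3, k)), index=cells,
                           columns=[f"F{i}" for i in range(k)]),
                       n_unfiltered_genes=n_unfiltered or len(genes))


class TestFactorize:
    def test_rank_one_matrix_is_recovered(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(1, 5, 60)
        h = rng.uniform(0.5, 3, 40)
        counts = np.outer(w, h)
        mm = matrix_from_counts(counts.astype(float))
        model = factorize(mm, 1, seed=0, max_iter=500, tol=1e-8)
        recon = (model.cell_scores.to_numpy()
                 @ model.gene_scores.to_numpy().T)
        # Poisson deviance of the reconstruction approaches zero
        dev = np.sum(counts * np.log(counts / recon) - counts + recon)
        assert dev / counts.sum() < 1e-4
        r = np.corrcoef(model.gene_scores["F0"], h)[0, 1]
        assert r > 0.999

    def test_same_seed_identical(self):
        counts = np.random.default_rng(1).poisson(2.0, size=(50, 30))
        mm = matrix_from_counts(counts)
        a = factorize(mm, 4, seed=9)
        b = factorize(mm, 4, seed=9)
        pd.testing.assert_frame_equal(a.gene_scores, b.gene_scores)

    def test_planted_disjoint_programs_recovered(self):
        rng = np.random.default_rng(2)
        k, genes_per = 8, 25
        h_true = np.zeros((k, k * genes_per))
        for f in range(k):
            h_true[f, f * genes_per:(f + 1) * genes_per] = rng.uniform(
                2, 6, genes_per)
        w_true = rng.gamma(2.0, 1.0, size=(400, k))
        counts = rng.poisson(w_true @ h_true)
        mm = matrix_from_counts(counts)
        model = factorize(mm, k, seed=0)
        got = model.gene_scores.to_numpy().T
        best = []
        used = set()
        for f in range(k):  # greedy one-to-one matching
            cors = [(abs(np.corrcoef(h_true[f], got[j])[0, 1]), j)
                    for j in range(k) if j not in used]
            c, j = max(cors)
            used.add(j)
            best.append(c)
        assert np.mean(best) >= 0.8

    def test_k_too_large_rejected(self):
        mm = matrix_from_counts(np.ones((5, 8), dtype=int))
        with pytest.raises(ValueError):
            factorize(mm, 5, seed=0)

    def test_gene_filter_applies_biotype_blacklist_and_detection(self):
        counts = np.ones((100, 4), dtype=int)
        counts[:, 3] = 0  # never detected
        mm = matrix_from_counts(counts, genes=["a", "b", "c", "d"])
        ann = pd.DataFrame({"biotype": ["protein_coding", "lincRNA",
                                        "protein_coding", "protein_coding"],
                            "is_mito": False},
                           index=pd.Index(["a", "b", "c", "d"]))
        keep = filter_genes_for_factorization(
            mm, ann, blacklist=pd.Index(["c"]))
        assert list(keep) == ["a"]


class TestKOverlap:
    def test_duplicated_factors_overlap_fully(self):
        scores = np.random.default_rng(3).uniform(size=(400, 1))
        model = model_from_scores(np.hstack([scores, scores]))
        assert k_overlap(model, top_n=300) == 300

    def test_disjoint_supports_overlap_zero(self):
        scores = np.zeros((40, 2))
        scores[:20, 0] = np.arange(20) + 1
        scores[20:, 1] = np.arange(20) + 1
        model = model_from_scores(scores)
        assert k_overlap(model, top_n=20) == 0

    def test_matches_all_pairs_set_oracle(self):
        rng = np.random.default_rng(4)
        scores = rng.uniform(size=(200, 5))
        model = model_from_scores(scores)
        got = k_overlap(model, top_n=50)
        genes = model.gene_scores.index.to_numpy()
        tops = []
        for f in model.gene_scores.columns:
            order = np.lexsort((genes, -model.gene_scores[f].to_numpy()))
            tops.append(set(genes[order[:50]]))
        expect = max(len(a & b) for a, b in itertools.combinations(tops, 2))
        assert got == expect


class TestOverlapPvalue:
    def test_zero_overlap_gives_one(self):
        assert overlap_pvalue(0, 15000, 300) == 1.0

    def test_full_overlap_is_vanishing(self):
        assert overlap_pvalue(300, 15000, 300) < 1e-100

    def test_exact_enumeration_population_40_draws_10(self):
        M, n = 40, 10
        for n_k in range(0, 11):
            expect = sum(math.comb(n, j) * math.comb(M - n, n - j)
                         for j in range(n_k, n + 1)) / math.comb(M, n)
            assert overlap_pvalue(n_k, M, n) == pytest.approx(expect)

    def test_monotone_nonincreasing_in_overlap(self):
        ps = [overlap_pvalue(n_k, 1000, 100) for n_k in range(101)]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(ValueError):
            overlap_pvalue(301, 15000, 300)


class TestSelectK:
    def test_stated_fixture(self):
        pvals = {6: .8, 7: .6, 8: .3, 9: .06, 10: .01, 11: .001, 12: .0001}
        assert select_k_from_pvalues(pvals) == 9

    def test_all_acceptable_picks_largest(self):
        assert select_k_from_pvalues({k: 0.5 for k in range(6, 13)}) == 12

    def test_all_significant_falls_back_to_smallest(self):
        assert select_k_from_pvalues({k: 0.01 for k in range(6, 13)}) == 6

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            select_k_from_pvalues({})


def template_models(noise_sd=0.05, seed=0, n_genes=300):
    """Three 4-factor models built from 4 shared templates plus noise."""
    rng = np.random.default_rng(seed)
    templates = rng.uniform(0, 1, size=(4, n_genes)) ** 3
    models = []
    for s in range(3):
        cols = {}
        for f in range(4):
            cols[f"F{f}"] = templates[f] + rng.normal(
                0, noise_sd * templates[f].std(), n_genes)
        genes = pd.Index([f"g{i}" for i in range(n_genes)])
        gene_scores = pd.DataFrame(cols, index=genes).clip(lower=0)
        cells = pd.Index([f"s{s}|c{i}" for i in range(3)])
        models.append(FactorModel(
            sample=f"s{s}", k=4, gene_scores=gene_scores,
            cell_scores=pd.DataFrame(np.ones((3, 4)), index=cells,
                                     columns=gene_scores.columns),
            n_unfiltered_genes=n_genes))
    return models, templates


class TestModuleClustering:
    def test_two_identical_factors_form_one_perfect_module(self):
        scores = np.random.default_rng(5).uniform(size=(200, 1))
        m1 = model_from_scores(scores, sample="a")
        m2 = model_from_scores(scores, sample="b")
        mods = cluster_factor_modules([m1, m2], top_bottom_n=50)
        assert len(mods.modules) == 1
        assert mods.modules[0].mean_correlation == pytest.approx(1.0)

    def test_templates_recovered_exactly(self):
        models, _ = template_models(noise_sd=0.1)
        mods = cluster_factor_modules(models, corr_min=0.25)
        assert len(mods.modules) == 4
        truth, found = [], []
        for i, mod in enumerate(mods.modules):
            for sample, factor in mod.members:
                truth.append(int(factor[1:]))
                found.append(i)
        assert adjusted_rand_score(truth, found) == 1.0

    def test_pure_noise_yields_no_modules(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            models = []
            for s in range(3):
                genes = pd.Index([f"g{i}" for i in range(2000)])
                gs = pd.DataFrame(rng.uniform(size=(2000, 4)), index=genes,
                                  columns=[f"F{i}" for i in range(4)])
                cells = pd.Index([f"s{s}|c{i}" for i in range(3)])
                models.append(FactorModel(
                    sample=f"s{s}", k=4, gene_scores=gs,
                    cell_scores=pd.DataFrame(np.ones((3, 4)), index=cells,
                                             columns=gs.columns),
                    n_unfiltered_genes=2000))
            mods = cluster_factor_modules(models, corr_min=0.25)
            assert len(mods.modules) == 0

    def test_invariant_to_model_order(self):
        models, _ = template_models(noise_sd=0.1, seed=3)
        a = cluster_factor_modules(models)
        b = cluster_factor_modules(models[::-1])
        sets_a = sorted(frozenset(m.members) for m in a.modules)
        sets_b = sorted(frozenset(m.members) for m in b.modules)
        assert sets_a == sets_b

    def test_dropping_loose_member_barely_changes_top_genes(self):
        models, templates = template_models(noise_sd=0.05, seed=4,
                                            n_genes=2000)
        # a loosely correlated member: same leading genes, scrambled body
        rng = np.random.default_rng(9)
        loose = templates[0].copy()
        body = np.argsort(-loose)[150:]
        loose[body] = rng.permutation(loose[body])
        assert np.corrcoef(loose, templates[0])[0, 1] < 0.5
        genes = models[0].gene_scores.index
        extra = FactorModel(
            sample="s3", k=1,
            gene_scores=pd.DataFrame({"F0": np.clip(loose, 0, None)},
                                     index=genes),
            cell_scores=pd.DataFrame(np.ones((3, 1)),
                                     index=pd.Index(["s3|c0", "s3|c1",
                                                     "s3|c2"]),
                                     columns=["F0"]),
            n_unfiltered_genes=2000)
        with_loose = cluster_factor_modules(models + [extra], corr_min=0.25)
        without = cluster_factor_modules(models, corr_min=0.25)

        def module_for_template0(ms):
            for m in ms.modules:
                if ("s0", "F0") in m.members:
                    return m
            raise AssertionError("template-0 module missing")

        top_a = set(module_for_template0(with_loose).top_genes.index[:50])
        top_b = set(module_for_template0(without).top_genes.index[:50])
        overlap = len(top_a & top_b) / 50
        assert overlap >= 0.9

    def test_single_model_is_an_error(self):
        models, _ = template_models()
        with pytest.raises(ValueError):
            cluster_factor_modules(models[:1])


class TestCd4Cd8Bias:
    def _model(self, cell_scores):
        cells = pd.Index([f"s|c{i}" for i in range(cell_scores.shape[0])])
        k = cell_scores.shape[1]
        return FactorModel(
            sample="s", k=k,
            gene_scores=pd.DataFrame(np.ones((5, k)),
                                     index=pd.Index(list("abcde")),
                                     columns=[f"F{i}" for i in range(k)]),
            cell_scores=pd.DataFrame(cell_scores, index=cells,
                                     columns=[f"F{i}" for i in range(k)]),
            n_unfiltered_genes=5)

    def test_equal_and_doubled_means(self):
        scores = np.array([[2.0, 4.0], [2.0, 4.0], [2.0, 2.0], [2.0, 2.0]])
        model = self._model(scores)
        bias = cd4_cd8_bias(model, np.array([1, 1, 0, 0], bool),
                            np.array([0, 0, 1, 1], bool))
        assert bias["F0"] == 0.0
        assert bias["F1"] == 1.0

    def test_matches_direct_formula_on_random_fixture(self):
        rng = np.random.default_rng(6)
        scores = rng.uniform(0.1, 5, size=(30, 4))
        cd4 = np.zeros(30, bool)
        cd4[:12] = True
        model = self._model(scores)
        bias = cd4_cd8_bias(model, cd4, ~cd4)
        expect = np.log2(scores[cd4].mean(0) / scores[~cd4].mean(0))
        assert bias.to_numpy() == pytest.approx(expect)

    def test_zero_mean_is_clamped(self):
        scores = np.array([[0.0, 1.0], [0.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        model = self._model(scores)
        bias = cd4_cd8_bias(model, np.array([1, 1, 0, 0], bool),
                            np.array([0, 0, 1, 1], bool))
        assert bias["F0"] == -10.0

    def test_overlapping_masks_rejected(self):
        model = self._model(np.ones((4, 2)))
        with pytest.raises(ValueError):
            cd4_cd8_bias(model, np.array([1, 1, 0, 0], bool),
                         np.array([1, 0, 1, 1], bool))


def test_ensemble_reconstruction_is_normalized_and_deterministic():
    counts = np.random.default_rng(8).poisson(2.0, size=(60, 40))
    mm = matrix_from_counts(counts)
    a = ensemble_reconstruction(mm, 3, seed=0, n_restarts=2)
    b = ensemble_reconstruction(mm, 3, seed=0, n_restarts=2)
    pd.testing.assert_frame_equal(a, b)
    assert a.sum(axis=1).to_numpy() == pytest.approx(np.ones(60))
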