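"""FST estimator vs hand-computed variance components, permutation
calibration, PCA vs SVD oracle, coancestry and clustering."""

import numpy as np
import pytest

from scallop_popgen.callset import MISSING
from scallop_popgen.coalescent import DemeConfig, DemographyEvent, simulate_genotype_matrix
from scallop_popgen.structure import (bonferroni_alpha, cluster_tree,
                                      coancestry_matrix, fst_permutation_test,
                                      fst_matrix, pca, weir_cockerham_fst)

from conftest import make_calls


def wc_theta_oracle(counts_a, counts_b):
    """Independent scalar transcription of the Weir-Cockerham (1984)
    variance components for one locus, two populations."""
    out_a = out_abc = 0.0
    (nA_AA, nA_Aa, nA_aa), (nB_AA, nB_Aa, nB_aa) = counts_a, counts_b
    n1 = nA_AA + nA_Aa + nA_aa
    n2 = nB_AA + nB_Aa + nB_aa
    p1 = (2 * nA_aa + nA_Aa) / (2 * n1)
    p2 = (2 * nB_aa + nB_Aa) / (2 * n2)
    h1 = nA_Aa / n1
    h2 = nB_Aa / n2
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = nbar / nc * (s2 - 1 / (nbar - 1)
                     * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a / (a + b + c)


def geno_from_counts(counts):
    nAA, nAa, naa = counts
    return [0] * nAA + [1] * nAa + [2] * naa


class TestWeirCockerham:
    def test_fixed_difference_is_one(self):
        geno = np.array([[0] * 4] * 5 + [[2] * 4] * 5)
        calls = make_calls(geno, populations=["A"] * 5 + ["B"] * 5)
        assert weir_cockerham_fst(calls, "A", "B") == pytest.approx(1.0)

    def test_panmictic_near_zero(self):
        rng = np.random.default_rng(0)
        geno = (rng.binomial(1, 0.3, (40, 10_000))
                + rng.binomial(1, 0.3, (40, 10_000)))
        calls = make_calls(geno, populations=["A"] * 20 + ["B"] * 20)
        assert abs(weir_cockerham_fst(calls, "A", "B")) < 0.01

    def test_matches_hand_computed_components(self):
        ca, cb = (8, 2, 0), (2, 2, 6)
        geno = np.array(geno_from_counts(ca) + geno_from_counts(cb))[:, None]
        calls = make_calls(geno, populations=["A"] * 10 + ["B"] * 10)
        assert weir_cockerham_fst(calls, "A", "B") == pytest.approx(
            wc_theta_oracle(ca, cb), abs=1e-10)

    def test_theta_monotone_in_divergence_time(self):
        ne = 5000.0
        thetas = []
        for t_factor in (0.02, 0.05, 0.12, 0.3, 0.7):
            t = t_factor * 2 * ne
            demes = [DemeConfig("X", 20, ne), DemeConfig("Y", 20, ne)]
            events = [DemographyEvent(t, "merge_demes", source="Y", dest="X")]
            geno, deme = simulate_genotype_matrix(demes, events, 10_000, 99)
            calls = make_calls(geno, populations=np.where(deme == 0, "X", "Y"))
            thetas.append(weir_cockerham_fst(calls, "X", "Y"))
        assert thetas == sorted(thetas)

    def test_missing_population_rejected(self):
        calls = make_calls(np.zeros((4, 3)), populations=["A"] * 4)
        with pytest.raises(ValueError):
            weir_cockerham_fst(calls, "A", "B")


class TestPermutationTest:
    def test_strong_divergence_minimal_p(self):
        rng = np.random.default_rng(1)
        pa = rng.binomial(2, 0.05, (15, 400))
        pb = rng.binomial(2, 0.95, (15, 400))
        calls = make_calls(np.vstack([pa, pb]),
                           populations=["A"] * 15 + ["B"] * 15)
        p = fst_permutation_test(calls, "A", "B", n_perm=200, rng_seed=0)
        assert p == pytest.approx(1 / 201)

    def test_null_p_super_uniform(self):
        # identical populations: P(p <= alpha) <= alpha + 2 SE
        rng = np.random.default_rng(2)
        alpha, n_rep = 0.1, 200
        hits = 0
        for rep in range(n_rep):
            geno = (rng.binomial(1, 0.4, (16, 60))
                    + rng.binomial(1, 0.4, (16, 60)))
            calls = make_calls(geno, populations=["A"] * 8 + ["B"] * 8)
            p = fst_permutation_test(calls, "A", "B", n_perm=49, rng_seed=rep)
            hits += p <= alpha
        se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert hits / n_rep <= alpha + 2 * se

    def test_zero_permutations_rejected(self):
        calls = make_calls(np.zeros((4, 3)), populations=["A"] * 2 + ["B"] * 2)
        with pytest.raises(ValueError):
            fst_permutation_test(calls, "A", "B", n_perm=0)


class TestBonferroni:
    def test_pair_counts(self):
        assert bonferroni_alpha(91) == pytest.approx(0.05 / 91)   # C(14,2)
        assert bonferroni_alpha(78) == pytest.approx(0.000641, abs=1e-6)
        assert bonferroni_alpha(1) == 0.05

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0)


class TestPca:
    def test_two_blocks_separate_on_pc1(self):
        geno = np.array([[0] * 6] * 4 + [[2] * 6] * 4)
        calls = make_calls(geno)
        res = pca(calls, n_components=3)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)
        assert np.sign(res.scores[:4, 0]).tolist() != np.sign(res.scores[4:, 0]).tolist()

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(3)
        geno = rng.integers(0, 3, (5, 8))
        calls = make_calls(geno)
        res = pca(calls, n_components=4)
        g = geno - geno.mean(axis=0)
        u, s, vt = np.linalg.svd(g.astype(float), full_matrices=False)
        for k in range(4):
            ours = res.scores[:, k]
            ref = u[:, k] * s[k]
            assert (np.allclose(ours, ref, atol=1e-8)
                    or np.allclose(ours, -ref, atol=1e-8))

    def test_duplicate_rows_equal_scores(self):
        rng = np.random.default_rng(4)
        base = rng.integers(0, 3, (3, 10))
        geno = np.vstack([base, base[0]])
        res = pca(make_calls(geno), n_components=2)
        assert np.allclose(res.scores[0], res.scores[3], atol=1e-10)

    def test_variance_ratios_sorted_and_bounded(self, small_dataset):
        res = pca(small_dataset.calls, n_components=6)
        evr = res.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert 0 < evr.sum() <= 1 + 1e-12


class TestCoancestry:
    def test_identical_and_opposite(self):
        geno = np.array([[0, 2, 1], [0, 2, 1], [2, 0, 1]])
        sim = coancestry_matrix(make_calls(geno))
        assert sim[0, 1] == pytest.approx(1.0)
        assert sim[0, 2] == pytest.approx(1 / 3)  # (0, 0, 1) shared halves

    def test_het_vs_hom_is_half(self):
        sim = coancestry_matrix(make_calls(np.array([[1], [0]])))
        assert sim[0, 1] == pytest.approx(0.5)

    def test_no_cotyped_pair_flagged(self):
        geno = np.array([[0, MISSING], [MISSING, 2]])
        sim = coancestry_matrix(make_calls(geno))
        assert np.isnan(sim[0, 1])


class TestClusterTree:
    def test_identical_pair_merges_first(self):
        geno = np.array([[0, 0, 2, 2], [0, 0, 2, 2], [2, 2, 0, 0]])
        sim = coancestry_matrix(make_calls(geno))
        tree = cluster_tree(sim, ["a", "b", "c"])
        assert tree.linkage[0, :2].tolist() == [0, 1]
        assert tree.newick().count("(") == 2

    def test_missing_entries_rejected(self):
        sim = np.array([[1.0, np.nan], [np.nan, 1.0]])
        with pytest.raises(ValueError):
            cluster_tree(sim)

    def test_lineages_cluster_together(self, small_dataset):
        calls = small_dataset.calls
        sim = coancestry_matrix(calls)
        tree = cluster_tree(np.nan_to_num(sim, nan=0.0), list(calls.individuals))
        # JAC individuals form one clade in the UPGMA tree: check via
        # cophenetic distances being smaller within JAC than across species
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform
        coph = squareform(cophenet(tree.linkage))
        jac = np.array([p.startswith("MPJ") for p in calls.individuals])
        within = coph[np.ix_(jac, jac)][np.triu_indices(jac.sum(), 1)]
        across = coph[np.ix_(jac, ~jac)]
        assert within.max() < across.min()


def test_fst_matrix_shape_and_alpha(small_dataset):
    m = fst_matrix(small_dataset.calls, n_perm=30, rng_seed=0)
    k = len(m.populations)
    assert m.theta.shape == (k, k)
    assert np.allclose(m.theta, m.theta.T, equal_nan=True)
    assert m.corrected_alpha == pytest.approx(0.05 / (k * (k - 1) / 2))
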