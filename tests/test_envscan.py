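"""Association scans: BH against brute force, latent-factor calibration,
Omega structure, Bayes factors vs closed form, consensus bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from scallop_popgen.envscan import (CHI2_MEDIAN, bayes_factor_scan,
                                    consensus_candidates, estimate_omega,
                                    latent_factor_scan,
                                    population_allele_frequencies,
                                    rank_env_importance)

from conftest import make_calls


def bh_bruteforce(pvals, alpha):
    """Step-up rule written out directly: reject the largest k with
    p_(k) <= k alpha / n, and everything below it."""
    n = len(pvals)
    order = np.argsort(pvals)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= rank * alpha / n:
            k_max = rank
    reject = np.zeros(n, dtype=bool)
    reject[order[:k_max]] = True
    return reject


class TestBenjaminiHochberg:
    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20),
           st.sampled_from([0.01, 0.05, 0.2]))
    def test_matches_bruteforce_step_up(self, pvals, alpha):
        p = np.asarray(pvals)
        ours = multipletests(p, alpha=alpha, method="fdr_bh")[0]
        assert np.array_equal(ours, bh_bruteforce(p, alpha))


def pop_calls(freqs, n_per_pop=20, n_loci=None, seed=0, pops=None):
    """Populations with given per-locus allele frequency rows."""
    rng = np.random.default_rng(seed)
    freqs = np.atleast_2d(freqs)
    P, L = freqs.shape
    geno = np.vstack([rng.binomial(2, freqs[i], size=(n_per_pop, L))
                      for i in range(P)])
    labels = pops or [f"pop{i}" for i in range(P)]
    return make_calls(geno, populations=np.repeat(labels, n_per_pop))


class TestLatentFactorScan:
    def test_global_null_rarely_rejects(self):
        # unstructured genotypes, env orthogonal to them: BH at alpha=0.01
        # yields zero rejections in nearly all replicates
        n_hits = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            geno = rng.binomial(2, 0.3, (60, 400))
            calls = make_calls(geno)
            env = rng.normal(size=60)
            scan = latent_factor_scan(calls, env, K=1, n_runs=2,
                                      rng_seed=seed)
            n_hits += scan.flags.any()
        assert n_hits <= 3  # >= 95% of seeds with zero rejections

    def test_k0_equals_simple_regression_oracle(self):
        rng = np.random.default_rng(1)
        geno = rng.binomial(2, 0.4, (50, 30)).astype(float)
        env = rng.normal(size=50)
        calls = make_calls(geno)
        scan = latent_factor_scan(calls, env, K=0, n_runs=1, rng_seed=0)
        x = (env - env.mean()) / env.std()
        X = np.column_stack([np.ones(50), x])
        for j in range(30):
            beta, res, *_ = np.linalg.lstsq(X, geno[:, j], rcond=None)
            resid = geno[:, j] - X @ beta
            s2 = (resid ** 2).sum() / (50 - 2)
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
            assert scan.z[j] == pytest.approx(beta[1] / se, abs=1e-8)

    def test_lambda_near_one_for_standard_normal_z(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=10_000)
        lam = np.median(z ** 2) / CHI2_MEDIAN
        assert 0.8 < lam < 1.2

    def test_constant_env_rejected(self):
        calls = make_calls(np.random.default_rng(0).binomial(2, .5, (10, 5)))
        with pytest.raises(ValueError):
            latent_factor_scan(calls, np.ones(10))

    def test_strong_spiked_loci_detected(self):
        # mechanics check on a small design with a strong spike; the
        # default-conditions power experiment lives in the acceptance suite
        from conftest import small_design
        from scallop_popgen.simulate import generate_dataset
        ds = generate_dataset(small_design(n_per_pop=15, adaptive_effect=0.35,
                                           missing_rate=0.0, seed=9))
        calls = ds.calls
        pop_series = pd.Series(list(calls.populations), index=calls.individuals)
        flags = np.zeros(calls.n_loci, dtype=bool)
        for vi, var in enumerate(("sst_mean", "doc_mean")):
            env_ind = ds.env.loc[pop_series, var].to_numpy()
            scan = latent_factor_scan(calls, env_ind, K=3, n_runs=3,
                                      rng_seed=5 + vi)
            flags |= scan.flags
        truth = np.isin(calls.locus_ids, ds.truth["adaptive_loci"])
        assert flags[truth].mean() >= 0.8
        assert flags[~truth].mean() <= 0.01


class TestOmega:
    def test_exchangeable_structure_under_panmixia(self):
        # P populations drawn from a common pool: standardized frequencies
        # have the exchangeable covariance with off-diagonal ~ -1/P of the
        # diagonal (centering constraint)
        rng = np.random.default_rng(3)
        P, L = 8, 4000
        f = rng.uniform(0.1, 0.9, L)
        freqs = np.clip(f + rng.normal(0, 0.03, (P, L)), 0.01, 0.99)
        calls = pop_calls(freqs, n_per_pop=15, seed=4)
        omega = estimate_omega(calls)
        diag = np.diag(omega).mean()
        off = omega[~np.eye(P, dtype=bool)]
        # centering makes rows of standardized frequencies sum to zero, so
        # each Omega row sums to ~0: mean off-diagonal = -diag/(P-1)
        expected_off = -diag / (P - 1)
        assert off.mean() == pytest.approx(expected_off,
                                           abs=3 * off.std() / np.sqrt(off.size))

    def test_duplicated_populations_match(self):
        rng = np.random.default_rng(5)
        freqs = rng.uniform(0.2, 0.8, (3, 2000))
        freqs = np.vstack([freqs, freqs[0]])  # pop3 duplicates pop0
        calls = pop_calls(freqs, n_per_pop=400, seed=6)
        omega = estimate_omega(calls)
        assert omega[0, 1] == pytest.approx(omega[3, 1], abs=0.05)
        assert omega[0, 2] == pytest.approx(omega[3, 2], abs=0.05)

    def test_single_population_positive_scalar(self):
        calls = pop_calls(np.random.default_rng(7).uniform(0.2, 0.8, (1, 100)))
        omega = estimate_omega(calls)
        assert omega.shape == (1, 1) and omega[0, 0] > 0

    def test_monomorphic_only_rejected(self):
        calls = make_calls(np.zeros((10, 5)),
                           populations=["a"] * 5 + ["b"] * 5)
        with pytest.raises(ValueError):
            estimate_omega(calls)


class TestBayesFactorScan:
    def make_env(self, pops, values):
        return pd.Series(values, index=pops)

    def test_collinear_locus_strong_evidence(self):
        rng = np.random.default_rng(8)
        P = 14
        x = np.linspace(-1.5, 1.5, P)
        base = rng.uniform(0.3, 0.7, (P, 300))
        freqs = base.copy()
        freqs[:, 0] = np.clip(0.5 + 0.3 * x, 0.02, 0.98)  # collinear locus
        calls = pop_calls(freqs, n_per_pop=25, seed=9)
        pops, _, _ = population_allele_frequencies(calls)
        scan = bayes_factor_scan(calls, self.make_env(pops, x))
        assert scan.bf_db[0] > 10.0

    def test_null_loci_rarely_exceed_threshold(self):
        rng = np.random.default_rng(10)
        P, L = 10, 10_000
        freqs = rng.uniform(0.2, 0.8, (P, L))
        calls = pop_calls(freqs, n_per_pop=20, seed=11)
        pops, _, _ = population_allele_frequencies(calls)
        x = rng.normal(size=P)
        scan = bayes_factor_scan(calls, self.make_env(pops, x))
        assert scan.flags.mean() <= 0.05

    def test_affine_env_rescaling_invariant(self):
        rng = np.random.default_rng(12)
        freqs = rng.uniform(0.2, 0.8, (6, 200))
        calls = pop_calls(freqs, n_per_pop=15, seed=13)
        pops, _, _ = population_allele_frequencies(calls)
        x = rng.normal(size=6)
        a = bayes_factor_scan(calls, self.make_env(pops, x))
        b = bayes_factor_scan(calls, self.make_env(pops, 3.5 * x - 11.0))
        assert np.allclose(a.bf_db, b.bf_db, atol=1e-8)

    def test_matches_closed_form_oracle(self):
        # with a N(0, sd^2) slope prior the marginal likelihood is Gaussian:
        # BF = exp(m^2 sd^2 / (2 (1 + sd^2 s))) / sqrt(1 + sd^2 s)
        rng = np.random.default_rng(14)
        freqs = rng.uniform(0.2, 0.8, (8, 50))
        calls = pop_calls(freqs, n_per_pop=30, seed=15)
        pops, y, poly = __import__("scallop_popgen.envscan", fromlist=["x"])._standardized_freqs(calls)
        x = rng.normal(size=8)
        omega = estimate_omega(calls)
        scan = bayes_factor_scan(calls, self.make_env(pops, x), omega=omega)
        xs = (x - x.mean()) / x.std()
        oi = np.linalg.inv(omega)
        s = xs @ oi @ xs
        for j in range(10):
            m = xs @ oi @ y[:, j]
            bf = np.exp(m ** 2 / (2 * (1 + s))) / np.sqrt(1 + s)
            assert scan.bf_db[j] == pytest.approx(10 * np.log10(bf), abs=1e-3)

    def test_bf_monotone_in_effect_size(self):
        # mean BF over replicate loci increases strictly with the simulated
        # environmental slope (5-point grid)
        rng = np.random.default_rng(16)
        P, reps = 12, 40
        x = np.linspace(-1.5, 1.5, P)
        effects = [0.0, 0.05, 0.1, 0.2, 0.3]
        cols = []
        for e in effects:
            base = rng.uniform(0.35, 0.65, reps)
            cols.append(np.clip(base[None, :] + e * x[:, None], 0.02, 0.98))
        freqs = np.hstack(cols)
        calls = pop_calls(freqs, n_per_pop=60, seed=17)
        pops, _, _ = population_allele_frequencies(calls)
        scan = bayes_factor_scan(calls, self.make_env(pops, x))
        means = [scan.bf_db[i * reps:(i + 1) * reps].mean()
                 for i in range(len(effects))]
        assert means == sorted(means)


class TestImportanceRanking:
    def test_driver_ranks_first(self, small_dataset):
        ds = small_dataset
        imp = rank_env_importance(ds.calls, ds.env, rng_seed=0)
        assert imp.iloc[0]["variable"] in ("sst_mean", "doc_mean", "latitude",
                                           "sbt_mean", "doc_min", "doc_max",
                                           "sst_min", "sst_max")
        # the two spiked drivers score above the pure-noise chlorophyll stats
        chl = imp.set_index("variable")["importance"]
        assert chl["sst_mean"] > chl["chlorophyll_mean"]
        assert chl["doc_mean"] > chl["chlorophyll_mean"]

    def test_duplicated_variable_identical_importance(self, small_dataset):
        env = small_dataset.env.copy()
        env["sst_copy"] = env["sst_mean"]
        imp = rank_env_importance(small_dataset.calls, env, rng_seed=1)
        s = imp.set_index("variable")["importance"]
        assert s["sst_copy"] == pytest.approx(s["sst_mean"])

    def test_constant_variable_zero_importance(self, small_dataset):
        env = small_dataset.env.copy()
        env["flat"] = 1.0
        with pytest.warns(UserWarning):
            imp = rank_env_importance(small_dataset.calls, env, rng_seed=2)
        assert imp.set_index("variable")["importance"]["flat"] == 0.0


class TestConsensus:
    def test_intersection(self):
        cons = consensus_candidates({"latent": {"v": {1, 2}},
                                     "covariance": {"v": {2, 3}}})
        assert cons.consensus == {2}

    def test_disjoint_methods_empty(self):
        cons = consensus_candidates({"latent": {"v": {1}},
                                     "covariance": {"v": {2}}})
        assert cons.consensus == set()

    def test_union_over_variables_and_overlap_counts(self):
        sets = {"latent": {"doc": {"a", "b"}, "sst": {"a", "c"}},
                "covariance": {"doc": {"a"}, "sst": {"c", "d"}}}
        cons = consensus_candidates(sets)
        assert cons.method_sets["latent"] == {"a", "b", "c"}
        assert cons.consensus == {"a", "c"}
        counts = cons.overlap_counts("latent")
        assert counts == {"both": 1, "doc_only": 1, "sst_only": 1}

    def test_order_independent_and_idempotent(self):
        sets = {"latent": {"v": {1, 2, 3}}, "covariance": {"v": {2, 3}}}
        c1 = consensus_candidates(sets)
        c2 = consensus_candidates(dict(reversed(list(sets.items()))))
        assert c1.consensus == c2.consensus
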