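"""Filter chain: threshold strictness, HWE exact test vs enumeration
oracle, LD pruning, idempotence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scallop_popgen.callset import MISSING
from scallop_popgen.qc import (QcConfig, filter_biallelic_snps,
                               filter_individual_missingness, filter_maf,
                               filter_max_depth, filter_site_call_rate,
                               genotype_r2, hwe_exact_test, hwe_filter,
                               ld_prune, mask_low_quality_calls, run_qc)

from conftest import make_calls


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Independent route: enumerate every genotype-count configuration with
    the observed allele counts and accumulate multinomial probabilities of
    those no more probable than the observed one."""
    n = n_AA + n_Aa + n_aa
    na = 2 * n_aa + n_Aa  # copies of the 'a' allele
    configs = []
    for h in range(na % 2, min(na, 2 * n - na) + 1, 2):
        aa = (na - h) // 2
        AA = n - h - aa
        if AA < 0:
            continue
        # number of allele pairings giving (AA, h, aa), up to normalization
        w = (math.factorial(n) // (math.factorial(AA) * math.factorial(h)
                                   * math.factorial(aa))) * 2 ** h
        configs.append((h, w))
    total = sum(w for _, w in configs)
    p_obs = dict(configs)[n_Aa] / total
    return sum(w for _, w in configs if w / total <= p_obs * (1 + 1e-12)) / total


class TestHweExactTest:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(7, 0, 0) == 1.0

    def test_two_het_two_diploids(self):
        # alleles 2A/2a in 2 diploids: P(het=2)=2/3 > P(het=0)=1/3, so the
        # observed all-het configuration has cumulative p = 1
        assert hwe_exact_test(0, 2, 0) == pytest.approx(1.0)
        assert hwe_exact_test(1, 0, 1) == pytest.approx(1 / 3)

    def test_extreme_het_deficit(self):
        assert hwe_exact_test(50, 0, 50) < 1e-6

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 0)

    @settings(max_examples=150, deadline=None)
    @given(st.integers(0, 10), st.integers(0, 10), st.integers(0, 10))
    def test_matches_enumeration_oracle(self, a, h, b):
        if a + h + b == 0 or a + h + b > 10:
            return
        assert hwe_exact_test(a, h, b) == pytest.approx(
            hwe_enumeration_oracle(a, h, b), abs=1e-10)

    def test_symmetric_under_allele_swap(self):
        assert hwe_exact_test(6, 2, 1) == pytest.approx(hwe_exact_test(1, 2, 6))


class TestIndividualFilters:
    def test_biallelic_keeps_only_snps(self):
        calls = make_calls(np.zeros((2, 4)), n_alleles=np.array([2, 3, 2, 2]),
                           is_indel=np.array([False, False, True, False]))
        out = filter_biallelic_snps(calls)
        assert out.locus_ids.tolist() == ["snp000000", "snp000003"]

    def test_low_quality_mask_is_strict(self):
        geno = np.array([[0, 1, 2]])
        dp = np.array([[5, 6, 6]])
        gq = np.array([[9, 5, 6]])
        out = mask_low_quality_calls(make_calls(geno, depth=dp, qual=gq))
        # DP=5 masked, GQ=5 masked, DP=6/GQ=6 kept
        assert out.genotypes.tolist() == [[MISSING, MISSING, 2]]

    def test_call_rate_at_threshold_kept(self):
        geno = np.zeros((10, 3), dtype=int)
        geno[:2, 0] = MISSING   # 80% exactly -> kept
        geno[:3, 1] = MISSING   # 70% -> dropped
        out = filter_site_call_rate(make_calls(geno))
        assert out.n_loci == 2
        assert "snp000001" not in out.locus_ids

    def test_max_depth_cap_strict(self):
        geno = np.zeros((4, 3), dtype=int)
        depth = np.tile(np.array([[28, 29, 5]]), (4, 1))
        out = filter_max_depth(make_calls(geno, depth=depth, qual=depth), cap=28.0)
        assert out.locus_ids.tolist() == ["snp000000", "snp000002"]
        with pytest.raises(ValueError):
            filter_max_depth(make_calls(geno, depth=depth, qual=depth), cap=0.0)

    def test_individual_missingness_strict(self):
        geno = np.zeros((3, 10), dtype=int)
        geno[0, :2] = MISSING  # 20% exactly -> kept
        geno[1, :3] = MISSING  # 30% -> dropped
        out = filter_individual_missingness(make_calls(geno))
        assert out.n_individuals == 2
        with pytest.raises(ValueError):
            filter_individual_missingness(
                make_calls(np.full((2, 4), MISSING)))

    def test_maf_threshold(self):
        # 100 diploids, one heterozygote -> MAF 1/200 = 0.005 -> removed
        geno = np.zeros((100, 3), dtype=int)
        geno[0, 0] = 1
        geno[:2, 1] = 1; geno[2, 1] = 2  # MAF 4/200 = 0.02 -> kept
        out = filter_maf(make_calls(geno))
        assert out.locus_ids.tolist() == ["snp000001"]  # monomorphic also gone


class TestHweFilter:
    def test_conforming_dataset_unchanged(self):
        rng = np.random.default_rng(0)
        p = 0.4
        geno = rng.binomial(1, p, (60, 20)) + rng.binomial(1, p, (60, 20))
        out = hwe_filter(make_calls(geno), alpha=1e-6)
        assert out.n_loci == 20

    def test_gross_violation_removed(self):
        geno = np.vstack([np.zeros((25, 1)), np.full((25, 1), 2)]).astype(int)
        out = hwe_filter(make_calls(geno))
        assert out.n_loci == 0

    def test_empty_locus_removed_with_warning(self):
        geno = np.array([[0, MISSING], [1, MISSING], [1, MISSING], [0, MISSING]])
        with pytest.warns(UserWarning):
            out = hwe_filter(make_calls(geno))
        assert out.n_loci == 1


class TestLdPrune:
    def test_duplicate_column_pruned_to_one(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, 30)
        b = rng.integers(0, 3, 30)
        geno = np.column_stack([a, a, b])
        out = ld_prune(make_calls(geno))
        assert out.n_loci == 2

    def test_independent_columns_untouched(self):
        rng = np.random.default_rng(2)
        geno = rng.binomial(2, 0.5, (200, 12))
        assert ld_prune(make_calls(geno)).n_loci == 12

    def test_three_identical_leave_exactly_one(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 3, 40)
        geno = np.column_stack([a, a, a])
        out = ld_prune(make_calls(geno))
        assert out.n_loci == 1

    def test_within_tag_rule(self):
        # two perfectly linked SNPs on one tag: one survives even if the
        # window ordering would not compare them
        rng = np.random.default_rng(4)
        a = rng.integers(0, 3, 50)
        geno = np.column_stack([a, 2 - a])
        calls = make_calls(geno, tags=np.array([7, 7]), tag_pos=np.array([0, 1]))
        assert ld_prune(calls).n_loci == 1

    def test_r2_symmetric_and_label_swap_invariant(self):
        rng = np.random.default_rng(5)
        geno = rng.integers(0, 3, (40, 6))
        r2 = genotype_r2(geno)
        assert np.allclose(r2, r2.T)
        flipped = geno.copy()
        flipped[:, 2] = 2 - flipped[:, 2]
        assert np.allclose(genotype_r2(flipped), r2, atol=1e-12)


class TestRunQc:
    def test_report_chains_counts(self, small_dataset):
        _, report = run_qc(small_dataset.calls)
        for prev, cur in zip(report.steps, report.steps[1:]):
            assert cur["loci_before"] == prev["loci_after"]
            assert cur["individuals_before"] == prev["individuals_after"]

    def test_idempotent(self, small_dataset):
        once, _ = run_qc(small_dataset.calls)
        twice, report2 = run_qc(once)
        assert twice.n_loci == once.n_loci
        assert twice.n_individuals == once.n_individuals

    def test_spiked_low_maf_loci_removed(self):
        # 100 diploids: a single heterozygote is MAF 1/200 = 0.005 < 0.01
        rng = np.random.default_rng(8)
        geno = rng.binomial(1, 0.4, (100, 40)) + rng.binomial(1, 0.4, (100, 40))
        geno[:, :5] = 0
        geno[0, :5] = 1
        dp = np.full(geno.shape, 20, dtype=int)
        spiked = make_calls(geno, depth=dp, qual=dp)
        out, _ = run_qc(spiked)
        assert not set(spiked.locus_ids[:5]) & set(out.locus_ids)
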