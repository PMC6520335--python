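"""Post-calling SNP and individual filter chain.

The chain reproduces a RAD-seq quality-control recipe on a raw genotype
call set, in this fixed order:

1. keep only biallelic SNP records (no indels)
2. mask calls with genotype quality or depth not strictly greater than 5
3. drop loci genotyped in fewer than 80% of individuals
4. drop loci whose mean depth exceeds twice the raw-dataset mean depth
   (putative paralogs)
5. drop individuals with more than 20% missing calls
6. drop loci with minor-allele frequency not strictly greater than 0.01
7. drop loci failing a Hardy-Weinberg exact test at alpha 0.05 (pooled
   sample by default; a population-stratified mode is available)
8. greedy windowed LD pruning at r^2 > 0.5, plus at most one SNP per RAD
   tag when within-tag r^2 exceeds the threshold

Thresholds follow the recipe's wording exactly: "greater than 5" and
"greater than 0.01" are strict, "at least 80%" is inclusive, "more than
20%" is strict.  All thresholds are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import warnings

import numpy as np
from scipy.special import gammaln

from .callset import MISSING, GenotypeCallSet

__all__ = [
    "QcConfig", "QcReport", "run_qc",
    "filter_biallelic_snps", "mask_low_quality_calls", "filter_site_call_rate",
    "filter_max_depth", "filter_individual_missingness", "filter_maf",
    "hwe_exact_test", "hwe_filter", "ld_prune", "genotype_r2",
]


@dataclass
class QcConfig:
    min_gq: int = 5
    min_dp: int = 5
    min_call_rate: float = 0.8
    max_depth_factor: float = 2.0
    max_individual_missing: float = 0.2
    min_maf: float = 0.01
    hwe_alpha: float = 0.05
    hwe_midp: bool = False
    hwe_by_population: bool = False
    ld_r2: float = 0.5
    ld_window: int = 50
    ld_step: int = 5


@dataclass
class QcReport:
    """Per-step bookkeeping: (step, loci before/after, individuals
    before/after, threshold used)."""

    steps: list[dict] = field(default_factory=list)

    def add(self, name: str, loci_before: int, loci_after: int,
            ind_before: int, ind_after: int, threshold) -> None:
        self.steps.append({
            "step": name,
            "loci_before": loci_before, "loci_after": loci_after,
            "individuals_before": ind_before, "individuals_after": ind_after,
            "threshold": threshold,
        })

    def to_tsv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.steps).to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.steps, fh, indent=1)


# ---------------------------------------------------------------------------
# individual filters
# ---------------------------------------------------------------------------


def filter_biallelic_snps(calls: GenotypeCallSet) -> GenotypeCallSet:
    """Keep only biallelic SNP records (drop indels and multi-allelics)."""
    keep = (calls.n_alleles == 2) & ~calls.is_indel
    return calls.take_loci(np.nonzero(keep)[0])


def mask_low_quality_calls(calls: GenotypeCallSet, min_gq: int = 5,
                           min_dp: int = 5) -> GenotypeCallSet:
    """Set calls with GQ <= min_gq or DP <= min_dp to missing (strict >)."""
    if calls.depth is None or calls.qual is None:
        return calls
    bad = (calls.depth <= min_dp) | (calls.qual <= min_gq)
    geno = calls.genotypes.copy()
    geno[bad] = MISSING
    out = calls.take_loci(np.arange(calls.n_loci))  # shallow copy of metadata
    out.genotypes = geno
    return out


def filter_site_call_rate(calls: GenotypeCallSet, min_rate: float = 0.8) -> GenotypeCallSet:
    """Drop loci genotyped in fewer than ``min_rate`` of individuals
    (a call rate exactly at the threshold is kept)."""
    keep = calls.call_rate() >= min_rate
    return calls.take_loci(np.nonzero(keep)[0])


def filter_max_depth(calls: GenotypeCallSet, cap: float) -> GenotypeCallSet:
    """Drop loci whose mean depth (over called genotypes) exceeds ``cap``.

    The cap is computed by the caller on the raw, pre-filter dataset
    (conventionally twice its mean depth); a locus exactly at the cap is
    kept (strict >).
    """
    if cap <= 0:
        raise ValueError("depth cap must be > 0")
    if calls.depth is None:
        return calls
    typed = calls.genotypes != MISSING
    with np.errstate(invalid="ignore"):
        mean_dp = np.where(typed, calls.depth, 0).sum(axis=0) / typed.sum(axis=0)
    keep = ~(mean_dp > cap)
    return calls.take_loci(np.nonzero(keep)[0])


def filter_individual_missingness(calls: GenotypeCallSet,
                                  max_missing: float = 0.2) -> GenotypeCallSet:
    """Drop individuals with strictly more than ``max_missing`` missing."""
    frac = calls.missing_mask().mean(axis=1)
    keep = np.nonzero(frac <= max_missing)[0]
    if keep.size == 0:
        raise ValueError(
            f"all {calls.n_individuals} individuals exceed {max_missing:.0%} "
            f"missingness (min observed {frac.min():.1%})")
    return calls.take_individuals(keep)


def filter_maf(calls: GenotypeCallSet, min_maf: float = 0.01) -> GenotypeCallSet:
    """Drop loci with minor-allele frequency <= ``min_maf`` (strict >),
    computed over non-missing calls across all retained individuals."""
    maf = calls.maf()
    keep = maf > min_maf
    keep &= ~np.isnan(maf)
    return calls.take_loci(np.nonzero(keep)[0])


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def _hwe_het_logprobs(n_minor: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Log-probabilities of heterozygote counts conditional on allele counts.

    For ``n`` diploids carrying ``n_minor`` copies of the minor allele, the
    heterozygote count ``h`` has the same parity as ``n_minor`` and
    probability proportional to ``n! 2^h / (h! n_AA! n_aa!)``.
    """
    hs = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    n_aa = (n_minor - hs) // 2
    n_AA = n - hs - n_aa
    logw = (hs * np.log(2.0) - gammaln(hs + 1) - gammaln(n_aa + 1)
            - gammaln(n_AA + 1))
    logw -= logw.max()
    w = np.exp(logw)
    return hs, w / w.sum()


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int, midp: bool = False) -> float:
    """Two-sided exact Hardy-Weinberg test (conditional on allele counts).

    The p-value sums the probabilities of all heterozygote configurations
    no more probable than the observed one.  ``midp`` halves the
    contribution of the observed configuration.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype counts")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes")
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    hs, probs = _hwe_het_logprobs(n_minor, n)
    p_obs = probs[hs == n_Aa][0]
    mask = probs <= p_obs * (1 + 1e-12)
    p = probs[mask].sum()
    if midp:
        p -= 0.5 * p_obs
    return float(min(1.0, p))


def hwe_filter(calls: GenotypeCallSet, alpha: float = 0.05, midp: bool = False,
               by_population: bool = False) -> GenotypeCallSet:
    """Drop loci with exact HWE p < alpha.

    By default the test pools all retained individuals (Wahlund effects on
    structured data will inflate rejections; a stratified mode testing
    within each population and taking the minimum Bonferroni-adjusted p is
    available).
    """
    def pooled_p(geno: np.ndarray) -> np.ndarray:
        out = np.ones(geno.shape[1])
        nAA = (geno == 0).sum(axis=0)
        nAa = (geno == 1).sum(axis=0)
        naa = (geno == 2).sum(axis=0)
        for j in range(geno.shape[1]):
            if nAA[j] + nAa[j] + naa[j] == 0:
                out[j] = np.nan
            else:
                out[j] = hwe_exact_test(int(nAA[j]), int(nAa[j]), int(naa[j]),
                                        midp=midp)
        return out

    if by_population:
        pops = calls.population_indices()
        pvals = np.ones(calls.n_loci)
        for idx in pops.values():
            p = pooled_p(calls.genotypes[idx])
            pvals = np.fmin(pvals, np.minimum(1.0, p * len(pops)))
    else:
        pvals = pooled_p(calls.genotypes)
    empty = np.isnan(pvals)
    if empty.any():
        warnings.warn(f"{int(empty.sum())} loci with no genotype calls removed")
    keep = ~empty & ~(pvals < alpha)
    return calls.take_loci(np.nonzero(keep)[0])


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def genotype_r2(geno: np.ndarray) -> np.ndarray:
    """Pairwise squared genotype correlation of a dosage block.

    Missing calls are mean-imputed per locus before correlating; the
    result is symmetric and invariant to swapping allele labels (0<->2).
    """
    g = geno.astype(float)
    miss = geno == MISSING
    if miss.any():
        with np.errstate(invalid="ignore"):
            mu = np.where(miss, np.nan, g)
            mu = np.nanmean(mu, axis=0)
        mu = np.where(np.isnan(mu), 0.0, mu)
        g = np.where(miss, mu[None, :], g)
    g = g - g.mean(axis=0)
    denom = np.sqrt((g ** 2).sum(axis=0))
    denom[denom == 0] = np.nan
    with np.errstate(invalid="ignore"):
        r = (g.T @ g) / np.outer(denom, denom)
    return np.nan_to_num(r, nan=0.0) ** 2


def ld_prune(calls: GenotypeCallSet, r2_threshold: float = 0.5,
             window: int = 50, step: int = 5) -> GenotypeCallSet:
    """Greedy windowed LD pruning on (tag, position)-ordered loci.

    Within each sliding window, for every pair with r^2 above the
    threshold the member with the lower call rate is removed (ties remove
    the higher locus index).  Additionally all pairs within one RAD tag
    are always compared, so at most one SNP per tag survives when
    within-tag r^2 exceeds the threshold.  Passes over the surviving loci
    repeat until no window removes anything, which makes the operation
    idempotent (windows always slide over the current survivor ordering).
    """
    order = np.lexsort((calls.tag_pos, calls.tags))
    calls = calls.take_loci(order)

    def one_pass(cur: GenotypeCallSet) -> np.ndarray:
        L = cur.n_loci
        alive = np.ones(L, dtype=bool)
        rate = cur.call_rate()

        def prune_block(idx: np.ndarray) -> None:
            sub = genotype_r2(cur.genotypes[:, idx])
            for a in range(len(idx)):
                ia = idx[a]
                if not alive[ia]:
                    continue
                for b in range(a + 1, len(idx)):
                    ib = idx[b]
                    if not alive[ib] or sub[a, b] <= r2_threshold:
                        continue
                    if rate[ia] < rate[ib]:
                        alive[ia] = False
                        break
                    alive[ib] = False

        tag_change = np.nonzero(np.diff(cur.tags))[0] + 1
        for block in np.split(np.arange(L), tag_change):
            if len(block) > 1:
                prune_block(block)
        start = 0
        while start < L:
            idx = np.arange(start, min(start + window, L))
            idx = idx[alive[idx]]
            if len(idx) > 1:
                prune_block(idx)
            if start + window >= L:
                break
            start += step
        return alive

    while True:
        alive = one_pass(calls)
        if alive.all():
            return calls
        calls = calls.take_loci(np.nonzero(alive)[0])


# ---------------------------------------------------------------------------
# the chain
# ---------------------------------------------------------------------------


def run_qc(calls: GenotypeCallSet, config: QcConfig | None = None
           ) -> tuple[GenotypeCallSet, QcReport]:
    """Apply the full filter chain in its canonical order."""
    cfg = config or QcConfig()
    report = QcReport()

    def record(name, before, after, threshold):
        report.add(name, before.n_loci, after.n_loci,
                   before.n_individuals, after.n_individuals, threshold)

    cur = calls
    nxt = filter_biallelic_snps(cur)
    record("biallelic_snps", cur, nxt, "2 alleles, no indels")
    cur = nxt

    # the depth cap references the raw mean depth of the biallelic dataset
    if cur.depth is not None:
        typed = cur.genotypes != MISSING
        raw_mean_depth = float(np.where(typed, cur.depth, 0).sum() / max(1, typed.sum()))
    else:
        raw_mean_depth = float("nan")

    nxt = mask_low_quality_calls(cur, cfg.min_gq, cfg.min_dp)
    record("mask_low_quality_calls", cur, nxt,
           f"GQ>{cfg.min_gq}, DP>{cfg.min_dp}")
    cur = nxt

    nxt = filter_site_call_rate(cur, cfg.min_call_rate)
    record("site_call_rate", cur, nxt, f">={cfg.min_call_rate:.0%}")
    cur = nxt

    if cur.depth is not None:
        cap = cfg.max_depth_factor * raw_mean_depth
        nxt = filter_max_depth(cur, cap)
        record("max_mean_depth", cur, nxt, f"<= {cap:.2f} (2 x raw mean)")
        cur = nxt

    nxt = filter_individual_missingness(cur, cfg.max_individual_missing)
    record("individual_missingness", cur, nxt,
           f"<= {cfg.max_individual_missing:.0%}")
    cur = nxt

    nxt = filter_maf(cur, cfg.min_maf)
    record("maf", cur, nxt, f"> {cfg.min_maf}")
    cur = nxt

    nxt = hwe_filter(cur, cfg.hwe_alpha, cfg.hwe_midp, cfg.hwe_by_population)
    record("hwe", cur, nxt, f"p >= {cfg.hwe_alpha}")
    cur = nxt

    nxt = ld_prune(cur, cfg.ld_r2, cfg.ld_window, cfg.ld_step)
    record("ld_prune", cur, nxt,
           f"r2 <= {cfg.ld_r2} (window {cfg.ld_window}, step {cfg.ld_step})")
    return nxt, report
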