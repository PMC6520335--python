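"""Genetic diversity statistics: rarefied polymorphic-locus counts (NPL),
multilocus heterozygosity (MLH), group ANOVA and latitude regression.

NPL is standardized across unequal sample sizes by repeatedly drawing
``k`` individuals (with replacement by default; the smallest population in
the study design has exactly ``k`` members, so without-replacement draws
would be constant there) and counting loci showing at least two alleles
among the subsample's non-missing calls.  MLH is the raw proportion of
typed loci at which an individual is heterozygous; the sMLH
standardization (heterozygosity divided by the mean heterozygosity of the
loci the individual was typed at) is available as an option.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .callset import MISSING, GenotypeCallSet

__all__ = ["npl_rarefied", "mlh", "smlh", "group_anova",
           "latitude_regression", "diversity_table"]


def _polymorphic_count(geno: np.ndarray) -> int:
    """Loci with >= 2 alleles observed among non-missing calls."""
    has_het = (geno == 1).any(axis=0)
    has_ref = (geno == 0).any(axis=0)
    has_alt = (geno == 2).any(axis=0)
    return int((has_het | (has_ref & has_alt)).sum())


def npl_rarefied(calls: GenotypeCallSet, population: str, k: int = 5,
                 n_draws: int = 1000, rng_seed: int = 0,
                 with_replacement: bool = True,
                 exhaustive: bool = False) -> tuple[float, float]:
    """Mean and SE of the polymorphic-locus count over rarefied subsamples.

    ``exhaustive=True`` enumerates every ordered draw instead of sampling
    (only sensible for tiny ``n^k``); with ``with_replacement=False`` and
    ``k`` equal to the population size the statistic equals the observed
    polymorphic-locus count exactly.
    """
    if k <= 0:
        raise ValueError("subsample size k must be > 0")
    idx = np.nonzero(calls.populations == population)[0]
    if idx.size == 0:
        raise ValueError(f"population {population!r} has no individuals")
    if not with_replacement and k > idx.size:
        raise ValueError("k exceeds population size for draws without replacement")
    geno = calls.genotypes[idx]
    if exhaustive:
        if not with_replacement:
            raise ValueError("exhaustive mode enumerates draws with replacement")
        counts = [
            _polymorphic_count(geno[list(draw)])
            for draw in product(range(idx.size), repeat=k)
        ]
        vals = np.array(counts, dtype=float)
        return float(vals.mean()), float(vals.std(ddof=0) / np.sqrt(len(vals)))
    rng = np.random.default_rng(rng_seed)
    vals = np.empty(n_draws)
    for d in range(n_draws):
        sub = rng.choice(idx.size, size=k, replace=with_replacement)
        vals[d] = _polymorphic_count(geno[sub])
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(n_draws))


def mlh(calls: GenotypeCallSet, individual: str) -> float:
    """Proportion of typed loci at which the individual is heterozygous."""
    ids = list(calls.individuals)
    g = calls.genotypes[ids.index(individual)]
    typed = g != MISSING
    if typed.sum() == 0:
        import warnings
        warnings.warn(f"{individual}: no typed loci, MLH undefined")
        return float("nan")
    return float((g[typed] == 1).mean())


def smlh(calls: GenotypeCallSet, individual: str) -> float:
    """Standardized MLH: observed heterozygosity divided by the mean
    population heterozygosity of the loci the individual was typed at."""
    ids = list(calls.individuals)
    i = ids.index(individual)
    g = calls.genotypes
    typed_i = g[i] != MISSING
    if typed_i.sum() == 0:
        return float("nan")
    typed = g != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        locus_het = np.where(typed, g == 1, False).sum(axis=0) / typed.sum(axis=0)
    expected = np.nanmean(locus_het[typed_i])
    if expected == 0:
        return float("nan")
    return float((g[i][typed_i] == 1).mean() / expected)


def group_anova(values, group_labels) -> tuple[float, float]:
    """One-way ANOVA F statistic and p-value across labelled groups."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs >= 2 values")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def latitude_regression(per_pop_statistic, latitudes) -> tuple[float, float]:
    """OLS of a per-population statistic on latitude; returns (r^2, p)."""
    y = np.asarray(per_pop_statistic, dtype=float)
    x = np.asarray(latitudes, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 populations")
    if np.allclose(x, x[0]):
        raise ValueError("latitude is constant")
    res = stats.linregress(x, y)
    return float(res.rvalue ** 2), float(res.pvalue)


def diversity_table(calls: GenotypeCallSet, k: int = 5, n_draws: int = 1000,
                    rng_seed: int = 0) -> pd.DataFrame:
    """Per-population summary mirroring a sampling-design table:
    MLH mean/SE, rarefied NPL mean/SE and the observed (uncorrected)
    polymorphic-locus count."""
    rows = []
    ss = np.random.SeedSequence(rng_seed)
    pops = list(pd.unique(calls.populations))
    seeds = ss.generate_state(len(pops))
    for pop, seed in zip(pops, seeds):
        idx = np.nonzero(calls.populations == pop)[0]
        mlhs = np.array([mlh(calls, ind) for ind in calls.individuals[idx]])
        npl_mean, npl_se = npl_rarefied(calls, pop, k=k, n_draws=n_draws,
                                        rng_seed=int(seed >> 1))
        rows.append({
            "population": pop,
            "n": idx.size,
            "mlh_mean": float(np.nanmean(mlhs)),
            "mlh_se": float(np.nanstd(mlhs, ddof=1) / np.sqrt(idx.size))
            if idx.size > 1 else float("nan"),
            "npl_mean": npl_mean,
            "npl_se": npl_se,
            "observed_polymorphic": _polymorphic_count(calls.genotypes[idx]),
        })
    return pd.DataFrame(rows).set_index("population")
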