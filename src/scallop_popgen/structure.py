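"""Population structure: Weir-Cockerham FST, permutation tests, PCA,
allele-sharing coancestry and a clustering tree.

The pairwise FST is the Weir & Cockerham (1984) two-population theta,
combined across loci as the ratio of summed variance components
``sum a / sum (a+b+c)``.  Significance comes from permuting individuals
between the two populations.  The coancestry matrix is a deliberately
simple allele-sharing similarity (mean proportion of shared alleles per
co-typed locus) — a transparent stand-in for haplotype-painting coancestry
methods, and labelled as such in outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .callset import MISSING, GenotypeCallSet

__all__ = [
    "weir_cockerham_fst", "fst_permutation_test", "bonferroni_alpha",
    "fst_matrix", "FstMatrix", "pca", "PcaResult", "coancestry_matrix",
    "cluster_tree", "ClusterTree",
]


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------


def _pop_locus_stats(geno: np.ndarray):
    """Per-locus (n typed, allele freq, het fraction) for one population."""
    typed = geno != MISSING
    n = typed.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(typed, geno, 0).sum(axis=0) / (2.0 * n)
        h = np.where(typed, geno == 1, False).sum(axis=0) / n
    return n, p, h


def _wc_components(n1, p1, h1, n2, p2, h2):
    """Weir-Cockerham (1984) a, b, c variance components, r=2 populations."""
    r = 2.0
    n_bar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * n_bar - (n1 ** 2 + n2 ** 2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        inner = p_bar * (1 - p_bar) - (r - 1.0) / r * s2
        a = (n_bar / nc) * (s2 - (inner - h_bar / 4.0) / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (inner - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar)
        c = h_bar / 2.0
    return a, b, c


def _theta_from_geno(g1: np.ndarray, g2: np.ndarray) -> float:
    n1, p1, h1 = _pop_locus_stats(g1)
    n2, p2, h2 = _pop_locus_stats(g2)
    ok = (n1 >= 1) & (n2 >= 1) & ((n1 + n2) > 2)
    if not ok.any():
        raise ValueError("no loci typed in both populations")
    a, b, c = _wc_components(n1[ok], p1[ok], h1[ok], n2[ok], p2[ok], h2[ok])
    good = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = (a[good] + b[good] + c[good]).sum()
    if denom == 0:
        return 0.0
    return float(a[good].sum() / denom)


def weir_cockerham_fst(calls: GenotypeCallSet, pop_a: str, pop_b: str) -> float:
    """Multi-locus Weir-Cockerham theta between two populations
    (ratio of summed components; may be slightly negative)."""
    pops = calls.population_indices()
    for p in (pop_a, pop_b):
        if p not in pops or len(pops[p]) < 2:
            raise ValueError(f"population {p!r} needs >= 2 individuals")
    return _theta_from_geno(calls.genotypes[pops[pop_a]],
                            calls.genotypes[pops[pop_b]])


def fst_permutation_test(calls: GenotypeCallSet, pop_a: str, pop_b: str,
                         n_perm: int = 1000, rng_seed: int = 0,
                         add_one: bool = True) -> float:
    """Permutation p-value for theta > 0.

    Individuals are shuffled between the two groups preserving sizes.  The
    default add-one convention ``p = (1 + #{theta_perm >= theta_obs}) /
    (n_perm + 1)`` never returns zero; ``add_one=False`` gives the plain
    ``#{>=}/n_perm`` convention.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pops = calls.population_indices()
    idx = np.concatenate([pops[pop_a], pops[pop_b]])
    na = len(pops[pop_a])
    geno = calls.genotypes[idx]
    theta_obs = _theta_from_geno(geno[:na], geno[na:])
    rng = np.random.default_rng(rng_seed)
    count = 0
    perm = np.arange(len(idx))
    for _ in range(n_perm):
        rng.shuffle(perm)
        t = _theta_from_geno(geno[perm[:na]], geno[perm[na:]])
        if t >= theta_obs:
            count += 1
    if add_one:
        return (1 + count) / (n_perm + 1)
    return count / n_perm


def bonferroni_alpha(n_tests: int, family_alpha: float = 0.05) -> float:
    """Table-wide Bonferroni-corrected per-test alpha."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return family_alpha / n_tests


@dataclass
class FstMatrix:
    populations: list[str]
    theta: np.ndarray        # symmetric, NaN diagonal
    pvalues: np.ndarray      # symmetric, NaN diagonal
    n_perm: int
    corrected_alpha: float

    def to_tsv(self, theta_path, pvalue_path) -> None:
        import pandas as pd
        pd.DataFrame(self.theta, index=self.populations,
                     columns=self.populations).to_csv(theta_path, sep="\t")
        pd.DataFrame(self.pvalues, index=self.populations,
                     columns=self.populations).to_csv(pvalue_path, sep="\t")


def fst_matrix(calls: GenotypeCallSet, n_perm: int = 1000, rng_seed: int = 0,
               family_alpha: float = 0.05) -> FstMatrix:
    """All pairwise thetas with permutation p-values and the Bonferroni
    alpha for the number of pairs actually tested."""
    pops = [p for p, idx in calls.population_indices().items() if len(idx) >= 2]
    k = len(pops)
    theta = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    ss = np.random.SeedSequence(rng_seed)
    seeds = ss.generate_state(k * k)
    pairs = list(combinations(range(k), 2))
    for i, j in pairs:
        theta[i, j] = theta[j, i] = weir_cockerham_fst(calls, pops[i], pops[j])
        p = fst_permutation_test(calls, pops[i], pops[j], n_perm,
                                 int(seeds[i * k + j] >> 1))
        pval[i, j] = pval[j, i] = p
    return FstMatrix(pops, theta, pval, n_perm,
                     bonferroni_alpha(len(pairs), family_alpha))


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    scores: np.ndarray               # (n_individuals, n_components)
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray             # (n_loci, n_components)


def pca(calls: GenotypeCallSet, n_components: int = 10) -> PcaResult:
    """PCA of the individual x locus dosage matrix.

    Missing dosages are mean-imputed per locus, columns centered, and the
    decomposition taken by SVD.  The sign of each component is fixed so
    that its largest-magnitude loading is positive.
    """
    if calls.n_individuals < 2 or calls.n_loci < 2:
        raise ValueError("PCA needs >= 2 individuals and >= 2 loci")
    g = calls.genotypes.astype(float)
    miss = calls.genotypes == MISSING
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(np.where(miss, np.nan, g), axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    g = np.where(miss, mu[None, :], g)
    g -= g.mean(axis=0)
    if not g.any():
        raise ValueError("zero-variance genotype matrix")
    u, s, vt = np.linalg.svd(g, full_matrices=False)
    n_components = min(n_components, len(s))
    total = (s ** 2).sum()
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    flip = np.sign(vt[np.arange(n_components),
                      np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    scores = u * s[None, :] * flip[None, :]
    return PcaResult(scores, s ** 2 / total, vt.T)


# ---------------------------------------------------------------------------
# allele-sharing coancestry and clustering
# ---------------------------------------------------------------------------


def coancestry_matrix(calls: GenotypeCallSet,
                      locus_index: np.ndarray | None = None) -> np.ndarray:
    """Mean allele-sharing similarity per individual pair.

    For dosages ``a, b`` the per-locus similarity is ``1 - |a-b|/2``
    (identical genotypes 1, het vs hom 0.5, opposite homozygotes 0),
    averaged over co-typed loci.  Pairs with no co-typed locus are NaN.
    This is a simplified coancestry surrogate, not a haplotype-painting
    posterior.
    """
    if calls.n_individuals < 2:
        raise ValueError("need >= 2 individuals")
    g = calls.genotypes
    if locus_index is not None:
        g = g[:, locus_index]
    typed = (g != MISSING).astype(np.float64)
    gf = np.where(g == MISSING, 0, g).astype(np.float64)
    # |a-b| = (a-b)^2 - 2*[one hom-ref, other hom-alt]
    # computed with indicator matmuls over co-typed loci
    n_cotyped = typed @ typed.T
    sq = (gf ** 2 * typed) @ typed.T
    cross = (gf * typed) @ (gf * typed).T
    sum_d2 = sq + sq.T - 2 * cross
    i0 = ((g == 0).astype(np.float64))
    i2 = ((g == 2).astype(np.float64))
    opp = i0 @ i2.T
    sum_abs = sum_d2 - 2 * (opp + opp.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = 1.0 - 0.5 * sum_abs / n_cotyped
    return sim


@dataclass
class ClusterTree:
    linkage: np.ndarray
    labels: list[str]

    def newick(self) -> str:
        from scipy.cluster.hierarchy import to_tree

        def rec(node):
            if node.is_leaf():
                return self.labels[node.id]
            left, right = node.get_left(), node.get_right()
            dl = node.dist - left.dist
            dr = node.dist - right.dist
            return f"({rec(left)}:{dl / 2:.6g},{rec(right)}:{dr / 2:.6g})"

        return rec(to_tree(self.linkage)) + ";"


def cluster_tree(similarity: np.ndarray, labels: list[str] | None = None) -> ClusterTree:
    """UPGMA dendrogram on 1 - similarity (ultrametric heights).

    Distance ties are resolved by scipy's deterministic ordering, which
    joins the lowest-index pair first.
    """
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    sim = np.asarray(similarity, dtype=float)
    if np.isnan(sim).any():
        raise ValueError("similarity matrix has missing entries")
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="average")
    if labels is None:
        labels = [str(i) for i in range(sim.shape[0])]
    return ClusterTree(z, list(labels))
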