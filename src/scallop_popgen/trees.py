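"""Neighbor-joining trees from allele-sharing distances, with
locus-bootstrap support, built separately for neutral and environmentally
associated loci.

The distance between two individuals is one minus their mean proportion of
shared alleles over co-typed loci.  Trees are built with the Saitou-Nei
neighbor-joining algorithm (negative branch lengths clamped to zero,
Q-criterion ties joined at the lowest index pair) and handled as dendropy
trees, which also provide bipartition encoding for bootstrap support and
Robinson-Foulds comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .callset import MISSING, GenotypeCallSet
from .structure import coancestry_matrix

__all__ = ["allele_sharing_distance", "nj_tree", "bootstrap_support",
           "split_and_compare", "robinson_foulds", "SplitComparison"]


def allele_sharing_distance(calls: GenotypeCallSet,
                            locus_index: np.ndarray | None = None) -> np.ndarray:
    """1 - mean allele-sharing similarity per pair, over a locus subset."""
    if locus_index is not None and len(locus_index) == 0:
        raise ValueError("empty locus subset")
    sim = coancestry_matrix(calls, locus_index)
    if np.isnan(sim).any():
        raise ValueError("some pairs share no co-typed locus in the subset")
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, None)


def _nj_merge_order(dist: np.ndarray):
    """Run Saitou-Nei NJ; yields (i, j, li, lj) merges over node ids.

    Node ids: leaves 0..n-1, internal nodes n, n+1, ...  Ties in the
    Q-criterion pick the lexicographically smallest active pair.
    """
    n = dist.shape[0]
    d = dist.astype(float).copy()
    ids = list(range(n))
    next_id = n
    merges = []
    while len(ids) > 2:
        m = len(ids)
        sub = d[np.ix_(range(m), range(m))]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = np.argmin(q)            # ties: first in row-major = lowest pair
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = 0.5 * sub[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = sub[i, j] - li
        merges.append((ids[i], ids[j], max(li, 0.0), max(lj, 0.0)))
        new_row = 0.5 * (sub[i] + sub[j] - sub[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[:-1, :-1] = sub[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_row[keep]
        d2[-1, -1] = 0.0
        d = d2
        ids = [ids[x] for x in keep] + [next_id]
        next_id += 1
    if len(ids) == 2:
        merges.append((ids[0], ids[1], max(d[0, 1], 0.0), 0.0))
    return merges


def nj_tree(dist: np.ndarray, labels: list[str],
            taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    """Unrooted neighbor-joining tree from a distance matrix."""
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if n < 3:
        raise ValueError("need >= 3 taxa")
    if dist.shape != (n, n) or not np.allclose(dist, dist.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.isfinite(dist).all():
        raise ValueError("distances must be finite")
    if len(labels) != n:
        raise ValueError("labels length mismatch")
    tns = taxon_namespace or dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes: dict[int, dendropy.Node] = {}
    for i, lab in enumerate(labels):
        nd = dendropy.Node()
        nd.taxon = tns.get_taxon(lab)
        nodes[i] = nd
    merges = _nj_merge_order(dist)
    next_id = n
    for a, b, la, lb in merges[:-1]:
        parent = dendropy.Node()
        nodes[a].edge.length = la
        nodes[b].edge.length = lb
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes[next_id] = parent
        next_id += 1
    a, b, la, _ = merges[-1]
    # join the last two nodes through the seed (root) node of the tree
    root = tree.seed_node
    nodes[a].edge.length = la / 2.0
    nodes[b].edge.length = la / 2.0
    root.add_child(nodes[a])
    root.add_child(nodes[b])
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def bootstrap_support(calls: GenotypeCallSet, locus_index: np.ndarray,
                      labels: list[str] | None = None, n_boot: int = 100,
                      rng_seed: int = 0) -> dendropy.Tree:
    """NJ tree on a locus subset with locus-bootstrap node support.

    Loci are resampled with replacement ``n_boot`` times; the support of
    each internal bipartition of the full-data tree is the percentage of
    replicate trees containing it, stored as internal node labels.
    """
    locus_index = np.asarray(locus_index)
    if n_boot <= 0:
        raise ValueError("n_boot must be > 0")
    if locus_index.size < 2:
        raise ValueError("bootstrap needs >= 2 loci")
    labels = list(labels) if labels is not None else list(calls.individuals)
    tns = dendropy.TaxonNamespace(labels)
    base = nj_tree(allele_sharing_distance(calls, locus_index), labels, tns)
    base.encode_bipartitions()
    counts = {bp.split_bitmask: 0 for bp in base.bipartition_encoding}
    rng = np.random.default_rng(rng_seed)
    for _ in range(n_boot):
        sub = rng.choice(locus_index, size=locus_index.size, replace=True)
        rep = nj_tree(allele_sharing_distance(calls, sub), labels, tns)
        rep.encode_bipartitions()
        seen = {bp.split_bitmask for bp in rep.bipartition_encoding}
        for mask in counts:
            if mask in seen:
                counts[mask] += 1
    for node in base.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        mask = node.edge.bipartition.split_bitmask
        node.label = f"{100.0 * counts[mask] / n_boot:.0f}"
    return base


def robinson_foulds(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Unweighted Robinson-Foulds distance (unrooted, topology only)."""
    from dendropy.calculate import treecompare
    return int(treecompare.symmetric_difference(tree_a, tree_b))


@dataclass
class SplitComparison:
    neutral_tree: dendropy.Tree
    candidate_tree: dendropy.Tree | None
    rf_distance: int | None


def split_and_compare(calls: GenotypeCallSet, candidate_loci: set,
                      n_boot: int = 100, rng_seed: int = 0) -> SplitComparison:
    """Trees from the candidate (consensus) loci and their neutral
    complement, plus the Robinson-Foulds distance between them."""
    ids = list(calls.locus_ids)
    cand_idx = np.array([i for i, l in enumerate(ids) if l in candidate_loci],
                        dtype=int)
    neut_idx = np.array([i for i, l in enumerate(ids) if l not in candidate_loci],
                        dtype=int)
    labels = list(calls.individuals)
    tns = dendropy.TaxonNamespace(labels)
    ss = np.random.SeedSequence(rng_seed)
    s1, s2 = (int(s >> 1) for s in ss.generate_state(2))
    neutral = bootstrap_support(calls, neut_idx, labels, n_boot, s1)
    neutral.migrate_taxon_namespace(tns)
    if cand_idx.size < 2:
        import warnings
        warnings.warn("candidate set too small for a tree: returning the "
                      "neutral tree only")
        return SplitComparison(neutral, None, None)
    candidate = bootstrap_support(calls, cand_idx, labels, n_boot, s2)
    candidate.migrate_taxon_namespace(tns)
    return SplitComparison(neutral, candidate,
                           robinson_foulds(neutral, candidate))
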