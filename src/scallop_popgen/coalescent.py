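"""Discrete-deme continuous-time coalescent simulator for unlinked SNPs.

The engine simulates one genealogy per SNP under a multi-deme demography
without migration (demes exchange lineages only through merge events,
looking backward in time).  Population sizes are diploid effective sizes;
time is measured in generations before present; the coalescence rate for a
deme holding ``k`` lineages of size ``Ne`` is ``k(k-1)/2 / (2 Ne)`` per
generation.  Size changes between a contemporary and a historical size are
exponential by default (instantaneous change is available per deme).

A single segregating site is placed on each genealogy with probability
proportional to branch length, which conditions every simulated SNP on
being polymorphic in the total sample; no per-site mutation rate is needed.
A consequence worth keeping in mind is that the expected site frequency
spectrum is exactly invariant to a joint rescaling of all sizes and times.

The heavy per-genealogy loops are JIT-compiled with numba.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "DemeConfig",
    "DemographyEvent",
    "GenealogySample",
    "DemographyError",
    "simulate_snp",
    "expected_folded_sfs",
    "sample_snp_counts",
    "simulate_genotype_matrix",
]


class DemographyError(ValueError):
    """Raised for demographies that cannot reach a common ancestor."""


@dataclass
class DemeConfig:
    """One sampled (or ancestral) deme.

    Parameters
    ----------
    deme_id
        Label used by events to address this deme.
    sample_size
        Number of sampled haploid lineages (2 x diploid individuals); must
        be even and may be zero for purely ancestral demes.
    current_Ne
        Diploid effective size at the present.
    historical_Ne
        Diploid effective size before ``growth_onset`` generations ago.
        ``None`` means the deme keeps ``current_Ne`` at all times.
    growth_onset
        Time (generations before present) at which the size change between
        ``historical_Ne`` and ``current_Ne`` begins (forward in time).
    growth
        ``"exponential"`` (default) or ``"instantaneous"``.
    """

    deme_id: str
    sample_size: int
    current_Ne: float
    historical_Ne: float | None = None
    growth_onset: float = 0.0
    growth: str = "exponential"

    def __post_init__(self) -> None:
        if self.sample_size < 0 or self.sample_size % 2 != 0:
            raise ValueError(
                f"deme {self.deme_id}: sample_size must be even and >= 0, "
                f"got {self.sample_size}"
            )
        if self.current_Ne <= 0:
            raise ValueError(f"deme {self.deme_id}: current_Ne must be > 0")
        if self.historical_Ne is not None and self.historical_Ne <= 0:
            raise ValueError(f"deme {self.deme_id}: historical_Ne must be > 0")
        if self.growth_onset < 0:
            raise ValueError(f"deme {self.deme_id}: growth_onset must be >= 0")
        if self.growth not in ("exponential", "instantaneous"):
            raise ValueError(f"unknown growth mode {self.growth!r}")


@dataclass
class DemographyEvent:
    """A demographic event at ``time`` generations before present.

    Kinds
    -----
    ``merge_demes``
        All lineages in ``source`` move into ``dest`` (backward in time this
        is the split of ``source`` from ``dest``, forward in time).
    ``set_size``
        From ``time`` backward, deme ``dest`` has diploid size ``new_size``.
    ``start_growth``
        Overrides the ``growth_onset`` of deme ``dest``.
    """

    time: float
    kind: str
    source: str | None = None
    dest: str | None = None
    new_size: float | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("event time must be >= 0")
        if self.kind not in ("merge_demes", "set_size", "start_growth"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "merge_demes" and (self.source is None or self.dest is None):
            raise ValueError("merge_demes requires source and dest")
        if self.kind == "set_size" and (self.dest is None or self.new_size is None):
            raise ValueError("set_size requires dest and new_size")
        if self.kind == "set_size" and self.new_size <= 0:
            raise ValueError("set_size new_size must be > 0")


@dataclass
class GenealogySample:
    """Derived-allele counts of one simulated SNP, per deme."""

    derived_counts: np.ndarray  # int64, one entry per deme (deme order of input)
    total_branch_length: float


# ---------------------------------------------------------------------------
# demography -> piecewise-constant/exponential epoch schedule
# ---------------------------------------------------------------------------


@dataclass
class _Schedule:
    deme_names: list[str]
    sample_sizes: np.ndarray  # int64 per deme (haploid)
    deme_of_leaf: np.ndarray  # int64 per leaf
    epoch_starts: np.ndarray  # float64 ascending, starts at 0
    N0: np.ndarray  # float64 (n_epochs, n_demes), size at epoch start
    G: np.ndarray  # float64 (n_epochs, n_demes), backward exp rate in epoch
    merge_epoch: np.ndarray  # int64 per merge, epoch index at whose start it applies
    merge_src: np.ndarray
    merge_dst: np.ndarray


def _deme_size_profile(deme: DemeConfig, onset: float, set_sizes: list[tuple[float, float]]):
    """Return a callable N(t) and the set of change-point times for one deme."""
    cur = float(deme.current_Ne)
    hist = float(deme.historical_Ne) if deme.historical_Ne is not None else cur
    exponential = deme.growth == "exponential" and onset > 0 and hist != cur
    rate = math.log(hist / cur) / onset if exponential else 0.0
    ss = sorted(set_sizes)  # ascending times; deepest applicable wins going back

    def size_at(t: float) -> tuple[float, float]:
        """(N at time t, backward exponential rate applying just after t)."""
        applied = None
        for tau, new in ss:
            if t >= tau:
                applied = new
        if applied is not None:
            return applied, 0.0
        if t >= onset:
            return hist, 0.0
        if exponential:
            return cur * math.exp(rate * t), rate
        return cur, 0.0

    change_points = {onset} if onset > 0 else set()
    change_points.update(tau for tau, _ in ss)
    return size_at, change_points


def build_schedule(demes: list[DemeConfig], events: list[DemographyEvent]) -> _Schedule:
    """Flatten a deme/event description into per-epoch arrays for the kernel."""
    if not demes:
        raise DemographyError("at least one deme is required")
    names = [d.deme_id for d in demes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate deme ids")
    index = {n: i for i, n in enumerate(names)}
    sizes = np.array([d.sample_size for d in demes], dtype=np.int64)
    if sizes.sum() == 0:
        raise DemographyError("zero total samples")

    events = sorted(events, key=lambda e: e.time)
    onset = {d.deme_id: (d.growth_onset if d.historical_Ne is not None else 0.0) for d in demes}
    set_sizes: dict[str, list[tuple[float, float]]] = {n: [] for n in names}
    merges: list[tuple[float, int, int]] = []
    for ev in events:
        if ev.kind == "start_growth":
            onset[ev.dest or ev.source] = ev.time  # type: ignore[index]
        elif ev.kind == "set_size":
            set_sizes[ev.dest].append((ev.time, float(ev.new_size)))  # type: ignore[arg-type]
        else:
            merges.append((ev.time, index[ev.source], index[ev.dest]))  # type: ignore[index]

    # connectivity: every sampled deme must end up in a single component
    comp = {i: i for i in range(len(demes))}
    alive = set(range(len(demes)))
    for _, src, dst in merges:
        if src not in alive:
            raise DemographyError(f"deme {names[src]} merged twice")
        if dst not in alive:
            raise DemographyError(f"merge destination {names[dst]} no longer exists")
        for k, v in comp.items():
            if v == src:
                comp[k] = dst
        alive.discard(src)
    roots = {comp[i] for i in range(len(demes)) if sizes[i] > 0}
    if len(roots) > 1:
        raise DemographyError(
            "unreachable common ancestor: sampled demes are never united "
            f"({', '.join(names[r] for r in sorted(roots))})"
        )

    breakpoints = {0.0}
    for n in names:
        if onset[n] > 0:
            breakpoints.add(float(onset[n]))
        breakpoints.update(float(t) for t, _ in set_sizes[n])
    breakpoints.update(float(t) for t, _, _ in merges)
    epoch_starts = np.array(sorted(breakpoints), dtype=np.float64)
    n_epochs = len(epoch_starts)

    N0 = np.empty((n_epochs, len(demes)))
    G = np.zeros((n_epochs, len(demes)))
    for j, d in enumerate(demes):
        size_at, _ = _deme_size_profile(d, onset[d.deme_id], set_sizes[d.deme_id])
        for e, t0 in enumerate(epoch_starts):
            N0[e, j], G[e, j] = size_at(t0)

    epoch_of_time = {t: e for e, t in enumerate(epoch_starts)}
    merge_epoch = np.array([epoch_of_time[float(t)] for t, _, _ in merges], dtype=np.int64)
    merge_src = np.array([s for _, s, _ in merges], dtype=np.int64)
    merge_dst = np.array([d for _, _, d in merges], dtype=np.int64)

    deme_of_leaf = np.repeat(np.arange(len(demes), dtype=np.int64), sizes)
    return _Schedule(names, sizes, deme_of_leaf, epoch_starts, N0, G,
                     merge_epoch, merge_src, merge_dst)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _fold_flat(desc_v, sizes, D):
    """Flat index of the folded configuration of one branch's leaf counts."""
    m = 0
    S = 0
    for d in range(D):
        m += desc_v[d]
        S += sizes[d]
    fold = False
    if 2 * m > S:
        fold = True
    elif 2 * m == S:
        for d in range(D):
            c = desc_v[d]
            comp = sizes[d] - c
            if c < comp:
                break
            if c > comp:
                fold = True
                break
    idx = 0
    for d in range(D):
        c = sizes[d] - desc_v[d] if fold else desc_v[d]
        idx = idx * (sizes[d] + 1) + c
    return idx


@njit(cache=True, inline="always")
def _draw_next(t, e, d, kd, epoch_starts, N0, G):
    """Absolute candidate time of the next coalescence in deme ``d``."""
    k = kd[d]
    if k < 2:
        return np.inf
    C = 0.5 * k * (k - 1)
    gg = G[e, d]
    Nc = N0[e, d] * np.exp(gg * (t - epoch_starts[e]))
    E1 = np.random.exponential(1.0)
    if gg == 0.0:
        return t + 2.0 * Nc * E1 / C
    A = C / (2.0 * Nc)
    arg = 1.0 - gg * E1 / A
    if arg <= 0.0:
        return np.inf
    return t - np.log(arg) / gg


@njit(cache=True)
def _simulate_batch(seed, n_sims, deme_of_leaf, sizes, epoch_starts, N0, G,
                    merge_epoch, merge_src, merge_dst,
                    mode, n_out, mut_u, fold_map, flat_out, counts_out,
                    leaves_out, totlen_out):
    """Simulate ``n_sims`` genealogies.

    mode 0: emit ``n_out[i]`` SNPs from genealogy ``i`` (branch chosen with
            probability proportional to length, using externally supplied
            uniforms ``mut_u``) -> rows of counts_out
    mode 1: folded-SFS branch-length accumulation -> flat_out
    mode 2: as 0, additionally writes per-leaf derived states -> leaves_out
    mode 3: genealogy total lengths only -> totlen_out

    Genealogy construction consumes the global RNG identically in every
    mode, so two calls with the same seed reproduce the same genealogies;
    mutation placement uses only ``mut_u``.
    """
    np.random.seed(seed)
    n = deme_of_leaf.shape[0]
    D = sizes.shape[0]
    E = epoch_starts.shape[0]
    M = merge_epoch.shape[0]
    nn = 2 * n - 1

    node_time = np.empty(nn)
    child1 = np.empty(nn, np.int64)
    child2 = np.empty(nn, np.int64)
    desc = np.empty((nn, D), np.int64)
    blen = np.empty(nn)
    active = np.empty((D, n), np.int64)
    kd = np.empty(D, np.int64)
    stack = np.empty(nn, np.int64)

    row = 0
    for s in range(n_sims):
        for d in range(D):
            kd[d] = 0
        for i in range(n):
            d = deme_of_leaf[i]
            active[d, kd[d]] = i
            kd[d] += 1
            node_time[i] = 0.0
            for dd in range(D):
                desc[i, dd] = 0
            desc[i, d] = 1
        e = 0
        t = 0.0
        for m in range(M):
            if merge_epoch[m] == 0:
                sd = merge_src[m]
                dd2 = merge_dst[m]
                for q in range(kd[sd]):
                    active[dd2, kd[dd2]] = active[sd, q]
                    kd[dd2] += 1
                kd[sd] = 0
        n_nodes = n
        total_active = n
        # next-reaction scheme: each deme holds an absolute candidate
        # coalescence time, redrawn only when its lineage count changes or
        # an epoch boundary is crossed (valid by the memorylessness of the
        # competing exponential race)
        next_t = np.empty(D)
        for d in range(D):
            next_t[d] = _draw_next(t, e, d, kd, epoch_starts, N0, G)
        while total_active > 1:
            t_end = epoch_starts[e + 1] if e + 1 < E else np.inf
            best_d = 0
            for d in range(1, D):
                if next_t[d] < next_t[best_d]:
                    best_d = d
            if next_t[best_d] < t_end:
                t = next_t[best_d]
                k = kd[best_d]
                i = np.random.randint(0, k)
                j = np.random.randint(0, k - 1)
                if j >= i:
                    j += 1
                a = active[best_d, i]
                b = active[best_d, j]
                p = n_nodes
                n_nodes += 1
                node_time[p] = t
                child1[p] = a
                child2[p] = b
                for dd in range(D):
                    desc[p, dd] = desc[a, dd] + desc[b, dd]
                lo = i if i < j else j
                hi = i + j - lo
                active[best_d, lo] = p
                active[best_d, hi] = active[best_d, k - 1]
                kd[best_d] = k - 1
                total_active -= 1
                next_t[best_d] = _draw_next(t, e, best_d, kd,
                                            epoch_starts, N0, G)
            else:
                if e + 1 >= E:
                    raise RuntimeError(
                        "coalescent deadlock: multiple demes never merge")
                e += 1
                t = epoch_starts[e]
                for m in range(M):
                    if merge_epoch[m] == e:
                        sd = merge_src[m]
                        dd2 = merge_dst[m]
                        for q in range(kd[sd]):
                            active[dd2, kd[dd2]] = active[sd, q]
                            kd[dd2] += 1
                        kd[sd] = 0
                for d in range(D):
                    next_t[d] = _draw_next(t, e, d, kd, epoch_starts, N0, G)
        total = 0.0
        for p in range(n, n_nodes):
            a = child1[p]
            b = child2[p]
            blen[a] = node_time[p] - node_time[a]
            blen[b] = node_time[p] - node_time[b]
            total += blen[a] + blen[b]
        totlen_out[s] = total
        if mode == 1:
            # absolute branch lengths: normalizing the accumulated array by
            # its sum yields the unbiased length-weighted SFS estimate;
            # fold_map sends each raw configuration to its folded flat index
            for v in range(n_nodes - 1):  # root (last created) excluded
                idx = 0
                for d in range(D):
                    idx = idx * (sizes[d] + 1) + desc[v, d]
                flat_out[fold_map[idx]] += blen[v]
        elif mode == 0 or mode == 2:
            for q in range(n_out[s]):
                u = mut_u[row] * total
                chosen = n_nodes - 2
                acc = 0.0
                for v in range(n_nodes - 1):
                    acc += blen[v]
                    if u <= acc:
                        chosen = v
                        break
                for dd in range(D):
                    counts_out[row, dd] = desc[chosen, dd]
                if mode == 2:
                    for i in range(n):
                        leaves_out[row, i] = 0
                    top = 0
                    stack[top] = chosen
                    top += 1
                    while top > 0:
                        top -= 1
                        v = stack[top]
                        if v < n:
                            leaves_out[row, v] = 1
                        else:
                            stack[top] = child1[v]
                            top += 1
                            stack[top] = child2[v]
                            top += 1
                row += 1
    return row


_DUMMY_F = np.zeros(1, dtype=np.float64)
_DUMMY_I = np.zeros(1, dtype=np.int64)
_DUMMY_C = np.zeros((1, 1), dtype=np.int64)
_DUMMY_L = np.zeros((1, 1), dtype=np.uint8)

_FOLD_MAPS: dict[tuple[int, ...], np.ndarray] = {}


def _fold_map_for(sizes: np.ndarray) -> np.ndarray:
    """Flat lookup table raw configuration index -> folded flat index."""
    key = tuple(int(s) for s in sizes)
    cached = _FOLD_MAPS.get(key)
    if cached is not None:
        return cached
    from .sfs import fold_configurations  # local import: avoid cycle at load

    dims = tuple(s + 1 for s in key)
    raw = np.indices(dims).reshape(len(key), -1).T
    folded = fold_configurations(raw, np.array(key, dtype=np.int64))
    flat = np.ravel_multi_index(tuple(folded.T), dims).astype(np.int64)
    _FOLD_MAPS[key] = flat
    return flat


def _check_seed(seed: int) -> int:
    seed = int(seed)
    if not 0 <= seed < 2**32:
        raise ValueError("seed must be in [0, 2^32)")
    return seed


def _genealogy_lengths(sched: _Schedule, n_sims: int, seed: int) -> np.ndarray:
    lens = np.zeros(n_sims)
    _simulate_batch(seed, n_sims, sched.deme_of_leaf, sched.sample_sizes,
                    sched.epoch_starts, sched.N0, sched.G,
                    sched.merge_epoch, sched.merge_src, sched.merge_dst,
                    3, _DUMMY_I, _DUMMY_F, _DUMMY_I, _DUMMY_F, _DUMMY_C,
                    _DUMMY_L, lens)
    return lens


def _sample_sites(sched: _Schedule, n_snps: int, n_genealogies: int, seed: int,
                  want_leaves: bool):
    """Length-biased SNP sampling over a batch of genealogies.

    A SNP occurs on a genealogy with probability proportional to its total
    branch length (infinite-sites, conditioned on polymorphism), so a first
    pass records genealogy lengths, SNPs are allocated to genealogies with a
    length-weighted multinomial, and a second pass with the same seed
    replays the identical genealogies and places the mutations (mutation
    uniforms come from a separate stream, keeping the two passes in step).
    The normalisation over the finite batch leaves a relative bias of order
    ``1/n_genealogies``.
    """
    seed = _check_seed(seed)
    lens = _genealogy_lengths(sched, n_genealogies, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5F5E])
                                )
    n_out = rng.multinomial(n_snps, lens / lens.sum())
    mut_u = rng.random(n_snps)
    counts = np.zeros((n_snps, len(sched.deme_names)), dtype=np.int64)
    n_leaves = int(sched.sample_sizes.sum())
    leaves = (np.zeros((n_snps, n_leaves), dtype=np.uint8)
              if want_leaves else _DUMMY_L)
    totlen = np.zeros(n_genealogies)
    _simulate_batch(seed, n_genealogies, sched.deme_of_leaf, sched.sample_sizes,
                    sched.epoch_starts, sched.N0, sched.G,
                    sched.merge_epoch, sched.merge_src, sched.merge_dst,
                    2 if want_leaves else 0, n_out, mut_u, _DUMMY_I,
                    _DUMMY_F, counts, leaves, totlen)
    return counts, leaves, np.repeat(lens, n_out)


def simulate_snp(demes: list[DemeConfig], events: list[DemographyEvent],
                 rng_seed: int, n_genealogies: int = 256) -> GenealogySample:
    """Simulate one polymorphic SNP and return per-deme derived counts.

    An internal batch of ``n_genealogies`` genealogies is simulated and one
    is chosen with probability proportional to total branch length before
    the mutation is placed.
    """
    sched = build_schedule(demes, events)
    counts, _, lens = _sample_sites(sched, 1, n_genealogies, rng_seed, False)
    return GenealogySample(counts[0].copy(), float(lens[0]))


def sample_snp_counts(demes, events, n_snps: int, rng_seed: int) -> np.ndarray:
    """Per-deme derived-allele counts of ``n_snps`` unlinked SNPs."""
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    sched = build_schedule(demes, events)
    counts, _, _ = _sample_sites(sched, n_snps, max(n_snps, 256), rng_seed, False)
    return counts


def expected_folded_sfs(demes, events, n_sims: int, rng_seed: int) -> np.ndarray:
    """Monte-Carlo estimate of folded joint SFS entry probabilities.

    Returns an array of shape ``(s_1+1, ..., s_D+1)`` (haploid sample sizes
    ``s_d``) whose polymorphic folded entries sum to 1.  Every branch of
    every simulated genealogy contributes its absolute length to its folded
    frequency class, so the estimate is the length-weighted (infinite-sites)
    SFS with far lower variance than placing one mutation per genealogy.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    sched = build_schedule(demes, events)
    dims = tuple(int(s) + 1 for s in sched.sample_sizes)
    flat = np.zeros(int(np.prod(dims)), dtype=np.float64)
    totlen = np.zeros(n_sims)
    _simulate_batch(_check_seed(rng_seed), n_sims, sched.deme_of_leaf,
                    sched.sample_sizes, sched.epoch_starts, sched.N0, sched.G,
                    sched.merge_epoch, sched.merge_src, sched.merge_dst,
                    1, _DUMMY_I, _DUMMY_F, _fold_map_for(sched.sample_sizes),
                    flat, _DUMMY_C, _DUMMY_L, totlen)
    out = flat.reshape(dims)
    out /= out.sum()
    return out


def simulate_genotype_matrix(demes, events, n_snps: int, rng_seed: int):
    """Diploid 0/1/2 genotypes for ``n_snps`` unlinked polymorphic SNPs.

    Consecutive haploid lineages within each deme are paired into diploid
    individuals.  Returns ``(genotypes, deme_of_individual)`` where
    ``genotypes`` has shape ``(n_individuals, n_snps)``.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    sched = build_schedule(demes, events)
    for d in demes:
        if d.sample_size % 2 != 0:
            raise ValueError("sample sizes must be even to form diploids")
    _, leaves, _ = _sample_sites(sched, n_snps, n_snps, rng_seed, True)
    geno = (leaves[:, 0::2].astype(np.int8) + leaves[:, 1::2].astype(np.int8)).T
    deme_of_ind = sched.deme_of_leaf[0::2].copy()
    return geno, deme_of_ind
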