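"""Folded joint site-frequency-spectrum container and plain-text I/O.

The folded joint SFS over ``D`` demes with haploid sample sizes
``(s_1, ..., s_D)`` is a ``D``-dimensional count array indexed by
minor-allele counts.  Folding identifies a configuration ``c`` with its
complement ``s - c``; the representative kept is the one whose total count
is at most half the total sample (ties keep the lexicographically smaller
configuration).  The all-zero and all-maximum cells are structurally zero:
only polymorphic sites enter the spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FoldedJointSFS", "fold_configurations"]


def fold_configurations(counts: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Fold an ``(L, D)`` matrix of derived-allele counts.

    Returns the ``(L, D)`` matrix of folded (minor-allele-representative)
    configurations.
    """
    counts = np.asarray(counts, dtype=np.int64)
    sizes = np.asarray(sizes, dtype=np.int64)
    total = counts.sum(axis=1)
    S = int(sizes.sum())
    comp = sizes[None, :] - counts
    flip = 2 * total > S
    # ties: lexicographic comparison of configuration vs complement
    tie = 2 * total == S
    if tie.any():
        t_idx = np.nonzero(tie)[0]
        for i in t_idx:
            for c, k in zip(counts[i], comp[i]):
                if c != k:
                    flip[i] = c > k
                    break
    out = np.where(flip[:, None], comp, counts)
    return out


@dataclass
class FoldedJointSFS:
    """Observed folded joint SFS: integer counts over folded entries."""

    counts: np.ndarray  # int64, shape (s_1+1, ..., s_D+1)
    deme_names: list[str]
    sample_sizes: np.ndarray  # haploid sizes, int64 per deme

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.sample_sizes = np.asarray(self.sample_sizes, dtype=np.int64)
        if self.counts.shape != tuple(self.sample_sizes + 1):
            raise ValueError("counts shape does not match sample sizes")
        if (self.counts < 0).any():
            raise ValueError("negative SFS counts")

    @property
    def n_snps(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_count_matrix(cls, counts: np.ndarray, deme_names, sizes) -> "FoldedJointSFS":
        """Bin an ``(L, D)`` matrix of derived-allele counts into a folded SFS."""
        sizes = np.asarray(sizes, dtype=np.int64)
        folded = fold_configurations(counts, sizes)
        arr = np.zeros(tuple(sizes + 1), dtype=np.int64)
        np.add.at(arr, tuple(folded.T), 1)
        return cls(arr, list(deme_names), sizes)

    def probabilities(self) -> np.ndarray:
        if self.n_snps == 0:
            raise ValueError("empty SFS")
        return self.counts / self.n_snps

    # -- plain-text round trip ------------------------------------------------

    def to_text(self, path) -> None:
        """Sparse plain-text format: header names demes and haploid sizes,
        body has one ``i_1 ... i_D count`` line per non-zero entry."""
        with open(path, "w") as fh:
            fh.write("# folded joint SFS\n")
            fh.write("# demes: " + " ".join(self.deme_names) + "\n")
            fh.write("# haploid_sizes: "
                     + " ".join(str(int(s)) for s in self.sample_sizes) + "\n")
            nz = np.nonzero(self.counts)
            for idx in zip(*nz):
                fh.write(" ".join(str(int(i)) for i in idx)
                         + f" {int(self.counts[idx])}\n")

    @classmethod
    def from_text(cls, path) -> "FoldedJointSFS":
        names: list[str] = []
        sizes: np.ndarray | None = None
        entries = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if line.startswith("# demes:"):
                        names = line.split(":", 1)[1].split()
                    elif line.startswith("# haploid_sizes:"):
                        sizes = np.array(line.split(":", 1)[1].split(),
                                         dtype=np.int64)
                    continue
                entries.append([int(x) for x in line.split()])
        if sizes is None or not names:
            raise ValueError(f"{path}: missing SFS header")
        arr = np.zeros(tuple(sizes + 1), dtype=np.int64)
        for row in entries:
            arr[tuple(row[:-1])] = row[-1]
        return cls(arr, names, sizes)

    def fold(self) -> "FoldedJointSFS":
        """Fold the array again (identity on an already-folded spectrum)."""
        idx = np.array(list(np.ndindex(self.counts.shape)), dtype=np.int64)
        vals = self.counts.reshape(-1)
        folded = fold_configurations(idx, self.sample_sizes)
        arr = np.zeros_like(self.counts)
        np.add.at(arr, tuple(folded.T), vals)
        return FoldedJointSFS(arr, self.deme_names, self.sample_sizes)
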