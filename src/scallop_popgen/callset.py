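"""Genotype call-set container and study-input I/O (VCF, popmap, env table).

Genotypes are stored as an ``(individuals, loci)`` int8 dosage matrix with
``-1`` marking missing calls; per-call depth and genotype quality share the
shape.  Loci carry a RAD-tag id and a column within the tag (the ordering
used by LD pruning) plus raw-record flags (allele number, indel) consumed
by the first QC step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

__all__ = ["GenotypeCallSet", "MISSING", "read_vcf", "write_vcf",
           "read_popmap", "write_popmap", "read_env_table", "write_env_table"]


@dataclass
class GenotypeCallSet:
    genotypes: np.ndarray                 # int8 (n_ind, n_loci), -1 missing
    individuals: np.ndarray               # str per individual
    populations: np.ndarray               # str per individual
    locus_ids: np.ndarray                 # str per locus
    tags: np.ndarray                      # int per locus (RAD tag)
    tag_pos: np.ndarray                   # int per locus (column within tag)
    depth: np.ndarray | None = None       # int32, same shape as genotypes
    qual: np.ndarray | None = None        # int32 (genotype quality)
    n_alleles: np.ndarray | None = None   # int per locus (raw record)
    is_indel: np.ndarray | None = None    # bool per locus (raw record)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n_ind, n_loci = self.genotypes.shape
        for name in ("individuals", "populations"):
            setattr(self, name, np.asarray(getattr(self, name)))
            if len(getattr(self, name)) != n_ind:
                raise ValueError(f"{name} length != number of individuals")
        for name in ("locus_ids", "tags", "tag_pos"):
            setattr(self, name, np.asarray(getattr(self, name)))
            if len(getattr(self, name)) != n_loci:
                raise ValueError(f"{name} length != number of loci")
        for name in ("depth", "qual"):
            arr = getattr(self, name)
            if arr is not None and arr.shape != self.genotypes.shape:
                raise ValueError(f"{name} shape mismatch")
        if self.n_alleles is None:
            self.n_alleles = np.full(n_loci, 2, dtype=np.int64)
        if self.is_indel is None:
            self.is_indel = np.zeros(n_loci, dtype=bool)

    # -- basic shape and statistics ------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def call_rate(self) -> np.ndarray:
        """Per-locus fraction of non-missing calls."""
        return 1.0 - self.missing_mask().mean(axis=0)

    def maf(self) -> np.ndarray:
        """Per-locus minor-allele frequency over non-missing calls
        (NaN where a locus has no calls)."""
        g = self.genotypes
        typed = g != MISSING
        n = typed.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(typed, g, 0).sum(axis=0) / (2.0 * n)
        return np.minimum(p, 1.0 - p)

    # -- subsetting ------------------------------------------------------------

    def take_loci(self, index: np.ndarray) -> "GenotypeCallSet":
        return replace(
            self,
            genotypes=self.genotypes[:, index],
            depth=None if self.depth is None else self.depth[:, index],
            qual=None if self.qual is None else self.qual[:, index],
            locus_ids=self.locus_ids[index],
            tags=self.tags[index],
            tag_pos=self.tag_pos[index],
            n_alleles=self.n_alleles[index],
            is_indel=self.is_indel[index],
        )

    def take_individuals(self, index: np.ndarray) -> "GenotypeCallSet":
        return replace(
            self,
            genotypes=self.genotypes[index],
            depth=None if self.depth is None else self.depth[index],
            qual=None if self.qual is None else self.qual[index],
            individuals=self.individuals[index],
            populations=self.populations[index],
        )

    def population_indices(self) -> dict[str, np.ndarray]:
        return {p: np.nonzero(self.populations == p)[0]
                for p in pd.unique(self.populations)}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(calls: GenotypeCallSet, path) -> None:
    """Write a minimal VCF 4.2 with GT:DP:GQ calls.

    CHROM is the RAD tag (``tag<N>``), POS the 1-based column within the
    tag; alleles are written as A/C placeholders (the container does not
    track nucleotides).
    """
    dp = calls.depth if calls.depth is not None else np.zeros_like(calls.genotypes, dtype=np.int32)
    gq = calls.qual if calls.qual is not None else np.zeros_like(calls.genotypes, dtype=np.int32)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=scallop_popgen\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(calls.individuals) + "\n")
        g = calls.genotypes
        for j in range(calls.n_loci):
            fields = [f"tag{int(calls.tags[j])}", str(int(calls.tag_pos[j]) + 1),
                      str(calls.locus_ids[j]), "A", "C", ".", "PASS", ".",
                      "GT:DP:GQ"]
            col = [f"{_GT_STR[int(g[i, j])]}:{int(dp[i, j])}:{int(gq[i, j])}"
                   for i in range(calls.n_individuals)]
            fh.write("\t".join(fields + col) + "\n")


def read_vcf(path) -> GenotypeCallSet:
    """Read a VCF with GT(:DP:GQ) calls via cyvcf2.

    Multi-allelic and indel records are retained with their flags set so
    the QC chain can drop them; populations are filled in from a popmap by
    the caller.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.array(vcf.samples)
    genos, dps, gqs = [], [], []
    ids, tags, poss, nall, indel = [], [], [], [], []
    for v in vcf:
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = np.asarray(v.gt_types)
        row = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], MISSING).astype(np.int8)
        genos.append(row)
        fmt = v.FORMAT
        if "DP" in fmt:
            dp = np.asarray(v.format("DP")).reshape(-1).astype(np.int64)
            dps.append(np.where(dp < 0, 0, dp).astype(np.int32))
        if "GQ" in fmt:
            gq = np.asarray(v.format("GQ")).reshape(-1).astype(np.int64)
            gqs.append(np.where(gq < 0, 0, gq).astype(np.int32))
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        chrom = v.CHROM
        tags.append(int("".join(ch for ch in chrom if ch.isdigit()) or 0))
        poss.append(v.POS - 1)
        nall.append(1 + len(v.ALT))
        indel.append(bool(v.is_indel))
    if not genos:
        raise ValueError(f"{path}: no variant records")
    return GenotypeCallSet(
        genotypes=np.vstack(genos).T,
        individuals=samples,
        populations=np.array(["?"] * len(samples)),
        locus_ids=np.array(ids),
        tags=np.array(tags, dtype=np.int64),
        tag_pos=np.array(poss, dtype=np.int64),
        depth=np.vstack(dps).T if len(dps) == len(genos) else None,
        qual=np.vstack(gqs).T if len(gqs) == len(genos) else None,
        n_alleles=np.array(nall, dtype=np.int64),
        is_indel=np.array(indel, dtype=bool),
    )


# ---------------------------------------------------------------------------
# popmap and environment table
# ---------------------------------------------------------------------------


def write_popmap(df: pd.DataFrame, path) -> None:
    """TSV with columns individual/population/lineage (one row per sample)."""
    df.to_csv(path, sep="\t", index=False)


def read_popmap(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"individual", "population", "lineage"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: popmap needs columns {sorted(required)}")
    if df["individual"].duplicated().any():
        dup = df.loc[df["individual"].duplicated(), "individual"].tolist()
        raise ValueError(f"{path}: duplicated individuals {dup}")
    return df


def write_env_table(env: pd.DataFrame, path) -> None:
    env.to_csv(path, index=True, index_label="population")


def read_env_table(path) -> pd.DataFrame:
    env = pd.read_csv(path, index_col="population")
    if env.index.duplicated().any():
        dup = env.index[env.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicated population rows {dup}")
    if env.isna().any().any():
        raise ValueError(f"{path}: environment table has missing cells")
    return env


def attach_populations(calls: GenotypeCallSet, popmap: pd.DataFrame) -> GenotypeCallSet:
    """Match VCF samples to the popmap; every sample must be mapped."""
    mapping = dict(zip(popmap["individual"], popmap["population"]))
    unmapped = [s for s in calls.individuals if s not in mapping]
    if unmapped:
        raise ValueError(f"individuals absent from popmap: {unmapped}")
    return replace(calls, populations=np.array([mapping[s] for s in calls.individuals]))
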