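import numpy as np
import pytest

from scallop_popgen.callset import GenotypeCallSet
from scallop_popgen.simulate import StudyDesign, PopulationSpec, generate_dataset


def make_calls(geno, populations=None, depth=None, qual=None, tags=None,
               tag_pos=None, **kw):
    """Small helper to build a call set from a genotype matrix."""
    geno = np.asarray(geno, dtype=np.int8)
    n_ind, n_loci = geno.shape
    if populations is None:
        populations = ["P1"] * n_ind
    return GenotypeCallSet(
        genotypes=geno,
        individuals=np.array([f"ind{i}" for i in range(n_ind)]),
        populations=np.asarray(populations),
        locus_ids=np.array([f"snp{j:06d}" for j in range(n_loci)]),
        tags=np.arange(n_loci) if tags is None else np.asarray(tags),
        tag_pos=np.zeros(n_loci, dtype=int) if tag_pos is None else np.asarray(tag_pos),
        depth=None if depth is None else np.asarray(depth, dtype=np.int32),
        qual=None if qual is None else np.asarray(qual, dtype=np.int32),
        **kw,
    )


def small_design(n_snps=1500, n_per_pop=6, seed=0, **kw):
    """A reduced 8-population, three-lineage design for fast tests."""
    pops = (
        PopulationSpec("RDA", "ATL_S", n_per_pop, 42.3, -8.8),
        PopulationSpec("MPJ", "JAC", n_per_pop, 43.3, 3.9),
        PopulationSpec("RLB", "ATL_S", n_per_pop, 45.8, -1.2),
        PopulationSpec("PLY", "ATL_N", n_per_pop, 51.0, -4.3),
        PopulationSpec("MUL", "ATL_N", n_per_pop, 55.3, -7.7),
        PopulationSpec("SHE", "ATL_N", n_per_pop, 60.6, -0.9),
        PopulationSpec("NFB", "NOR", n_per_pop, 63.8, 8.7),
        PopulationSpec("NBG", "NOR", n_per_pop, 67.3, 14.4),
    )
    defaults = dict(populations=pops, n_snps=n_snps, n_adaptive_snps=40,
                    missing_rate=0.02, rng_seed=seed)
    defaults.update(kw)
    return StudyDesign(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    """One shared reduced synthetic dataset (8 pops x 6 ind, 1500 SNPs)."""
    return generate_dataset(small_design())


@pytest.fixture(scope="session")
def default_dataset():
    """A dataset under the full 14-population default design (6000 SNPs)."""
    return generate_dataset(StudyDesign(n_snps=6000, rng_seed=42))
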