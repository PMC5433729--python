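import numpy as np
import pytest

import keycontrib as kc

# Desk-scale version of the breeding design: same mating structure (every
# sire x 24 dams, one female each, 4 dams leaving a male+female pair), two
# 50 Mb chromosomes.
SMALL_DESIGN = kc.SimDesign(
    n_males=4,
    n_females=96,
    dams_per_sire=24,
    two_offspring_dams=4,
    n_chromosomes=2,
    chrom_length_bp=50_000_000,
    snps_per_chrom=500,
)


@pytest.fixture(scope="session")
def small_pop():
    """Two-generation desk-scale population with haplotypes (200 individuals)."""
    return kc.simulate_population(2, seed=11, design=SMALL_DESIGN)


@pytest.fixture(scope="session")
def small_exact_G(small_pop):
    return kc.true_ibd_matrix(small_pop.ancestry)


@pytest.fixture(scope="session")
def study_pop():
    """Full five-generation study-design pedigree and ancestry (no alleles)."""
    return kc.simulate_population(5, seed=101, with_alleles=False)


@pytest.fixture(scope="session")
def study_G(study_pop):
    """Exact-IBD relationship matrix of the full 5,100-individual population."""
    return kc.true_ibd_matrix(study_pop.ancestry, grid_points_per_chrom=100)


def random_psd(rng: np.random.Generator, n: int) -> kc.RelationshipMatrix:
    z = rng.standard_normal((n, n + 3))
    values = z @ z.T / (n + 3)
    return kc.RelationshipMatrix(values, [f"ind{i}" for i in range(n)], kind="external")
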