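import numpy as np
import pytest

from popadapt import GenotypeMatrix, SimConfig
from popadapt.simulate import simulate_dataset, simulate_genotypes


def make_genotype_matrix(geno, per_unigene=5, spacing=200):
    """Wrap a plain array as a GenotypeMatrix with synthetic locus labels."""
    geno = np.asarray(geno, dtype=float)
    n, L = geno.shape
    unigenes = np.array([f"UN{j // per_unigene + 1:05d}" for j in range(L)], dtype=object)
    positions = np.array([spacing * (j % per_unigene) + 100 for j in range(L)], dtype=int)
    return GenotypeMatrix(geno, [f"s{i}" for i in range(n)], unigenes, positions)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest 4-population dataset shared across read-only tests."""
    cfg = SimConfig(
        n_pops=4, n_ind_per_pop=[10, 10, 8, 10], n_loci=400, n_genes=200,
        fst_target=0.2, seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def hwe_matrix():
    """2000 loci drawn in Hardy-Weinberg proportions for a single deme."""
    rng = np.random.default_rng(0)
    p = rng.uniform(0.1, 0.9, 2000)
    g = rng.binomial(2, p, (30, 2000)).astype(float)
    return make_genotype_matrix(g)
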