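import numpy as np
import pytest

from epiblup.genio import GenotypeData
from epiblup.simgen import SimConfig, simulate_genotypes, simulate_phenotypes


@pytest.fixture
def tiny_geno() -> GenotypeData:
    """3 individuals x 2 SNPs with counts rows [2,0], [1,1], [0,2] (p = 0.5, 0.5)."""
    return GenotypeData(
        individual_ids=["a", "b", "c"],
        snp_ids=["s1", "s2"],
        chromosomes=np.array(["1", "2"], dtype=object),
        positions=np.array([100, 200]),
        counts=np.array([[2.0, 0.0], [1.0, 1.0], [0.0, 2.0]]),
    )


def make_random_geno(
    n: int, m: int, seed: int, n_chrom: int = 2, external_freqs: bool = False
) -> GenotypeData:
    """Random HWE genotypes; external_freqs decouples the coding frequencies
    from the sample so the resulting relationship matrices are nonsingular."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.2, 0.8, m)
    counts = ((rng.random((n, m)) < p).astype(float) + (rng.random((n, m)) < p))
    # guarantee polymorphism at tiny n
    for j in range(m):
        while counts[:, j].min() == counts[:, j].max():
            counts[:, j] = (rng.random(n) < p[j]).astype(float) + (rng.random(n) < p[j])
    per = m // n_chrom
    chroms = np.array(
        [f"c{min(j // per + 1, n_chrom)}" for j in range(m)], dtype=object
    )
    return GenotypeData(
        individual_ids=[f"i{j}" for j in range(n)],
        snp_ids=[f"s{j}" for j in range(m)],
        chromosomes=chroms,
        positions=np.arange(m) * 1000 + 1,
        counts=counts,
        freqs=p if external_freqs else None,
    )


@pytest.fixture
def random_geno_factory():
    return make_random_geno


@pytest.fixture(scope="session")
def sim_dataset():
    """Shared small simulated dataset: additive + pairwise epistasis trait."""
    cfg = SimConfig(n=150, chromosomes=(25, 25), fractions={"A": 0.3, "AA": 0.2}, seed=42)
    geno, hap = simulate_genotypes(cfg)
    pheno, truth = simulate_phenotypes(cfg, geno, hap)
    return cfg, geno, hap, pheno, truth
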