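import numpy as np
import pandas as pd
import pytest

from gpsel.genotypes import GenotypeMatrix
from gpsel.sim import SimConfig, phenotype_vector, simulate_genotypes, simulate_phenotypes


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(
        n_animals=150, n_snps=400, n_chromosomes=3, n_qtl=8, seed=7, later_missing_rate=0.2
    )


@pytest.fixture(scope="session")
def small_herd(small_cfg):
    genotypes = simulate_genotypes(small_cfg)
    phenotypes, truth = simulate_phenotypes(genotypes, small_cfg)
    return genotypes, phenotypes, truth


@pytest.fixture(scope="session")
def small_y(small_cfg, small_herd):
    genotypes, phenotypes, _ = small_herd
    return phenotype_vector(phenotypes, small_cfg.trait_name, 6, genotypes.animal_ids)


def make_matrix(codes, chrom=None, bp=None) -> GenotypeMatrix:
    """Hand-built genotype matrix for toy examples."""
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    chrom = np.ones(m, dtype=int) if chrom is None else np.asarray(chrom)
    bp = np.arange(1, m + 1) * 100 if bp is None else np.asarray(bp)
    markers = pd.DataFrame(
        {"chrom": chrom, "snp": [f"s{j}" for j in range(m)], "cm": 0.0, "bp": bp}
    )
    return GenotypeMatrix(codes, [f"a{i}" for i in range(n)], markers)
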