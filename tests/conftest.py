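import numpy as np
import pytest

from twasprs import (GenotypeMatrix, resample_genotypes, synthesize_haplotypes)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_pool():
    """10-SNP haplotype pool with two LD blocks (rho = 0.5)."""
    return synthesize_haplotypes(10, block_structure=[(5, 0.5), (5, 0.5)],
                                 n_hap=2000, seed=11)


@pytest.fixture()
def small_geno(small_pool):
    return resample_genotypes(small_pool, 400, seed=21)


@pytest.fixture()
def toy_geno():
    """Tiny deterministic 4 x 3 genotype matrix for hand computations."""
    dosages = np.array([[0.0, 1.0, 2.0],
                        [1.0, 0.0, 1.0],
                        [2.0, 2.0, 0.0],
                        [1.0, 1.0, 1.0]])
    return GenotypeMatrix(dosages=dosages, snp_ids=["s1", "s2", "s3"],
                          sample_ids=["a", "b", "c", "d"],
                          effect_alleles=["A", "C", "G"],
                          other_alleles=["T", "G", "T"])
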