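import numpy as np
import pytest

from episcan import GenotypeDataset


@pytest.fixture
def toy_dataset() -> GenotypeDataset:
    """4 individuals (2 cases, 2 controls) x 2 SNPs, no missing data."""
    return GenotypeDataset(
        phenotype=np.array([1, 1, 0, 0]),
        genotypes=np.array([[0, 2], [1, 1], [2, 0], [1, 2]]),
        snp_ids=["rs1", "rs2"],
    )


def make_dataset(rng: np.random.Generator, n: int, m: int, missing_rate: float = 0.0):
    """Small random dataset for property tests; phenotype independent of genotypes."""
    geno = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    if missing_rate > 0:
        geno[rng.random(geno.shape) < missing_rate] = -1
    phen = rng.integers(0, 2, size=n).astype(np.int8)
    return GenotypeDataset(phen, geno, [f"rs{j}" for j in range(m)])
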