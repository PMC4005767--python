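import numpy as np
import pytest

from pairstab import GenotypeMatrix, Phenotype


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_dataset():
    """6-sample, 2-SNP toy: controls carry pairs (0,0),(0,1),(1,1); cases (1,1),(2,2),(2,2)."""
    geno = np.array(
        [
            [0, 0],
            [0, 1],
            [1, 1],
            [1, 1],
            [2, 2],
            [2, 2],
        ],
        dtype=np.int8,
    )
    matrix = GenotypeMatrix(geno, ["snpA", "snpB"], [f"s{i}" for i in range(6)])
    phenotype = Phenotype(np.array([0, 0, 0, 1, 1, 1], dtype=np.int8))
    return matrix, phenotype


def random_dataset(rng, n_samples=60, n_snps=8, missing_rate=0.05):
    """Small random dataset with both phenotype classes guaranteed."""
    geno = rng.integers(0, 3, size=(n_samples, n_snps)).astype(np.int8)
    if missing_rate:
        mask = rng.random(geno.shape) < missing_rate
        geno[mask] = -1
    labels = np.zeros(n_samples, dtype=np.int8)
    labels[: n_samples // 2] = 1
    rng.shuffle(labels)
    matrix = GenotypeMatrix(geno, [f"snp{i}" for i in range(n_snps)], [f"s{i}" for i in range(n_samples)])
    return matrix, Phenotype(labels)
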