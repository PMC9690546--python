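import numpy as np
import pytest

from breedgate.io_genotypes import GenotypeDataset, MarkerInfo, MISSING
from breedgate.synth_breeds import paper_like_fixture_full


def make_dataset(calls, breeds=None, chrom=None, alleles=None, prefix="S"):
    """Small dataset builder for hand-constructed genotype matrices."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    breeds = breeds or ["X"] * n
    chrom = chrom or ["1"] * m
    alleles = alleles or [("A", "G")] * m
    markers = [
        MarkerInfo(f"m{j + 1}", chrom[j], 1000 * (j + 1), *alleles[j]) for j in range(m)
    ]
    samples = [(f"{prefix}{i + 1}", breeds[i]) for i in range(n)]
    return GenotypeDataset(samples=samples, markers=markers, calls=calls)


def random_dataset(rng, n_samples=10, n_markers=20, missing_rate=0.1, n_breeds=2):
    calls = rng.integers(0, 3, size=(n_samples, n_markers)).astype(np.int8)
    if missing_rate:
        calls[rng.random(calls.shape) < missing_rate] = MISSING
    breeds = [f"B{rng.integers(n_breeds)}" for _ in range(n_samples)]
    return make_dataset(calls, breeds=breeds)


@pytest.fixture(scope="session")
def study_fixture():
    """One study-shaped synthetic dataset shared across the session."""
    return paper_like_fixture_full(1)


@pytest.fixture
def toy_2x3():
    return make_dataset([[0, 1, 2], [2, MISSING, 0]], breeds=["X", "Y"])
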