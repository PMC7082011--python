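import numpy as np
import pytest

from mitopop import SimulationConfig, collapse_haplotypes, make_alignment, simulate_dataset


@pytest.fixture
def toy_alignment():
    """Three specimens, two sites, one segregating site."""
    return make_alignment(
        [
            ("sp1", "north", "ACGT"),
            ("sp2", "north", "ACGT"),
            ("sp3", "south", "ACGA"),
        ]
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A compact two-haplogroup dataset shared by the slower tests."""
    cfg = SimulationConfig(
        n_per_site=(20, 20, 20, 20, 20, 20),
        seed=20240101,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_haplotypes(small_dataset):
    return collapse_haplotypes(small_dataset.alignment)


def brute_force_differences(seqs, ignore_missing=True):
    """Independent nested-loop pairwise-difference oracle."""
    n = len(seqs)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d = 0
            for a, b in zip(seqs[i], seqs[j]):
                if ignore_missing and (a in "-N" or b in "-N"):
                    continue
                if a != b:
                    d += 1
            out[i, j] = d
    return out
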