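import numpy as np
import pytest

from svlocus import genome, simulate


@pytest.fixture(scope="session")
def landmarks():
    return genome.build_reference_locus()


@pytest.fixture(scope="session")
def presets(landmarks):
    return genome.allele_presets(landmarks)


@pytest.fixture(scope="session")
def sim_params(landmarks):
    return simulate.SimParams(region=landmarks.region)


@pytest.fixture(scope="session")
def topologies():
    return simulate.default_topologies()


@pytest.fixture(scope="session")
def expected_active(landmarks, presets, sim_params, topologies):
    """Noise-free active-state maps per allele, reference coordinates."""
    out = {}
    for name in ("WT", "Inv1", "Inv2", "Rel1", "Rel2", "Rel3"):
        E = simulate.expected_matrix(presets[name], topologies["active"],
                                     sim_params, landmarks)
        bmap = genome.allele_bin_map(presets[name], landmarks.region,
                                     landmarks.bin_size)
        out[name] = genome.remap_matrix(E, bmap, landmarks.n_bins)
    return out


@pytest.fixture
def toy_region():
    """Six 5-kb bins starting at 1."""
    return genome.GenomicInterval("chrT", 1, 30_000)


def random_symmetric_counts(rng: np.random.Generator, n: int,
                            density: float = 0.5, high: int = 50):
    """Symmetric non-negative integer matrix helper shared across tests."""
    upper = rng.integers(0, high, size=(n, n))
    upper[rng.random((n, n)) > density] = 0
    m = np.triu(upper)
    return m + np.triu(m, 1).T
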