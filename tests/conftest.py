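import numpy as np
import pytest

import mitophylo as mp

PRESET_SEED = 101


@pytest.fixture(scope="session")
def preset():
    """Default six-clade, four-leaves-per-clade simulated dataset."""
    cfg = mp.SimulationConfig()
    genomes, truth = mp.simulate_dataset(cfg, seed=PRESET_SEED)
    return cfg, genomes, truth


@pytest.fixture(scope="session")
def preset_matrix(preset):
    _, genomes, _ = preset
    return mp.build_supermatrix(genomes)


@pytest.fixture(scope="session")
def preset_nj(preset_matrix):
    return mp.neighbor_joining(mp.pairwise_differences(preset_matrix))


@pytest.fixture(scope="session")
def small():
    """Two leaves per clade: 12 taxa, cheap enough for ML-heavy tests."""
    cfg = mp.SimulationConfig(leaves_per_clade=2)
    genomes, truth = mp.simulate_dataset(cfg, seed=11)
    return cfg, genomes, truth


@pytest.fixture(scope="session")
def small_matrix(small):
    _, genomes, _ = small
    return mp.build_supermatrix(genomes)


@pytest.fixture(scope="session")
def small_ml(small_matrix):
    return mp.ml_search(small_matrix, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230609)
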