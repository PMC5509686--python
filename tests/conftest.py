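import numpy as np
import pytest

from beedelim.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def clean_dataset():
    """A noiseless inventory: perfect labels, both loci everywhere."""
    config = SimulationConfig(
        n_species=20, seed=3, missing_locus_rate=0.0, morph_error=(0.0, 0.0, 0.0)
    )
    return config, simulate_dataset(config)


@pytest.fixture(scope="session")
def benchmark_dataset():
    """The 30-species benchmark under the default (noisy) study conditions."""
    config = SimulationConfig(n_species=30, seed=1)
    return config, simulate_dataset(config)


@pytest.fixture(scope="session")
def gap_dataset():
    """Default conditions except that every specimen carries both loci,
    so every pairwise distance is a genuine two-locus combination."""
    config = SimulationConfig(n_species=30, seed=1, missing_locus_rate=0.0)
    return config, simulate_dataset(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
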