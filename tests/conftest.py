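import pytest

from agochip.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def sim():
    """One default-condition synthetic dataset shared across tests."""
    return simulate_dataset(SimulationConfig(seed=101))


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """The same dataset written out as a file bundle."""
    out = tmp_path_factory.mktemp("bundle")
    simulate_dataset(SimulationConfig(seed=101), out)
    return out
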