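import numpy as np
import pytest

from spectrakin import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def desk_data():
    """One desk-scale simulated dataset shared by read-only tests."""
    cfg = SimConfig.desk_scale(seed=42, traits=("kCN", "bCN"))
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def desk_bundle(desk_data):
    return desk_data[0]


@pytest.fixture(scope="session")
def desk_truth(desk_data):
    return desk_data[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
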