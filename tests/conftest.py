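import numpy as np
import pytest

from crelink.simulate import SimConfig, generate_multiome


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def default_multiome(default_config):
    """One default-sized synthetic multiome shared across tests."""
    return generate_multiome(default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
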