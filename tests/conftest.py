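import numpy as np
import pytest

import reachbench as rb


@pytest.fixture(scope="session")
def small_config():
    """Reduced-size study configuration for fast unit tests."""
    return rb.SyntheticConfig(trials_per_target=2, n_channels=8)


@pytest.fixture(scope="session")
def small_session(small_config):
    return rb.gen_session(small_config, seed=1234)


@pytest.fixture(scope="session")
def small_recording(small_config, small_session):
    return rb.encode_neural(small_session, small_config, seed=1235)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
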