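import numpy as np
import pytest

from betapop.synthetic_data import GeneratorConfig, generate_session


@pytest.fixture(scope="session")
def small_day():
    """A small synthetic day shared by read-only tests."""
    config = GeneratorConfig(seed=7, n_trials_co=10, n_trials_per_target=5, n_units=8)
    session, truth = generate_session(config)
    return config, session, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
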