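import numpy as np
import pytest

from licktime.synthetic import SimConfig, simulate_session


@pytest.fixture(scope="session")
def small_bundle():
    """A modest simulated session shared by read-only tests."""
    return simulate_session(SimConfig(n_trials=40, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
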