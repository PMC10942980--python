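import numpy as np
import pytest

from overstride.simulate import SimConfig, simulate_participant


@pytest.fixture(scope="session")
def small_config():
    """Short trials, default noise levels."""
    return SimConfig(n_participants=2, tm_duration=8.0, og_duration=8.0,
                     seed=42)


@pytest.fixture(scope="session")
def small_participant(small_config):
    return simulate_participant(small_config, 0)


@pytest.fixture(scope="session")
def noiseless_participant():
    cfg = SimConfig(n_participants=1, tm_duration=6.0, og_duration=6.0,
                    seed=7).noiseless()
    return cfg, simulate_participant(cfg, 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
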