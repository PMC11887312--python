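import numpy as np
import pytest

from accelagree.synthetic_data import SimConfig, simulate_minute_streams


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Noise-free 5-subject stream configuration for exact round trips."""
    return SimConfig(n_subjects=5, days_per_subject=7, seed=11)


@pytest.fixture(scope="session")
def small_streams(small_config):
    """(ag, om, om_daily, truth) for the 5-subject noise-free fixture."""
    return simulate_minute_streams(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240304)
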