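import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nmmnet import (
    ColumnParams,
    DriveParams,
    SimulationConfig,
    make_toy_network,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """Canonical column constants."""
    return ColumnParams()


@pytest.fixture(scope="session")
def chaos_drive():
    """Driving point inside the chaotic domain (f = 8.5 Hz, delta/C = 0.49)."""
    return DriveParams(delta=0.49 * 133.5, f=8.5)


@pytest.fixture(scope="session")
def undriven():
    return DriveParams(delta=0.0)


@pytest.fixture(scope="session")
def short_config():
    """Small but attractor-reaching run for fast integration tests."""
    return SimulationConfig(t_total=10.0, t_transient=5.0, seed=0)


@pytest.fixture(scope="session")
def pair_topology():
    return make_toy_network("pair")


@pytest.fixture(scope="session")
def star_topology():
    return make_toy_network("star", 5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
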