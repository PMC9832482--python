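import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aedskit import (
    Coordinate,
    EndState,
    Harmonic,
    SimulationConfig,
    ThermoContext,
    ToySystem,
    make_t4l_like_toy,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ctx():
    return ThermoContext(300.0)


@pytest.fixture(scope="session")
def harmonic_1d():
    """A single harmonic endstate on one linear coordinate (k = 10)."""
    return ToySystem(
        [Coordinate("x", "linear", -10.0, 10.0)],
        [EndState("s01", 0.0, (Harmonic("x", 0.0, 10.0),))],
    )


@pytest.fixture(scope="session")
def two_state_toy():
    """Two endstates, modest orthogonal barrier (solvent-like conditions)."""
    return make_t4l_like_toy(2, barrier=6.0, preference_split=1, seed=7)


@pytest.fixture(scope="session")
def short_cfg():
    return SimulationConfig(n_steps=4000, stride=2, seed=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
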