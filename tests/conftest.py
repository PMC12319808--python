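import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ctspectra.ctmodel import CTParams, SimConfig, simulate, sweep_config

settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def params():
    """Normative resting-state parameters."""
    return CTParams()


@pytest.fixture(scope="session")
def normative_run(params):
    """One 60-s normative simulation at the default 1-ms step (shared
    across tests; the integrator is deterministic for a fixed config)."""
    return simulate(params, SimConfig(seed=1))


@pytest.fixture(scope="session")
def stable_run(params):
    """A simulation with the accurate sweep-grade integration settings,
    where the normative fixed point is a damped resonator."""
    return simulate(params, sweep_config(seed=3).replace(duration=60.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
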