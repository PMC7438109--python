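import numpy as np
import pytest

from preygaze.synthetic import SimulationParams, simulate_session


@pytest.fixture(scope="session")
def default_session():
    """One default 600 s session, shared across tests (deterministic)."""
    return simulate_session(SimulationParams(duration=600.0, seed=11))


@pytest.fixture(scope="session")
def short_session():
    return simulate_session(SimulationParams(duration=60.0, seed=23))


@pytest.fixture(scope="session")
def perfect_vor_session():
    """VOR gain 1, no saccade trigger, no noise: gaze must be constant."""
    return simulate_session(SimulationParams(
        duration=60.0, seed=5, saccade_trigger_deg=np.inf,
        sigma_meas=0.0, sigma_pos=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
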