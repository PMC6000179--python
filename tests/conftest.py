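"""Shared fixtures: expensive simulations are session-scoped and reused."""

import numpy as np
import pytest

from hsrsim import Step, final_parameters, integrate, steady_state
from hsrsim.protocols import DAY, HOUR, MINUTE, Sinusoid
from hsrsim.synthetic_data import NoiseSpec, generate_calibration_dataset


@pytest.fixture(scope="session")
def params():
    return final_parameters()


@pytest.fixture(scope="session")
def ss25(params):
    return steady_state(params, 25.0)


@pytest.fixture(scope="session")
def step_trajectory(params, ss25):
    """Typical heat shock: 25 -> 42 degC step at t = 20 min, 4 h of response."""
    return integrate(params, Step(25.0, 42.0, 20 * MINUTE),
                     4 * HOUR + 20 * MINUTE, init=ss25, n_points=1201)


@pytest.fixture(scope="session")
def diel_trajectory(params):
    """Sinusoidal hot day (22-40 degC), one spin-up day plus two scored days."""
    return integrate(params, Sinusoid(22.0, 40.0), 3 * DAY, n_points=2881)


@pytest.fixture(scope="session")
def clean_dataset(params):
    """Noise-free synthetic calibration dataset from the final parameters."""
    return generate_calibration_dataset(
        params, NoiseSpec(sigma=0.0, replicates=1, seed=1))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
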