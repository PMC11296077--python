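import numpy as np
import pytest

from bouncework import RunningWorkPartition, SimulationParams, WobbleParams
from bouncework.synthetic_data import simulate_trial

SEED = 3


@pytest.fixture(scope="session")
def rigid_sim():
    """Default rigid synthetic trial (10 strides, instrument noise)."""
    params = SimulationParams(n_strides=10)
    trial, truth = simulate_trial(params, seed=SEED)
    return params, trial, truth


@pytest.fixture(scope="session")
def rigid_results(rigid_sim):
    _, trial, _ = rigid_sim
    with np.errstate(all="ignore"):
        return RunningWorkPartition(trial).fit()


@pytest.fixture(scope="session")
def wobble_sim():
    """Same trial with the default wobbling-mass element (same seed)."""
    params = SimulationParams(n_strides=10, wobble=WobbleParams())
    trial, truth = simulate_trial(params, seed=SEED)
    return params, trial, truth


@pytest.fixture(scope="session")
def wobble_results(wobble_sim):
    _, trial, _ = wobble_sim
    return RunningWorkPartition(trial).fit()


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free rigid trial for oracle comparisons on the data path."""
    params = SimulationParams(n_strides=6, force_noise_sd=0.0,
                              marker_noise_sd=0.0)
    trial, truth = simulate_trial(params, seed=SEED)
    return params, trial, truth


@pytest.fixture(scope="session")
def clean_results(clean_sim):
    _, trial, _ = clean_sim
    return RunningWorkPartition(trial).fit()
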