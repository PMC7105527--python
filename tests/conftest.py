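import numpy as np
import pytest

from pibflow import phantom as ph
from pibflow.io_core import default_schedule


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def ctl_spec():
    """Small noise-free control phantom spec (keeps the suite fast)."""
    return ph.default_phantom_spec(grid_shape=(12, 12, 12), noise_scale=0.0, seed=11)


@pytest.fixture(scope="session")
def ctl_phantom(ctl_spec, schedule):
    """Noise-free dynamic phantom with ground truth, shared across tests."""
    return ph.make_dynamic_pet(ctl_spec, schedule)


@pytest.fixture(scope="session")
def gamma_input():
    """Dense gamma-variate bolus (undispersed, dispersed) pair."""
    return ph.make_input_function(peak_time=25.0, peak_value=80.0, tau=4.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
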