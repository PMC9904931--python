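import numpy as np
import pytest

from subwave import SignalPanel, simulate_cohort
from subwave.config import BoostingParams
from subwave.study import default_simulation_config


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small but structurally complete cohort: 40 patients, short series."""
    config = default_simulation_config(
        seed=5, n_patients=40, t_min=60, t_max=80
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def fast_boosting():
    return BoostingParams(n_estimators=12, max_depth=2, learning_rate=0.3)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def make_panel(rng, n_channels=3, n_times=50, pid="p1", state=None):
    channels = rng.normal(size=(n_channels, n_times))
    if state is None:
        state = (rng.random(n_times) < 0.3).astype(int)
    return SignalPanel(patient_id=pid, channels=channels, state=state)
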