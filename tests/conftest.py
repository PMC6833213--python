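import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from oursense import (  # noqa: E402
    ECOLI,
    OfflineDataset,
    OURSeries,
    discrete_stage_a_experiment,
)


@pytest.fixture(scope="session")
def ecoli_maintenance():
    return ECOLI.maintenance


@pytest.fixture(scope="session")
def exact_two_phase_experiment():
    """Offline dataset + cOUR series generated exactly by the discrete model."""
    return discrete_stage_a_experiment(alpha=1.01, k1=4e-3, t_i=10.0)


@pytest.fixture()
def small_offline_dataset():
    t = np.array([1.0, 2.0, 3.0])
    x = np.array([1.0, 2.0, 4.0])
    return OfflineDataset(sample_times=t, biomass=x, x0=1.0)
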