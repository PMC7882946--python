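import pytest
from hypothesis import HealthCheck, settings

import mirounga as mg

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config():
    return mg.SimConfig(
        n_females=6,
        n_males=6,
        seed=101,
        trip_length_days={"female": 180.0, "male": 200.0},
        trip_length_sd_days=10.0,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """A small but complete synthetic study shared across tests."""
    return mg.simulate_study(small_config)


@pytest.fixture(scope="session")
def bathy(small_study):
    return small_study.bathy


@pytest.fixture(scope="session")
def coast(bathy):
    return mg.coast_distance_grid(bathy)
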