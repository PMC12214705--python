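import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from braindiff import (
    SimulationConfig,
    generate_adolescent_cohort,
    generate_parcel_geometry,
    generate_reference_cohort,
)


@pytest.fixture(scope="session")
def small_geometry():
    return generate_parcel_geometry(20, seed=7)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_rois=20, n_ref_adults=80, n_adolescents=120, n_mortality=1500, seed=11
    )


@pytest.fixture(scope="session")
def reference_cohort(small_config, small_geometry):
    return generate_reference_cohort(small_config, small_geometry)


@pytest.fixture(scope="session")
def adolescent_cohort(small_config, small_geometry):
    return generate_adolescent_cohort(small_config, small_geometry)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
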