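import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from zfmri.synthetic import PhantomSpec, make_phantom

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

T1_TIMES = np.array([50.0, 150.0, 275.0, 450.0, 600.0])
T2_TIMES = np.array([12.2, 36.6, 60.94])


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Reduced grid so unit tests stay fast; geometry proportions preserved."""
    return PhantomSpec(shape=(32, 18, 20), voxel_size_mm=0.3, seed=42)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return make_phantom(small_spec)


@pytest.fixture(scope="session")
def default_phantom():
    return make_phantom(PhantomSpec(seed=7))
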