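import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from orthotrack.phantom4d import PhantomSpec, generate_phantom

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Coarse phantom for rendering-heavy tests."""
    return PhantomSpec(grid_shape=(64, 64, 48), spacing=(3.0, 3.0, 3.0))


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def default_phantom():
    """The study-conditions phantom (cohort-median tumor and motion)."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
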