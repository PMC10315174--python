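import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from canevo import make_fixture

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_fixture():
    """Deterministic 6-gene, 2-trait map with founder and environments."""
    return make_fixture("tiny", seed=7)


@pytest.fixture(scope="session")
def small_fixture():
    """Deterministic 100-gene, 20-trait map with founder and environments."""
    return make_fixture("small", seed=7)
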