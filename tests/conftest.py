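import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from squeezefilm.hydrodynamics import WATER, REFERENCE_PATCH

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def water():
    return WATER


@pytest.fixture(scope="session")
def reference_patch():
    return REFERENCE_PATCH


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230629)
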