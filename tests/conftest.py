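import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from speedprior.design import build_design

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def af_design():
    return build_design("af")


@pytest.fixture(scope="session")
def contrast_design():
    return build_design("contrast")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
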