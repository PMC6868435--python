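import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fretforce as ff

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schedule():
    """Default experimental loading schedule (14.00 -> 16.96 um at 455 nm/s)."""
    return ff.loading_schedule()


@pytest.fixture(scope="session")
def tether():
    return ff.TetherModel()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
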