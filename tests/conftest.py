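import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", max_examples=25, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def medin_table():
    from fibrilstack.datasets import medin_shift_table
    return medin_shift_table()


@pytest.fixture(scope="session")
def cd_basis():
    from fibrilstack.cd import default_basis
    return default_basis()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
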