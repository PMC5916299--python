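import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from divefmr.fixtures import load_fixtures

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tables():
    return load_fixtures()


@pytest.fixture(scope="session")
def merged(tables):
    return tables.merged


@pytest.fixture()
def rng():
    return np.random.default_rng(20180402)
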