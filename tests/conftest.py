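import pytest
from hypothesis import HealthCheck, settings

from qbbn import fixtures

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toys():
    return fixtures.toy_fixtures()


@pytest.fixture(scope="session")
def chain2(toys):
    return toys.networks["chain2"]


@pytest.fixture(scope="session")
def chain6(toys):
    return toys.networks["chain6"]


@pytest.fixture(scope="session")
def recip2(toys):
    return toys.networks["recip2"]


@pytest.fixture(scope="session")
def web8(toys):
    return toys.networks["web8"]
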