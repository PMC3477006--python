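import pytest
from hypothesis import HealthCheck, settings

from oborel import fixtures

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def pro():
    return fixtures.pro_fragment()


@pytest.fixture
def xao():
    return fixtures.xao_fragment()


@pytest.fixture
def go_root():
    return fixtures.go_root_fragment()


@pytest.fixture
def go_mi():
    return fixtures.go_mi_fragment()
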