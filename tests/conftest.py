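import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from cosolvency import ppn_fixture
from cosolvency.piperine import PIPERINE_FUSION, PIPERINE_MASSES


@pytest.fixture(scope="session")
def ppn():
    """The packaged piperine / THP / water solubility grid (55 records)."""
    return ppn_fixture()


@pytest.fixture(scope="session")
def fusion():
    return PIPERINE_FUSION


@pytest.fixture(scope="session")
def masses():
    return PIPERINE_MASSES
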