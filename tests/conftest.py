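import pytest

from neuropep.fixtures import PresenceFixture, observations_from_fixture
from neuropep.simulate import synthetic_precursors
from neuropep.types import FilterConfig, default_design


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def precursors():
    return synthetic_precursors()


@pytest.fixture(scope="session")
def fixture_observations(design, precursors):
    """Minimal noiseless table realizing the printed 29x4 presence matrix."""
    return observations_from_fixture(PresenceFixture(), design, precursors)
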