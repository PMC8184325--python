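import pytest

from ctmsmt import (
    CouplingModel,
    HHParameters,
    PulseSpec,
    SimulationConfig,
    find_resting_state,
)


@pytest.fixture(scope="session")
def params():
    return HHParameters()


@pytest.fixture(scope="session")
def config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def coupling():
    return CouplingModel()


@pytest.fixture(scope="session")
def resting(params, config):
    return find_resting_state(params, config)


@pytest.fixture(scope="session")
def reference_pulse():
    """The 60 us, m = 0.2 unidirectional pulse whose published RMT anchors validation."""
    return PulseSpec(family="unidirectional", main_pw=60.0, m_ratio=0.2, direction="AP")
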