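import pytest

from liverecon import SimulationClock, load_parameters
from liverecon.scenarios import baseline_bundle


@pytest.fixture(scope="session")
def baseline():
    """The packaged published input table."""
    return load_parameters("table1_baseline")


@pytest.fixture(scope="session")
def bundle():
    """Baseline table plus published with-MELD anchors."""
    return baseline_bundle()


@pytest.fixture(scope="session")
def clock():
    return SimulationClock()


def override(overrides: dict):
    """Baseline table with the named base values replaced."""
    return load_parameters({"baseline": "table1_baseline", "overrides": overrides})
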