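import hypothesis
import pytest

from revpot import GradientSet, SpeciesTerm, TransportCycle
from revpot import scenarios

hypothesis.settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=60
)
hypothesis.settings.load_profile("suite")


@pytest.fixture
def vcindy_cycle():
    return scenarios.vcindy_cycle()


@pytest.fixture
def screen_gradients():
    """1:4 inward Na+ gradient, 10:1 outward succinate gradient (1 uM in)."""
    return scenarios.vcindy_screen_gradients()


@pytest.fixture
def population():
    return scenarios.default_population()
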