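import numpy as np
import pytest

from homeoplast.synth import GeneratorSpec
from homeoplast.traces import StimulusSchedule


@pytest.fixture(scope="session")
def control_spec() -> GeneratorSpec:
    return GeneratorSpec.for_scenario("young_control", seed=11)


@pytest.fixture(scope="session")
def young_stim_spec() -> GeneratorSpec:
    return GeneratorSpec.for_scenario("young_stim", seed=11)


@pytest.fixture(scope="session")
def old_stim_spec() -> GeneratorSpec:
    return GeneratorSpec.for_scenario("old_stim", seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def flicker_schedule() -> StimulusSchedule:
    """One 85 s trial: 17 cycles of 3 s flicker-on / 2 s off."""
    return StimulusSchedule.flicker_trial(n_events=17)
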