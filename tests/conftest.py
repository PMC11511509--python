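import numpy as np
import pytest

from spinekin.config import CUED_SIGN, MOVEMENTS, SEGMENTS, PipelineConfig
from spinekin.synthetic import (
    BASE_AMPLITUDES,
    MotionScenario,
    NoiseModel,
    truth_trajectories,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240613)


@pytest.fixture
def config():
    return PipelineConfig()


def default_scenario(participant="S01", trial=1, movements=MOVEMENTS,
                     sec=4.0, ter=2.0, **kwargs) -> MotionScenario:
    amps = {
        (s, m): (CUED_SIGN[m] * BASE_AMPLITUDES[(s, m)], sec, ter)
        for s in SEGMENTS for m in movements
    }
    return MotionScenario(participant, trial, amps, **kwargs)


@pytest.fixture
def scenario():
    return default_scenario()


@pytest.fixture
def truths(scenario):
    return truth_trajectories(scenario)


@pytest.fixture
def noise_free():
    return NoiseModel.noise_free()
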