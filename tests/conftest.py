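import logging

import numpy as np
import pytest

from collarmotion import synthetic as syn
from collarmotion.trace import CalibrationParams

# the singular-fit warning is expected on synthetic data where all
# individuals share one generator; keep test output readable
logging.getLogger("collarmotion.ethogram").setLevel(logging.ERROR)

BASE_SEED = 1


@pytest.fixture(scope="session")
def miscalib() -> CalibrationParams:
    """The worked-example sensor-error parameters used throughout."""
    return CalibrationParams(offset=[0.1, -0.2, 0.05], scale=[1.1, 0.9, 1.05])


@pytest.fixture(scope="session")
def small_dataset():
    """A mixed-behavior labeled dataset big enough to train on (~500 windows)."""
    sched = syn.Schedule.uniform_random(1000, seed=BASE_SEED)
    return syn.gen_dataset(sched, fs=64, seed=BASE_SEED)


@pytest.fixture(scope="session")
def rest_trace():
    return syn.gen_behavior_trace(
        syn.DEFAULT_BEHAVIORS["rest"], duration=60, fs=64, seed=BASE_SEED
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(BASE_SEED)
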