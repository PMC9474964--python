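import numpy as np
import pytest

from dtwpet import (
    InputFunction,
    KineticParams,
    build_frame_schedule,
    feng_input,
    model_tac,
)

# canonical tissue parameter sets used across the suite
CORTEX = KineticParams(0.10, 0.13, 0.06, 0.045)
MUSCLE = KineticParams(0.03, 0.22, 0.02, 0.025)
TUMOR = KineticParams(0.35, 0.40, 0.10, 0.080)


@pytest.fixture(scope="session")
def schedule():
    return build_frame_schedule()


@pytest.fixture(scope="session")
def input_fn():
    return feng_input()


@pytest.fixture(scope="session")
def cortex_tac(schedule, input_fn):
    return model_tac(input_fn, CORTEX, schedule)


@pytest.fixture(scope="session")
def tissue_cases(schedule, input_fn):
    """(name, params, noise-free frame-averaged TAC) for three tissues."""
    return [
        (name, p, model_tac(input_fn, p, schedule))
        for name, p in [("cortex", CORTEX), ("muscle", MUSCLE), ("tumor", TUMOR)]
    ]
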