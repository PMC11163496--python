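import numpy as np
import pytest

from qaerr.dose import EngineParams, synthesize_plan
from qaerr.plans import Beam, ControlPoint


@pytest.fixture
def single_pair_beam() -> Beam:
    """Two-control-point beam with one fully open leaf pair at +/-50 mm."""
    cps = (
        ControlPoint(np.array([-50.0]), np.array([50.0]), 0.0),
        ControlPoint(np.array([-50.0]), np.array([50.0]), 1.0),
    )
    return Beam("b0", "p0", cps)


@pytest.fixture
def synth_beam() -> Beam:
    return synthesize_plan(1, seed=7)[0]


@pytest.fixture
def engine() -> EngineParams:
    return EngineParams(seed=5)


@pytest.fixture
def noiseless_engine() -> EngineParams:
    return EngineParams(noise_sd_fraction=0.0, seed=5)
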