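import numpy as np
import pytest

from leadtto.core import (
    CHINA_EXPERIMENTAL,
    CHINA_STANDARD,
    SINGAPORE_EXPERIMENTAL,
    SINGAPORE_STANDARD,
)
from leadtto.respondents import ProfileParams, RespondentProfile, StudyDesign, simulate_study

#: Fixed seed for every stochastic test in the suite.
SUITE_SEED = 20130731


@pytest.fixture
def cfg10():
    """Standard arm: 10-year lead time over 5 unhealthy years."""
    return CHINA_STANDARD


@pytest.fixture
def cfg5():
    """Experimental lead-time arm: 5-year lead time over 5 unhealthy years."""
    return CHINA_EXPERIMENTAL


@pytest.fixture
def sg_configs():
    return {"standard": SINGAPORE_STANDARD, "experimental": SINGAPORE_EXPERIMENTAL}


def exact_agent(u, state="11145", **kwargs):
    """Error-free agent: zero noise, zero tolerance, no biases."""
    return RespondentProfile("a0", {state: u}, **kwargs)


@pytest.fixture
def small_study():
    """A small two-arm lead-time study with realistic noise, for QC/analysis."""
    params = ProfileParams(
        state_sd=0.3,
        respondent_sd=0.2,
        decision_sd=0.15,
        indifference_tol=0.05,
        framing_coeff=0.0,
        visual_error_coeff=0.0,
        engagement_gain=0.0,
        time_sd=0.4,
    )
    design = StudyDesign(n_per_arm=40, seed=SUITE_SEED)
    configs = {"standard": CHINA_STANDARD, "experimental": CHINA_EXPERIMENTAL}
    return simulate_study(design, params, configs)
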