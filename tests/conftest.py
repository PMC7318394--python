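import numpy as np
import pytest

from pisa import (
    KMCurveGrid,
    ParametricArm,
    SyntheticTrialSpec,
    generate_trial,
    time_gain,
    time_lost,
)

LAMBDA_C = 0.01
LAMBDA_A = 0.008


@pytest.fixture(scope="session")
def exp_arms():
    """Exponential control/active arms with a realistic CV-prevention effect."""
    return (
        ParametricArm("exponential", {"hazard": LAMBDA_C}),
        ParametricArm("exponential", {"hazard": LAMBDA_A}),
    )


@pytest.fixture(scope="session")
def exp_trial(exp_arms):
    """Exact-curve 60-month exponential trial (no noise), t50 = T/2."""
    control, active = exp_arms
    spec = SyntheticTrialSpec(control=control, active=active, duration_T=60.0)
    return generate_trial(spec)


@pytest.fixture(scope="session")
def exp_gain(exp_trial):
    return time_gain(time_lost(exp_trial.control), time_lost(exp_trial.active))


def make_grid(incidence, step=0.25, label="arm"):
    incidence = np.asarray(incidence, dtype=float)
    times = np.arange(incidence.size) * step
    return KMCurveGrid(step, times, incidence, arm_label=label)


@pytest.fixture
def grid_factory():
    return make_grid
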