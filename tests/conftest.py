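import numpy as np
import pytest

from doxodyn.data_model import Condition, MultiDoseParams, TimeCourse, TreatmentSchedule


@pytest.fixture
def cond():
    return Condition(1, 75.0, None, 1)


@pytest.fixture
def logistic_tc(cond):
    """Clean logistic series, well below carrying capacity."""
    t = np.arange(0.0, 300.0, 4.0)
    n = 50000.0 * 2000.0 * np.exp(0.025 * t) / (50000.0 + 2000.0 * (np.exp(0.025 * t) - 1.0))
    return TimeCourse(t, n, "rep1", cond)


@pytest.fixture
def single_dose_params():
    return MultiDoseParams(
        g0=0.025, gs=0.012, gd=0.018, kd=-0.03,
        theta_u=53873.0, theta_dox=45000.0,
        fs=[0.3], gamma_d=[0.03], N0=2000.0, mode="constant",
    )


@pytest.fixture
def two_dose_params():
    return MultiDoseParams(
        g0=0.025, gs=0.012, gd=0.018, kd=-0.03,
        theta_u=53873.0, theta_dox=45000.0,
        fs=[0.3, 0.4], gamma_d=[0.03, 0.02], N0=2000.0, mode="adaptive",
    )


@pytest.fixture
def schedule_1dose():
    return TreatmentSchedule([48.0], [75.0])


@pytest.fixture
def schedule_2dose():
    return TreatmentSchedule([48.0, 288.0], [75.0, 75.0])
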