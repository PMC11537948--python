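import warnings

import numpy as np
import pandas as pd
import pytest

from lmsref.simulate import SyntheticCohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by read-only tests."""
    return generate_cohort(SyntheticCohortSpec(n=600), seed=42)


@pytest.fixture(scope="session")
def healthy_row():
    """One subject row passing every eligibility rule."""
    return {
        "id": "X1", "sex": "female", "age": 9.0, "weight": 30.0,
        "height": 135.0, "triceps_sf": 10.0, "calf_sf": 9.0, "thigh_sf": 12.0,
        "glucose": 85.0, "total_chol": 150.0, "hdl": 55.0, "ldl": 90.0,
        "triglycerides": 70.0, "insulin": 8.0, "sbp": 95.0, "dbp": 60.0,
        "tanner": 1, "bmi_z": 0.2,
    }


def one_row_frame(base: dict, **overrides) -> pd.DataFrame:
    row = dict(base)
    row.update(overrides)
    return pd.DataFrame([row])


@pytest.fixture
def constant_lms_curve():
    """An age-constant fitted curve (L=1, M=10, S=0.1) for table tests."""

    class _Const:
        age_range_ = (4.0, 21.0)

        def predict_params(self, ages):
            ages = np.asarray(ages, float)
            lo, hi = self.age_range_
            if np.any((ages < lo) | (ages > hi)):
                raise ValueError("age outside range")
            one = np.ones_like(ages)
            return one * 1.0, one * 10.0, one * 0.1

    return _Const()


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*GCV minimum.*")
        warnings.filterwarnings("ignore", message=".*z-score beyond.*")
        yield
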