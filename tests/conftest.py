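import numpy as np
import pandas as pd
import pytest

from chime.core import (
    BASELINE_COLUMNS,
    BIOMARKERS,
    HISTORY_FLAGS,
    MEDICATIONS,
)
from chime.synthetic import default_bundle, default_profile, generate_cohort


def make_baseline_row(pid="p1", age=60.0, sex="female",
                      glycemic_status="prediabetes", duration=0.0,
                      smoking="never", **biomarker_overrides):
    """One valid baseline CSV row as a dict."""
    biomarkers = {"bmi": 25.0, "hba1c": 6.0, "sbp": 130.0, "dbp": 78.0,
                  "hdl": 1.3, "ldl": 3.0, "triglycerides": 1.5,
                  "egfr": 90.0, "hemoglobin": 13.5, "wbc": 7.0}
    biomarkers.update(biomarker_overrides)
    row = {"id": pid, "age": age, "sex": sex,
           "glycemic_status": glycemic_status, "duration": duration,
           "smoking": smoking}
    row.update(biomarkers)
    row.update({m: 0 for m in MEDICATIONS})
    row.update({h: 0 for h in HISTORY_FLAGS})
    return row


def baseline_frame(rows):
    return pd.DataFrame(rows, columns=list(BASELINE_COLUMNS))


@pytest.fixture(scope="session")
def bundle():
    return default_bundle()


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort (baseline, panel) with the default truth."""
    profile = default_profile(n=800, follow_up=6)
    baseline, panel, manifest = generate_cohort(profile, seed=20240)
    return baseline, panel, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
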