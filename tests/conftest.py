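import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from depcea import SyntheticTrialConfig, generate_cohort
from depcea.imputation import impute_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Trial-sized cohort (202/204) under the default study conditions."""
    return generate_cohort(SyntheticTrialConfig(), seed=0)


@pytest.fixture(scope="session")
def completed_default(default_cohort):
    return impute_cohort(default_cohort)


@pytest.fixture(scope="session")
def large_full_cohort():
    """n=10,000/arm with no dropout, for calibration checks."""
    cfg = SyntheticTrialConfig()
    cfg.n_intervention = cfg.n_control = 10000
    for arm in cfg.dropout_prob_by_wave_and_arm:
        cfg.dropout_prob_by_wave_and_arm[arm] = (0.0, 0.0, 0.0)
    return generate_cohort(cfg, seed=11)


@pytest.fixture()
def toy_breakdown():
    """Two participants per arm with simple hand-checkable costs."""
    cats = {
        "intervention": [299, 299, 10, 10],
        "gp_internist": [100, 200, 50, 150],
        "mental_health": [0, 80, 40, 0],
        "other_specialist": [0, 0, 0, 0],
        "inpatient": [0, 400, 0, 0],
        "daycare": [0, 0, 0, 100],
        "antidepressants": [10, 0, 0, 20],
        "private_therapist": [0, 50, 0, 0],
        "copayments": [5, 5, 5, 5],
        "otc": [0, 10, 10, 0],
        "informal_care": [0, 0, 100, 0],
        "domestic_help": [0, 0, 0, 0],
        "travel": [3, 6, 3, 0],
        "absenteeism": [1000, 0, 500, 500],
        "presenteeism": [0, 240, 0, 0],
        "opportunity_time": [69.3, 69.3, 11.55, 11.55],
    }
    return pd.DataFrame({
        "pid": [0, 1, 2, 3],
        "arm": ["intervention", "intervention", "control", "control"],
        **cats,
    })


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
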