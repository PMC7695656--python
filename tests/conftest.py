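import logging
import warnings

import numpy as np
import pandas as pd
import pytest

logging.getLogger("arviz").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def small_cohort():
    """Small default-condition synthetic cohort shared across tests."""
    from dietnafld.simulate import SimConfig, generate_cohort

    cohort, truth = generate_cohort(SimConfig(n_participants=300, seed=101))
    return cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def eligible_row():
    """A single participant row passing every exclusion rule."""
    return {
        "has_ultrasound": 1, "energy_kcal": 1932.0, "lsm_kpa": 4.9,
        "lsm_iqr_kpa": 0.7, "te_attempts": 2, "viral_hepatitis": 0,
        "alcohol_units": 0.49, "sex": "female", "steatogenic_drugs": 0,
        "intracardiac_device": 0, "steatosis": 0,
    }


def make_roster(eligible_row, overrides_list):
    rows = []
    for ov in overrides_list:
        row = dict(eligible_row)
        row.update(ov)
        rows.append(row)
    return pd.DataFrame(rows)
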