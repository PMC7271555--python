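from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from actiplan import DailyCohortConfig, generate_daily_cohort
from actiplan.cohort import CohortDataset


@pytest.fixture(scope="session")
def recovery_cohort():
    """Large simulated cohort used for parameter-recovery checks.

    500 subjects x 28 days, between-subject variance 100 and
    within-subject variance 25, so the true ICC is 0.8.
    """
    return generate_daily_cohort(
        DailyCohortConfig(
            mu=60.0,
            sigma_b2=100.0,
            sigma_w2=25.0,
            n_subjects=500,
            days_per_subject=28,
            seed=1,
        )
    )


def make_valid_day_cohort(n_subjects=5, n_days=28, seed=0, mu=60.0):
    """Small deterministic valid-day cohort table for subset tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        for d in range(n_days):
            rows.append(
                {
                    "subject_id": sid,
                    "date": date(2020, 1, 6) + timedelta(days=d),
                    "value": float(mu + rng.normal(0, 5)),
                }
            )
    return CohortDataset(pd.DataFrame(rows), label="all_days")


@pytest.fixture
def small_cohort():
    return make_valid_day_cohort()
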