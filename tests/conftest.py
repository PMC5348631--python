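import numpy as np
import pandas as pd
import pytest

import tagdisc as td


@pytest.fixture(scope="session")
def schedule():
    """A fixed 216-trial session at the cohort-typical discount rate."""
    return td.build_session(0.085, seed=11)


@pytest.fixture(scope="session")
def simulated_choices(schedule):
    return td.simulate_choices(schedule, 0.085, 2.0, rng=5)


@pytest.fixture()
def ten_trial_fixture():
    """Small hand-checkable choice table (single condition)."""
    return pd.DataFrame({
        "subject_id": 0,
        "condition": "control",
        "delay_days": [1, 2, 6, 7, 13, 15, 28, 32, 85, 170],
        "amount_eur": [21.0, 24.0, 30.5, 33.0, 42.0, 46.5, 61.0, 70.0, 79.5, 79.5],
        "choice": ["delayed", "immediate", "delayed", "delayed", "immediate",
                   "delayed", "immediate", "delayed", "immediate", "immediate"],
        "rt_ms": 900.0,
    })


@pytest.fixture(scope="session")
def small_cohort():
    """Five-subject cohort with full trial tables, for pipeline tests."""
    spec = td.CohortSpec(n_subjects=5, seed=42)
    return td.simulate_cohort(spec)
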