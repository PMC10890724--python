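import numpy as np
import pytest

from vlsupp.prep import build_analysis_table
from vlsupp.simulate import SimulationConfig, generate_cohort, generate_outcomes


@pytest.fixture(scope="session")
def small_config():
    """A fast ~260-person cohort with the default generative truth."""
    return SimulationConfig(
        n_per_regimen={"EFV": 120, "ATVr": 100, "DTG": 40}, seed=3
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    cohort = generate_cohort(small_config)
    vl = generate_outcomes(cohort, small_config)
    return cohort, vl


@pytest.fixture(scope="session")
def small_table(small_dataset):
    cohort, vl = small_dataset
    table, report = build_analysis_table(cohort, vl)
    return table, report


def full_attendance_config(**overrides):
    """Everyone attends every visit exactly on schedule (no jitter)."""
    base = dict(
        n_per_regimen={"EFV": 30, "ATVr": 30, "DTG": 20},
        attendance_prob={
            r: {w: 1.0 for w in (12, 24, 48, 72, 96)} for r in ("EFV", "ATVr", "DTG")
        },
        jitter_sd=0.0,
        out_of_window_prob=0.0,
        seed=11,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def force_full_followup(cohort):
    """Give every person 700 days of follow-up regardless of calendar."""
    import datetime as dt

    import pandas as pd

    out = cohort.copy()
    end = pd.to_datetime(out["baseline_date"]) + pd.Timedelta(days=700)
    out["end_date"] = end.dt.date.astype(str)
    return out
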