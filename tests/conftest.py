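import datetime as dt

import numpy as np
import pandas as pd
import pytest

from pdhf.cohort import (
    Cohort,
    CohortConfig,
    DailyRecord,
    PatientProfile,
    PatientSeries,
    generate_cohort,
)


def make_series(
    values: dict[str, np.ndarray],
    patient_id: str = "P0",
    start: dt.date = dt.date(2020, 1, 1),
    hf_date: dt.date | None = None,
) -> PatientSeries:
    """Build a PatientSeries from per-variable value arrays (daily cadence)."""
    n = len(next(iter(values.values())))
    weight = np.asarray(values.get("weight", np.full(n, 60.0)), dtype=float)
    urine = np.asarray(values.get("urine", np.full(n, 800.0)), dtype=float)
    sbp = np.asarray(values.get("sbp", np.full(n, 135.0)), dtype=float)
    dbp = np.asarray(values.get("dbp", np.full(n, 85.0)), dtype=float)
    profile = PatientProfile(
        patient_id=patient_id,
        sex="female",
        age=50.0,
        first_dialysis_date=start - dt.timedelta(days=365),
        pd_duration=1.0,
        hf_hospitalization_date=hf_date,
    )
    records = [
        DailyRecord(
            patient_id=patient_id,
            date=start + dt.timedelta(days=i),
            weight=float(weight[i]),
            urine_volume=float(urine[i]),
            sbp=float(sbp[i]),
            dbp=float(dbp[i]),
        )
        for i in range(n)
    ]
    return PatientSeries(profile=profile, records=records)


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(
        n_patients=150,
        hf_prevalence=0.1,
        follow_up_days=(45, 90),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config) -> Cohort:
    return generate_cohort(small_config)


def rows_with_counts(n_cases: int, n_controls: int, rng=None) -> pd.DataFrame:
    """Minimal analysis-row frame with exact case/control counts."""
    rng = np.random.default_rng(rng)
    n = n_cases + n_controls
    rows = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "sex": rng.choice(["male", "female"], size=n),
            "age": rng.normal(47.0, 5.0, size=n),
            "pd_duration": rng.lognormal(0.0, 0.8, size=n),
        }
    )
    for c in ("weight_cat", "urine_cat", "sbp_cat", "dbp_cat", "pp_cat"):
        rows[c] = rng.choice(["normal", "abnormal"], size=n, p=[0.95, 0.05])
    rows["hf_label"] = np.r_[np.ones(n_cases, int), np.zeros(n_controls, int)]
    return rows
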