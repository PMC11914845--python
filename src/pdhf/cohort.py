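"""Synthetic cohorts of home peritoneal-dialysis (PD) monitoring streams.

Patients on continuous ambulatory peritoneal dialysis upload daily vitals
(weight, 24 h urine volume, systolic/diastolic blood pressure) from home.
A small fraction are hospitalized for capacity-overload heart failure (HF);
the days leading up to hospitalization carry a physiological signal (fluid
retention, blood-pressure drift) that downstream modules try to detect
against each patient's *own* baseline.

This module generates cohorts with that structure: per-patient random
intercepts, a small linear drift, i.i.d. Gaussian day-to-day noise, and —
for HF cases only — a mean shift applied during the progression window
(the ``hf_window_days`` days immediately before hospitalization).  The
within-patient dynamics are deliberately the same linear-trend-plus-noise
form the personalized least-squares detector assumes, so tests can plant
exact violations.

Defaults emulate the published cohort this package models: 6,635 patients,
HF prevalence 0.71%, ~61% female, median age ~46.9 y, median PD duration
~1.0 y, and a 15-day progression window.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

#: Vitals that are monitored directly, in canonical order.
MONITORED_VARIABLES = ("weight", "urine", "sbp", "dbp")
#: Derived vitals (never stored; recomputed from the monitored ones).
DERIVED_VARIABLES = ("pulse_pressure",)
#: Everything the anomaly detector runs on.
ALL_VARIABLES = MONITORED_VARIABLES + DERIVED_VARIABLES

#: z-score of the 75th percentile; converts an IQR to a log-normal sigma.
_Z75 = 0.6744897501960817

#: Column layouts of the two on-disk tables.
RECORD_COLUMNS = ("patient_id", "date", "weight_kg", "urine_ml", "sbp_mmhg", "dbp_mmhg")
PATIENT_COLUMNS = (
    "patient_id",
    "sex",
    "age_years",
    "first_dialysis_date",
    "pd_duration_years",
    "hf_date",
)


class ConfigError(ValueError):
    """A cohort configuration field violates its invariant."""


class CohortParseError(ValueError):
    """A cohort file contains malformed or invariant-violating rows."""


@dataclass(frozen=True)
class VitalLevel:
    """Population parameters of one vital: mean, between-patient SD of the
    personal intercept, and within-patient SD of the daily noise."""

    mean: float
    between_sd: float
    within_sd: float


def _default_levels() -> dict[str, VitalLevel]:
    # Plausible adult CAPD population values (kg, mL/day, mmHg).
    return {
        "weight": VitalLevel(60.0, 10.0, 0.5),
        "urine": VitalLevel(800.0, 350.0, 150.0),
        "sbp": VitalLevel(135.0, 15.0, 8.0),
        "dbp": VitalLevel(85.0, 10.0, 5.0),
    }


def _default_slope_sd() -> dict[str, float]:
    # Units/day: slow personal drift over months of follow-up.
    return {"weight": 0.005, "urine": 0.5, "sbp": 0.02, "dbp": 0.02}


def _default_hf_effect() -> dict[str, float]:
    # Shift in within-patient SD units during the progression window:
    # fluid retention (weight up, urine down) and blood-pressure rise,
    # strongest diastolic — the predictor the published model retained.
    return {"weight": 1.0, "urine": -1.0, "sbp": 1.5, "dbp": 2.0}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    ``hf_effect`` values are expressed in within-patient SD units and are
    applied additively to the variable's mean only on days inside
    ``[hf_date - hf_window_days, hf_date)``.
    """

    n_patients: int = 6635
    hf_prevalence: float = 0.0071
    follow_up_days: tuple[int, int] = (90, 365)
    female_fraction: float = 0.6115
    age_median: float = 46.9
    age_iqr: tuple[float, float] = (44.68, 50.59)
    pd_duration_median: float = 1.0
    pd_duration_iqr: tuple[float, float] = (0.53, 1.64)
    baseline_levels: Mapping[str, VitalLevel] = field(default_factory=_default_levels)
    trend_slope_sd: Mapping[str, float] = field(default_factory=_default_slope_sd)
    hf_effect: Mapping[str, float] = field(default_factory=_default_hf_effect)
    hf_window_days: int = 15
    missing_rate: float = 0.0
    bp_corr_between: float = 0.8  # corr of personal SBP/DBP intercepts
    bp_corr_within: float = 0.5  # corr of daily SBP/DBP noise
    start_date: dt.date = dt.date(2017, 1, 1)
    study_span_days: int = 2300
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        for name in ("hf_prevalence", "female_fraction", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1], got {v}")
        lo, hi = self.follow_up_days
        if lo < 1 or hi < lo:
            raise ConfigError("follow_up_days must satisfy 1 <= min <= max")
        if self.hf_window_days < 1:
            raise ConfigError("hf_window_days must be >= 1")
        if self.age_median <= 0 or self.pd_duration_median <= 0:
            raise ConfigError("age_median and pd_duration_median must be positive")
        for var in MONITORED_VARIABLES:
            if var not in self.baseline_levels:
                raise ConfigError(f"baseline_levels missing variable {var!r}")
            lvl = self.baseline_levels[var]
            if lvl.between_sd < 0 or lvl.within_sd < 0:
                raise ConfigError(f"baseline_levels[{var!r}] SDs must be >= 0")
            if self.trend_slope_sd.get(var, 0.0) < 0:
                raise ConfigError(f"trend_slope_sd[{var!r}] must be >= 0")
        for c in ("bp_corr_between", "bp_corr_within"):
            if not -1.0 <= getattr(self, c) <= 1.0:
                raise ConfigError(f"{c} must be a correlation in [-1, 1]")
        if self.study_span_days < hi:
            raise ConfigError("study_span_days must cover the longest follow-up")


@dataclass(frozen=True)
class PatientProfile:
    patient_id: str
    sex: str  # "male" | "female"
    age: float  # years
    first_dialysis_date: dt.date
    pd_duration: float  # years
    hf_hospitalization_date: dt.date | None = None

    @property
    def has_hf(self) -> bool:
        return self.hf_hospitalization_date is not None


@dataclass(frozen=True)
class DailyRecord:
    patient_id: str
    date: dt.date
    weight: float  # kg
    urine_volume: float  # mL/day
    sbp: float  # mmHg
    dbp: float  # mmHg

    @property
    def pulse_pressure(self) -> float:
        return self.sbp - self.dbp


@dataclass
class PatientSeries:
    """One patient's profile plus their time-ordered daily records."""

    profile: PatientProfile
    records: list[DailyRecord]

    def frame(self) -> pd.DataFrame:
        """Records as a DataFrame with the derived pulse pressure column."""
        df = pd.DataFrame(
            {
                "date": [r.date for r in self.records],
                "weight": [r.weight for r in self.records],
                "urine": [r.urine_volume for r in self.records],
                "sbp": [r.sbp for r in self.records],
                "dbp": [r.dbp for r in self.records],
            }
        )
        df["pulse_pressure"] = df["sbp"] - df["dbp"]
        return df


class Cohort:
    """A generated or loaded cohort, held as two tables.

    ``patients`` has one row per patient (profile fields, ``hf_date`` is
    NaT for non-cases); ``records`` one row per patient-day.  Iterating a
    Cohort yields :class:`PatientSeries` objects on demand so that
    patient-level code never has to materialize millions of record objects.
    """

    def __init__(self, patients: pd.DataFrame, records: pd.DataFrame):
        self.patients = patients.reset_index(drop=True)
        self.records = records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def case_ids(self) -> list[str]:
        m = self.patients["hf_date"].notna()
        return list(self.patients.loc[m, "patient_id"])

    def profile(self, patient_id: str) -> PatientProfile:
        row = self.patients.loc[self.patients["patient_id"] == patient_id]
        if row.empty:
            raise KeyError(patient_id)
        r = row.iloc[0]
        hf = r["hf_date"]
        return PatientProfile(
            patient_id=r["patient_id"],
            sex=r["sex"],
            age=float(r["age_years"]),
            first_dialysis_date=pd.Timestamp(r["first_dialysis_date"]).date(),
            pd_duration=float(r["pd_duration_years"]),
            hf_hospitalization_date=None if pd.isna(hf) else pd.Timestamp(hf).date(),
        )

    def series(self, patient_id: str) -> PatientSeries:
        profile = self.profile(patient_id)
        recs = self.records.loc[self.records["patient_id"] == patient_id]
        recs = recs.sort_values("date")
        records = [
            DailyRecord(
                patient_id=patient_id,
                date=pd.Timestamp(r.date).date(),
                weight=float(r.weight),
                urine_volume=float(r.urine),
                sbp=float(r.sbp),
                dbp=float(r.dbp),
            )
            for r in recs.itertuples()
        ]
        return PatientSeries(profile=profile, records=records)

    def __iter__(self) -> Iterator[PatientSeries]:
        for pid in self.patients["patient_id"]:
            yield self.series(pid)


def _lognormal_from_median_iqr(
    rng: np.random.Generator, n: int, median: float, iqr: tuple[float, float]
) -> np.ndarray:
    """Log-normal draws matched to a printed median and IQR.

    mu = ln(median); sigma chosen so the log-scale IQR matches ln(q3/q1).
    """
    q1, q3 = iqr
    sigma = np.log(q3 / q1) / (2.0 * _Z75)
    return rng.lognormal(mean=np.log(median), sigma=sigma, size=n)


def generate_profiles(config: CohortConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the patient-level table only (cheap; no daily records).

    Separated out so that patient-level calibration checks (HF counts,
    sex/age marginals) can run over many replicates without paying for
    record generation.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_patients
    pid = np.array([f"P{i:06d}" for i in range(n)])
    female = rng.random(n) < config.female_fraction
    age = _lognormal_from_median_iqr(rng, n, config.age_median, config.age_iqr)
    pd_dur = _lognormal_from_median_iqr(
        rng, n, config.pd_duration_median, config.pd_duration_iqr
    )
    lo, hi = config.follow_up_days
    follow_up = rng.integers(lo, hi + 1, size=n)
    start_offset = rng.integers(0, config.study_span_days - follow_up + 1)
    hf = rng.random(n) < config.hf_prevalence
    # Hospitalization lands uniformly in the last third of follow-up so a
    # complete progression window always exists before it.
    hf_lo = np.ceil(2.0 * follow_up / 3.0).astype(int)
    hf_lo = np.clip(np.maximum(hf_lo, config.hf_window_days), 1, follow_up)
    hf_day = rng.integers(hf_lo, follow_up + 1)

    start = np.datetime64(config.start_date) + start_offset.astype("timedelta64[D]")
    first_dialysis = pd.to_datetime(start) - pd.to_timedelta(
        np.round(pd_dur * 365.25), unit="D"
    )
    hf_date = pd.Series(pd.NaT, index=range(n), dtype="datetime64[ns]")
    hf_date[hf] = pd.to_datetime(start[hf]) + pd.to_timedelta(hf_day[hf], unit="D")

    return pd.DataFrame(
        {
            "patient_id": pid,
            "sex": np.where(female, "female", "male"),
            "age_years": age,
            "first_dialysis_date": first_dialysis.normalize(),
            "pd_duration_years": pd_dur,
            "hf_date": hf_date,
            "_start": pd.to_datetime(start),
            "_follow_up": follow_up,
            "_hf_day": np.where(hf, hf_day, -1),
        }
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full cohort of daily monitoring streams.

    Pure function of ``config`` (including its ``seed``).  HF cases stop
    uploading on the hospitalization day, so their last record is the day
    before ``hf_date`` and the progression window is their trailing
    ``hf_window_days`` days.
    """
    rng = np.random.default_rng(config.seed)
    prof = generate_profiles(config, rng)
    n = len(prof)
    if n == 0:
        records = pd.DataFrame(
            {
                "patient_id": pd.Series(dtype=str),
                "date": pd.Series(dtype="datetime64[ns]"),
                "weight": pd.Series(dtype=float),
                "urine": pd.Series(dtype=float),
                "sbp": pd.Series(dtype=float),
                "dbp": pd.Series(dtype=float),
            }
        )
        return Cohort(prof.drop(columns=["_start", "_follow_up", "_hf_day"]), records)

    follow_up = prof["_follow_up"].to_numpy()
    hf_day = prof["_hf_day"].to_numpy()
    # Number of record days: up to hospitalization for cases.
    n_days = np.where(hf_day >= 0, hf_day, follow_up).astype(int)

    total = int(n_days.sum())
    pidx = np.repeat(np.arange(n), n_days)  # patient index per record row
    day = np.arange(total) - np.repeat(np.cumsum(n_days) - n_days, n_days)

    # Personal intercepts; SBP/DBP intercepts are correlated so the pulse
    # pressure stays physiologic (SBP > DBP) essentially everywhere.
    lv = config.baseline_levels
    z_sbp = rng.standard_normal(n)
    z_dbp_i = rng.standard_normal(n)
    rb = config.bp_corr_between
    z_dbp = rb * z_sbp + np.sqrt(1.0 - rb**2) * z_dbp_i
    intercepts = {
        "weight": lv["weight"].mean + lv["weight"].between_sd * rng.standard_normal(n),
        "urine": lv["urine"].mean + lv["urine"].between_sd * rng.standard_normal(n),
        "sbp": lv["sbp"].mean + lv["sbp"].between_sd * z_sbp,
        "dbp": lv["dbp"].mean + lv["dbp"].between_sd * z_dbp,
    }
    slopes = {
        v: config.trend_slope_sd.get(v, 0.0) * rng.standard_normal(n)
        for v in MONITORED_VARIABLES
    }

    e_sbp = rng.standard_normal(total)
    e_dbp_i = rng.standard_normal(total)
    rw = config.bp_corr_within
    noise = {
        "weight": rng.standard_normal(total),
        "urine": rng.standard_normal(total),
        "sbp": e_sbp,
        "dbp": rw * e_sbp + np.sqrt(1.0 - rw**2) * e_dbp_i,
    }

    # Progression-window indicator per record row.
    win_start = hf_day - config.hf_window_days
    in_window = (hf_day[pidx] >= 0) & (day >= win_start[pidx]) & (day < hf_day[pidx])

    values: dict[str, np.ndarray] = {}
    for v in MONITORED_VARIABLES:
        w = lv[v].within_sd
        shift = config.hf_effect.get(v, 0.0) * w
        values[v] = (
            intercepts[v][pidx]
            + slopes[v][pidx] * day
            + w * noise[v]
            + shift * in_window
        )
    values["urine"] = np.maximum(values["urine"], 0.0)  # physical floor
    values["weight"] = np.maximum(values["weight"], 1.0)
    # Final invariant guard (SBP > DBP > 0); correlation makes this rare.
    values["dbp"] = np.clip(values["dbp"], 1.0, values["sbp"] - 1.0)

    dates = prof["_start"].to_numpy()[pidx] + day.astype("timedelta64[D]")
    records = pd.DataFrame(
        {
            "patient_id": prof["patient_id"].to_numpy()[pidx],
            "date": pd.to_datetime(dates),
            "weight": values["weight"],
            "urine": values["urine"],
            "sbp": values["sbp"],
            "dbp": values["dbp"],
        }
    )
    if config.missing_rate > 0.0:
        keep = rng.random(total) >= config.missing_rate
        records = records.loc[keep].reset_index(drop=True)

    patients = prof.drop(columns=["_start", "_follow_up", "_hf_day"])
    return Cohort(patients, records)


# ---------------------------------------------------------------------------
# On-disk format: plain CSV, ISO-8601 dates.
# ---------------------------------------------------------------------------


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write ``patients.csv`` and ``records.csv`` under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pat = cohort.patients.copy()
    pat["first_dialysis_date"] = pd.to_datetime(pat["first_dialysis_date"]).dt.strftime(
        "%Y-%m-%d"
    )
    pat["hf_date"] = pd.to_datetime(pat["hf_date"]).dt.strftime("%Y-%m-%d")
    pat = pat.rename(columns={})[list(PATIENT_COLUMNS)]
    pat.to_csv(path / "patients.csv", index=False)

    rec = cohort.records.copy()
    rec["date"] = pd.to_datetime(rec["date"]).dt.strftime("%Y-%m-%d")
    rec = rec.rename(
        columns={
            "weight": "weight_kg",
            "urine": "urine_ml",
            "sbp": "sbp_mmhg",
            "dbp": "dbp_mmhg",
        }
    )[list(RECORD_COLUMNS)]
    rec.to_csv(path / "records.csv", index=False)


def _check_records(rec: pd.DataFrame) -> list[str]:
    """Row-level invariant diagnostics; row numbers are 1-based data rows."""
    problems: list[str] = []
    rows = rec.index.to_numpy() + 2  # +1 header, +1 zero-based
    bad = rec["weight"].to_numpy() <= 0
    problems += [f"records.csv line {r}: weight must be > 0" for r in rows[bad]]
    bad = rec["urine"].to_numpy() < 0
    problems += [f"records.csv line {r}: urine volume must be >= 0" for r in rows[bad]]
    bad = ~(rec["sbp"].to_numpy() > rec["dbp"].to_numpy())
    problems += [f"records.csv line {r}: requires sbp > dbp" for r in rows[bad]]
    bad = rec["dbp"].to_numpy() <= 0
    problems += [f"records.csv line {r}: dbp must be > 0" for r in rows[bad]]
    dup = rec.duplicated(subset=["patient_id", "date"], keep=False)
    for r in rows[dup.to_numpy()]:
        problems.append(f"records.csv line {r}: duplicate patient-day")
    return problems


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort`, validating invariants.

    Raises :class:`CohortParseError` with line numbers for malformed rows.
    """
    path = Path(path)
    pat = pd.read_csv(path / "patients.csv", dtype={"patient_id": str})
    missing = set(PATIENT_COLUMNS) - set(pat.columns)
    if missing:
        raise CohortParseError(f"patients.csv missing columns: {sorted(missing)}")
    pat["first_dialysis_date"] = pd.to_datetime(pat["first_dialysis_date"])
    pat["hf_date"] = pd.to_datetime(pat["hf_date"])

    rec = pd.read_csv(path / "records.csv", dtype={"patient_id": str})
    missing = set(RECORD_COLUMNS) - set(rec.columns)
    if missing:
        raise CohortParseError(f"records.csv missing columns: {sorted(missing)}")
    try:
        rec["date"] = pd.to_datetime(rec["date"], format="%Y-%m-%d")
    except (ValueError, TypeError) as exc:
        raise CohortParseError(f"records.csv: unparseable date ({exc})") from exc
    rec = rec.rename(
        columns={
            "weight_kg": "weight",
            "urine_ml": "urine",
            "sbp_mmhg": "sbp",
            "dbp_mmhg": "dbp",
        }
    )
    problems = _check_records(rec)
    if problems:
        raise CohortParseError("; ".join(problems[:20]))
    return Cohort(pat, rec)


# ---------------------------------------------------------------------------
# Patient-level row simulator (model-scale experiments)
# ---------------------------------------------------------------------------

#: Log-odds used when planting the published effect magnitudes:
#: female vs male OR 0.06, age OR 1.19 per year, abnormal diastolic
#: pressure OR 38.79; everything else null.
DEFAULT_ROW_COEF: dict[str, float] = {
    "sex": float(np.log(0.06)),
    "age": float(np.log(1.19)),
    "pd_duration": 0.0,
    "weight_cat": 0.0,
    "urine_cat": 0.0,
    "sbp_cat": 0.0,
    "dbp_cat": float(np.log(38.79)),
    "pp_cat": 0.0,
}

#: Marginal abnormal-category rates for the binary predictors (full-cohort
#: scale, strict 99% criterion).
DEFAULT_ABNORMAL_RATES: dict[str, float] = {
    "weight_cat": 0.027,
    "urine_cat": 0.038,
    "sbp_cat": 0.027,
    "dbp_cat": 0.018,
    "pp_cat": 0.024,
}


def simulate_analysis_rows(
    n: int,
    *,
    coef: Mapping[str, float] | None = None,
    intercept: float | None = None,
    target_prevalence: float = 0.0071,
    abnormal_rates: Mapping[str, float] | None = None,
    female_fraction: float = 0.6115,
    age_median: float = 46.9,
    age_iqr: tuple[float, float] = (44.68, 50.59),
    pd_duration_median: float = 1.0,
    pd_duration_iqr: tuple[float, float] = (0.53, 1.64),
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Simulate patient-level analysis rows directly from a logistic model.

    Skips the daily-stream layer: covariates are drawn from the cohort
    marginals and the HF label from a logistic model with the given
    log-odds ``coef``.  If ``intercept`` is None it is calibrated by root
    finding so the mean event probability over the drawn covariates equals
    ``target_prevalence``.  This is the fast path for model-scale
    experiments (parameter recovery, selection stability) where the
    anomaly-detection layer is not under study.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    coef = dict(DEFAULT_ROW_COEF if coef is None else coef)
    rates = dict(DEFAULT_ABNORMAL_RATES if abnormal_rates is None else abnormal_rates)

    female = rng.random(n) < female_fraction
    age = _lognormal_from_median_iqr(rng, n, age_median, age_iqr)
    pd_dur = _lognormal_from_median_iqr(rng, n, pd_duration_median, pd_duration_iqr)
    cats = {c: (rng.random(n) < rates[c]) for c in rates}

    lp = (
        coef.get("sex", 0.0) * female
        + coef.get("age", 0.0) * age
        + coef.get("pd_duration", 0.0) * pd_dur
    )
    for c, flag in cats.items():
        lp = lp + coef.get(c, 0.0) * flag

    if intercept is None:
        lo, hi = -200.0, 200.0
        intercept = brentq(lambda b0: expit(b0 + lp).mean() - target_prevalence, lo, hi)
    p = expit(intercept + lp)
    hf = rng.random(n) < p

    out = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "sex": np.where(female, "female", "male"),
            "age": age,
            "pd_duration": pd_dur,
        }
    )
    for c, flag in cats.items():
        out[c] = np.where(flag, "abnormal", "normal")
    out["hf_label"] = hf.astype(int)
    out.attrs["intercept"] = float(intercept)
    return out
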