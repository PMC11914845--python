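"""Case-control study construction for heart-failure prediction.

Heart failure in home peritoneal dialysis is a progressive event: the 15
days before the hospitalization date are treated as the progression window
and monitoring data inside it as HF-related.  Because HF is rare (<1% of
the cohort), the analysis dataset is built case-control style: every HF
case is kept and R controls per case are drawn uniformly without
replacement (R = 6 in the main analysis, 4 and 10 in sensitivity
analyses), then split 80/20 into training and validation sets.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, PatientProfile

DEFAULT_WINDOW_DAYS = 15

#: Analysis-row columns, in canonical (model candidate) order.
CATEGORY_COLS = ("weight_cat", "urine_cat", "sbp_cat", "dbp_cat", "pp_cat")
ROW_COLUMNS = ("patient_id", "sex", "age", "pd_duration") + CATEGORY_COLS + ("hf_label",)

_VAR_TO_COL = {
    "weight": "weight_cat",
    "urine": "urine_cat",
    "sbp": "sbp_cat",
    "dbp": "dbp_cat",
    "pulse_pressure": "pp_cat",
}


def label_hf_window(
    profile: PatientProfile,
    window_days: int = DEFAULT_WINDOW_DAYS,
    first_record_date: dt.date | None = None,
) -> tuple[dt.date, dt.date] | None:
    """Progression window ``[hf_date - window_days, hf_date)`` or None.

    Half-open: the day exactly ``window_days`` before hospitalization is
    inside, the hospitalization day itself is not.  If the patient's first
    record starts after the nominal window start, the window is truncated
    (with a warning) rather than extended before observation began.
    """
    if profile.hf_hospitalization_date is None:
        return None
    end = profile.hf_hospitalization_date
    start = end - dt.timedelta(days=window_days)
    if first_record_date is not None and first_record_date > start:
        warnings.warn(
            f"patient {profile.patient_id}: progression window truncated at "
            f"first record ({first_record_date} > {start})",
            stacklevel=2,
        )
        start = first_record_date
    return start, end


def assessment_windows(
    cohort: Cohort, window_days: int = DEFAULT_WINDOW_DAYS
) -> pd.DataFrame:
    """Half-open per-patient assessment windows for the whole cohort.

    HF cases get the progression window before hospitalization; controls
    get the trailing ``window_days`` days of their follow-up, so both
    groups are assessed over the same exposure duration.
    """
    g = cohort.records.groupby("patient_id")["date"]
    last = g.max()
    first = g.min()
    pat = cohort.patients.set_index("patient_id")
    hf = pd.to_datetime(pat["hf_date"])
    # Controls: [last - (window_days - 1), last + 1) covers the trailing
    # window_days observed calendar days.
    end = hf.fillna(last.reindex(pat.index) + pd.Timedelta(days=1))
    start = end - pd.Timedelta(days=window_days)
    start = np.maximum(start, pd.to_datetime(first.reindex(pat.index)))
    return pd.DataFrame(
        {"patient_id": pat.index, "start": start.to_numpy(), "end": end.to_numpy()}
    ).reset_index(drop=True)


def build_rows(cohort: Cohort, flags: pd.DataFrame, alpha_criterion: float) -> pd.DataFrame:
    """Assemble one model-ready analysis row per patient.

    ``flags`` is the long-form table from
    :func:`pdhf.baseline.discretize_cohort`; ``alpha_criterion`` selects
    which band level (0.05 or 0.01) supplies the categories.  The HF label
    is 1 iff a hospitalization date is present.  Raises if any patient has
    no flags at the requested alpha.
    """
    sub = flags.loc[np.isclose(flags["alpha"].astype(float), alpha_criterion)]
    if sub.empty:
        raise ValueError(f"no flags at alpha={alpha_criterion}")
    wide = sub.pivot_table(
        index="patient_id", columns="variable", values="category", aggfunc="first"
    )
    missing_vars = set(_VAR_TO_COL) - set(wide.columns)
    if missing_vars:
        raise ValueError(f"flags missing variables: {sorted(missing_vars)}")
    pat = cohort.patients.set_index("patient_id")
    missing = pat.index.difference(wide.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} patients missing flags: {list(missing[:10])}"
        )
    wide = wide.reindex(pat.index)
    rows = pd.DataFrame(
        {
            "patient_id": pat.index,
            "sex": pat["sex"].to_numpy(),
            "age": pat["age_years"].astype(float).to_numpy(),
            "pd_duration": pat["pd_duration_years"].astype(float).to_numpy(),
        }
    )
    for var, col in _VAR_TO_COL.items():
        rows[col] = wide[var].to_numpy()
    rows["hf_label"] = pat["hf_date"].notna().astype(int).to_numpy()
    return rows.reset_index(drop=True)


@dataclass
class StudyDataset:
    """A ratio-controlled case-control dataset, optionally split."""

    rows: pd.DataFrame
    ratio: int
    alpha_criterion: float
    seed: int | None = None
    split_seed: int | None = field(default=None)

    @property
    def n_cases(self) -> int:
        return int((self.rows["hf_label"] == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.rows["hf_label"] == 0).sum())

    def subset(self, which: str) -> pd.DataFrame:
        if "split" not in self.rows.columns:
            raise ValueError("dataset has not been split yet")
        return self.rows.loc[self.rows["split"] == which].reset_index(drop=True)


def sample_case_control(
    rows: pd.DataFrame,
    ratio: int,
    seed: int | np.random.Generator | None = None,
    *,
    alpha_criterion: float = 0.05,
) -> StudyDataset:
    """Keep all cases; draw ``ratio`` controls per case without replacement.

    Controls are drawn uniformly; the draw is deterministic given the
    seed.  Raises with explicit counts if too few controls exist.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cases = rows.loc[rows["hf_label"] == 1]
    controls = rows.loc[rows["hf_label"] == 0]
    n_needed = ratio * len(cases)
    if len(controls) < n_needed:
        raise ValueError(
            f"need {n_needed} controls for {len(cases)} cases at ratio 1:{ratio}, "
            f"only {len(controls)} available"
        )
    pick = rng.choice(len(controls), size=n_needed, replace=False)
    sampled = pd.concat([cases, controls.iloc[np.sort(pick)]], ignore_index=True)
    return StudyDataset(
        rows=sampled,
        ratio=ratio,
        alpha_criterion=alpha_criterion,
        seed=None if isinstance(seed, np.random.Generator) else seed,
    )


def split_train_validation(
    dataset: StudyDataset,
    train_frac: float = 0.8,
    seed: int | np.random.Generator | None = None,
) -> StudyDataset:
    """Fill the train/validation split, stratified by the HF label.

    Within each outcome stratum, ``round(train_frac * n)`` patients go to
    training; the partition is exhaustive, disjoint, and deterministic
    given the seed.  A stratum with fewer than 2 members goes entirely to
    training with a warning.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = dataset.rows.copy()
    split = np.empty(len(rows), dtype=object)
    for label, idx in rows.groupby("hf_label").indices.items():
        n = len(idx)
        if n < 2:
            warnings.warn(
                f"stratum hf_label={label} has {n} member(s); all to training",
                stacklevel=2,
            )
            split[idx] = "train"
            continue
        n_train = int(round(train_frac * n))
        n_train = min(max(n_train, 1), n - 1)  # both sides non-empty
        perm = rng.permutation(n)
        split[idx[perm[:n_train]]] = "train"
        split[idx[perm[n_train:]]] = "validation"
    rows["split"] = split
    return StudyDataset(
        rows=rows,
        ratio=dataset.ratio,
        alpha_criterion=dataset.alpha_criterion,
        seed=dataset.seed,
        split_seed=None if isinstance(seed, np.random.Generator) else seed,
    )
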