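"""End-to-end pipeline: simulate -> flag -> build -> fit -> evaluate.

One :class:`PipelineConfig` drives a fully reproducible run: the cohort
simulator, the anomaly detector at both band levels, the case-control
build at the main ratio, the four-model fit and selection, validation
metrics, and the ratio sensitivity analysis.  All artifacts are plain CSV
or JSON; a manifest records the config hash and every seed.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .baseline import DEFAULT_ALPHAS, DEFAULT_MIN_OBS, discretize_cohort
from .cohort import (
    Cohort,
    CohortConfig,
    VitalLevel,
    read_cohort,
    write_cohort,
)
from .metrics import run_ratio, sensitivity_analysis
from .study import assessment_windows, build_rows

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    alphas: tuple[float, float] = DEFAULT_ALPHAS
    ratio: int = 6
    ratios_sensitivity: tuple[int, ...] = (4, 6, 10)
    train_frac: float = 0.8
    threshold_policy: str | float = "youden"
    min_obs: int = DEFAULT_MIN_OBS
    band: str = "prediction"
    seed_simulate: int = 0
    seed_sample: int = 1
    seed_split: int = 2

    def __post_init__(self):
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must be in (0, 1)")
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = dataclasses.asdict(self.cohort)
        d["cohort"]["start_date"] = self.cohort.start_date.isoformat()
        d["cohort"]["baseline_levels"] = {
            k: dataclasses.asdict(v) if isinstance(v, VitalLevel) else dict(v)
            for k, v in self.cohort.baseline_levels.items()
        }
        d["cohort"]["trend_slope_sd"] = dict(self.cohort.trend_slope_sd)
        d["cohort"]["hf_effect"] = dict(self.cohort.hf_effect)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        c = dict(d.pop("cohort", {}))
        if "start_date" in c and isinstance(c["start_date"], str):
            c["start_date"] = dt.date.fromisoformat(c["start_date"])
        if "baseline_levels" in c:
            c["baseline_levels"] = {
                k: VitalLevel(**v) if isinstance(v, dict) else v
                for k, v in c["baseline_levels"].items()
            }
        for t in ("follow_up_days", "age_iqr", "pd_duration_iqr"):
            if t in c and isinstance(c[t], list):
                c[t] = tuple(c[t])
        for t in ("alphas", "ratios_sensitivity"):
            if t in d and isinstance(d[t], list):
                d[t] = tuple(d[t])
        return cls(cohort=CohortConfig(**c), **d)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def validate_inputs(records_path: str | Path, patients_path: str | Path) -> list[str]:
    """Schema, date-parse, and invariant diagnostics with row numbers.

    Returns a list of human-readable diagnostics; an empty list means the
    files are clean.  Never raises for content problems — the diagnostics
    *are* the output.
    """
    from .cohort import PATIENT_COLUMNS, RECORD_COLUMNS, _check_records

    problems: list[str] = []
    records_path, patients_path = Path(records_path), Path(patients_path)
    for p in (records_path, patients_path):
        if not p.exists():
            problems.append(f"missing file: {p}")
    if problems:
        return problems

    pat = pd.read_csv(patients_path, dtype=str)
    missing = set(PATIENT_COLUMNS) - set(pat.columns)
    if missing:
        problems.append(f"{patients_path.name}: missing columns {sorted(missing)}")
    rec = pd.read_csv(records_path, dtype={"patient_id": str})
    missing = set(RECORD_COLUMNS) - set(rec.columns)
    if missing:
        problems.append(f"{records_path.name}: missing columns {sorted(missing)}")
        return problems

    dates = pd.to_datetime(rec["date"], format="%Y-%m-%d", errors="coerce")
    for i in np.flatnonzero(dates.isna().to_numpy()):
        problems.append(
            f"{records_path.name} line {i + 2}: column 'date' is not ISO-8601 "
            f"({rec['date'].iloc[i]!r})"
        )
    rec = rec.assign(date=dates).rename(
        columns={
            "weight_kg": "weight",
            "urine_ml": "urine",
            "sbp_mmhg": "sbp",
            "dbp_mmhg": "dbp",
        }
    )
    for c in ("weight", "urine", "sbp", "dbp"):
        rec[c] = pd.to_numeric(rec[c], errors="coerce")
    problems.extend(_check_records(rec.dropna(subset=["date"])))
    return problems


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline and write all artifacts under ``out_dir``.

    Identical configs produce identical artifacts.  On a stage failure a
    ``FAILED`` marker naming the stage is written and the exception
    re-raised; artifacts from completed stages are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "init"
    try:
        manifest = {
            "package": "pdhf",
            "version": __version__,
            "config": config.to_dict(),
            "config_sha256": config_hash(config),
        }
        _write_json(out / "manifest.json", manifest)

        stage = "simulate"
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed_simulate)
        cohort = generate_or_load(cohort_cfg, out)

        stage = "flag"
        windows = assessment_windows(cohort, cohort_cfg.hf_window_days)
        flags = discretize_cohort(
            cohort,
            windows,
            config.alphas,
            min_obs=config.min_obs,
            band=config.band,
        )
        flags.to_csv(out / "flags.csv", index=False)

        stage = "build"
        rows95 = build_rows(cohort, flags, config.alphas[0])
        rows99 = build_rows(cohort, flags, config.alphas[1])
        rows95.to_csv(out / "rows_alpha05.csv", index=False)
        rows99.to_csv(out / "rows_alpha01.csv", index=False)

        stage = "fit"
        main = run_ratio(
            rows95,
            rows99,
            config.ratio,
            sample_seed=config.seed_sample,
            split_seed=config.seed_split,
            train_frac=config.train_frac,
            threshold_policy=config.threshold_policy,
        )
        main["dataset"].rows.to_csv(out / "dataset.csv", index=False)
        _write_json(
            out / "models.json",
            {
                str(k): m.to_dict() for k, m in main["models"].items()
            }
            | {"selection": main["selection_log"]},
        )

        stage = "evaluate"
        report = main["report"]
        _write_json(out / "report.json", report.to_dict())
        report.roc.to_csv(out / "roc.csv", index=False)
        report.decision_curve.to_csv(out / "dca.csv", index=False)

        stage = "sensitivity"
        extra = [r for r in config.ratios_sensitivity if r != config.ratio]
        sens = sensitivity_analysis(
            rows95,
            rows99,
            extra,
            sample_seed=config.seed_sample,
            split_seed=config.seed_split,
            train_frac=config.train_frac,
            threshold_policy=config.threshold_policy,
        )
        sens[config.ratio] = main
        sens_out = {}
        for r, res in sorted(sens.items()):
            if "error" in res:
                sens_out[str(r)] = {"error": res["error"]}
            else:
                sens_out[str(r)] = {
                    "optimal_model": res["optimal"].to_dict(),
                    "report": res["report"].to_dict(),
                }
        _write_json(out / "sensitivity.json", sens_out)
        return {"main": main, "sensitivity": sens, "cohort": cohort, "out": out}
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise


def generate_or_load(cohort_cfg: CohortConfig, out: Path) -> Cohort:
    """Generate the cohort and persist it as CSV (round-trip checked once)."""
    from .cohort import generate_cohort

    cohort = generate_cohort(cohort_cfg)
    write_cohort(cohort, out)
    return cohort
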