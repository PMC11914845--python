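"""Classifier evaluation: confusion metrics, ROC/AUC, decision curves.

The four confusion-matrix summaries are

    sensitivity = TP / (TP + FN)
    specificity = TN / (FP + TN)
    accuracy    = (TP + TN) / (TP + FP + FN + TN)
    Youden      = sensitivity + specificity - 1

AUC uses the rank (Mann-Whitney) formulation with tie correction; its 95%
CI and the paired comparison of two models on the same patients use the
DeLong asymptotic covariance for correlated ROC curves.  Decision-curve
analysis reports the net benefit TP/n - (FP/n) * pt/(1-pt) across
threshold probabilities pt against treat-all and treat-none references.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .models import FittedModel, fit_model_quartet, select_optimal
from .study import sample_case_control, split_train_validation


class UndefinedMetricError(ValueError):
    """A metric's denominator class is empty."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class Metrics:
    sensitivity: float
    specificity: float
    accuracy: float
    youden: float


def confusion_counts(
    labels: np.ndarray, scores: np.ndarray, threshold: float
) -> ConfusionCounts:
    """Counts at ``predicted positive iff score >= threshold``."""
    labels = np.asarray(labels).astype(int)
    pred = np.asarray(scores) >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (labels == 1))),
        fp=int(np.sum(pred & (labels == 0))),
        fn=int(np.sum(~pred & (labels == 1))),
        tn=int(np.sum(~pred & (labels == 0))),
    )


def confusion_metrics(counts: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity, accuracy and Youden index from counts."""
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("no positives: sensitivity undefined")
    if counts.fp + counts.tn == 0:
        raise UndefinedMetricError("no negatives: specificity undefined")
    sens = counts.tp / (counts.tp + counts.fn)
    spec = counts.tn / (counts.fp + counts.tn)
    acc = (counts.tp + counts.tn) / counts.n
    return Metrics(
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        youden=sens + spec - 1.0,
    )


# ---------------------------------------------------------------------------
# AUC: Mann-Whitney point estimate + DeLong variance
# ---------------------------------------------------------------------------


def _check_two_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return labels == 1, labels == 0


def mann_whitney_auc(scores, labels) -> float:
    """AUC as the tie-corrected Mann-Whitney probability."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_classes(labels)
    ranks = stats.rankdata(scores)  # midranks handle ties
    n1, n0 = pos.sum(), neg.sum()
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _delong_components(scores: np.ndarray, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the V10 (cases) and V01 (controls) structural components."""
    pos, neg = _check_two_classes(labels)
    x = np.asarray(scores, dtype=float)[pos]
    y = np.asarray(scores, dtype=float)[neg]
    m, n = len(x), len(y)
    # psi(x_i, y_j) = 1 if x>y, 0.5 if tie, 0 otherwise, via midranks
    all_r = stats.rankdata(np.concatenate([x, y]))
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - rx) / n  # mean_j psi(x_i, y_j)
    v01 = 1.0 - (all_r[m:] - ry) / m  # mean_i psi(x_i, y_j)
    return float(auc), v10, v01


def delong_variance(scores, labels) -> tuple[float, float]:
    """(AUC, asymptotic variance) for one model."""
    auc, v10, v01 = _delong_components(scores, labels)
    m, n = len(v10), len(v01)
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    return auc, float(var)


@dataclass
class AucResult:
    auc: float
    ci_lower: float
    ci_upper: float
    variance: float


def roc_auc(scores, labels, alpha: float = 0.05) -> AucResult:
    """AUC with a DeLong (asymptotic) two-sided 1-alpha CI."""
    auc, var = delong_variance(scores, labels)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(var)
    return AucResult(
        auc=auc,
        ci_lower=max(0.0, auc - half),
        ci_upper=min(1.0, auc + half),
        variance=var,
    )


@dataclass
class PairedAucTest:
    auc1: float
    auc2: float
    z: float
    p_value: float


def delong_paired_test(scores1, scores2, labels) -> PairedAucTest:
    """DeLong test for two correlated AUCs on the same observations."""
    auc1, v10_1, v01_1 = _delong_components(scores1, labels)
    auc2, v10_2, v01_2 = _delong_components(scores2, labels)
    m, n = len(v10_1), len(v01_1)
    s10 = np.cov(v10_1, v10_2, ddof=1)
    s01 = np.cov(v01_1, v01_2, ddof=1)
    var_diff = (
        s10[0, 0] / m + s10[1, 1] / m - 2 * s10[0, 1] / m
        + s01[0, 0] / n + s01[1, 1] / n - 2 * s01[0, 1] / n
    )
    if var_diff <= 0:
        z = 0.0 if np.isclose(auc1, auc2) else np.inf * np.sign(auc1 - auc2)
    else:
        z = (auc1 - auc2) / np.sqrt(var_diff)
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return PairedAucTest(auc1=auc1, auc2=auc2, z=float(z), p_value=p)


def roc_points(scores, labels) -> pd.DataFrame:
    """(fpr, tpr, threshold) points of the empirical ROC curve."""
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def youden_threshold(scores, labels) -> float:
    """Score threshold maximizing sensitivity + specificity - 1.

    Ties are broken toward the highest threshold (fewest positives).
    """
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    j = tpr - fpr
    best = int(np.argmax(j))  # first occurrence = highest threshold
    t = thr[best]
    return float(min(t, 1.0))  # sklearn's top sentinel is max(score)+1


# ---------------------------------------------------------------------------
# Decision-curve analysis
# ---------------------------------------------------------------------------


def decision_curve(
    scores, labels, thresholds: np.ndarray | None = None
) -> pd.DataFrame:
    """Net benefit of the model vs treat-all / treat-none references.

    ``net_benefit_model(pt) = TP/n - (FP/n) * pt / (1 - pt)`` where the
    model treats everyone with score >= pt.  Thresholds outside (0, 1)
    are excluded with a warning.
    """
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    bad = (thresholds <= 0.0) | (thresholds >= 1.0)
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} threshold(s) outside (0, 1)", stacklevel=2
        )
        thresholds = thresholds[~bad]
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    n = len(labels)
    prevalence = labels.mean()
    rows = []
    for pt in thresholds:
        pred = scores >= pt
        tp = np.sum(pred & (labels == 1)) / n
        fp = np.sum(pred & (labels == 0)) / n
        w = pt / (1.0 - pt)
        rows.append(
            {
                "threshold": pt,
                "net_benefit_model": tp - fp * w,
                "net_benefit_all": prevalence - (1.0 - prevalence) * w,
                "net_benefit_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model-level evaluation
# ---------------------------------------------------------------------------


@dataclass
class MetricReport:
    """Full validation report for one model at one threshold."""

    threshold: float
    threshold_policy: str
    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    accuracy: float
    youden: float
    auc: float
    auc_ci: tuple[float, float]
    roc: pd.DataFrame = field(repr=False)
    decision_curve: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "threshold": float(self.threshold),
            "threshold_policy": self.threshold_policy,
            "counts": {
                "tp": self.counts.tp,
                "fp": self.counts.fp,
                "fn": self.counts.fn,
                "tn": self.counts.tn,
            },
            "sensitivity": float(self.sensitivity),
            "specificity": float(self.specificity),
            "accuracy": float(self.accuracy),
            "youden": float(self.youden),
            "auc": float(self.auc),
            "auc_ci": [float(self.auc_ci[0]), float(self.auc_ci[1])],
        }


def evaluate_model(
    model: FittedModel,
    rows: pd.DataFrame,
    threshold_policy: str | float = "youden",
) -> MetricReport:
    """Score ``rows`` with ``model`` and emit the full metric report.

    ``threshold_policy``: ``"youden"`` derives the Youden-optimal cutoff
    from the model's *training* ROC (standard practice when a Youden index
    is reported); a float is used as-is; ``"half"`` uses 0.5.
    """
    if rows.empty:
        raise ValueError("validation rows are empty")
    labels = rows["hf_label"].to_numpy(dtype=int)
    if labels.min() == labels.max():
        raise ValueError("validation rows must contain both classes")
    scores = model.predict(rows)
    if threshold_policy == "youden":
        if model.training_scores is None:
            raise ValueError("model carries no training scores for Youden policy")
        thr = youden_threshold(model.training_scores, model.training_labels)
        policy = "youden"
    elif threshold_policy == "half":
        thr, policy = 0.5, "half"
    else:
        thr, policy = float(threshold_policy), "fixed"
    counts = confusion_counts(labels, scores, thr)
    m = confusion_metrics(counts)
    auc = roc_auc(scores, labels)
    return MetricReport(
        threshold=thr,
        threshold_policy=policy,
        counts=counts,
        sensitivity=m.sensitivity,
        specificity=m.specificity,
        accuracy=m.accuracy,
        youden=m.youden,
        auc=auc.auc,
        auc_ci=(auc.ci_lower, auc.ci_upper),
        roc=roc_points(scores, labels),
        decision_curve=decision_curve(scores, labels),
    )


# ---------------------------------------------------------------------------
# Ratio sensitivity analysis
# ---------------------------------------------------------------------------


def run_ratio(
    rows95: pd.DataFrame,
    rows99: pd.DataFrame,
    ratio: int,
    *,
    sample_seed: int | None = None,
    split_seed: int | None = None,
    train_frac: float = 0.8,
    threshold_policy: str | float = "youden",
) -> dict:
    """One full build -> fit -> select -> evaluate pass at a given ratio.

    The control sample and the train/validation split are drawn once on
    the 95%-criterion rows and shared with the 99% build, so the four
    candidate models see the same patients.
    """
    ds95 = sample_case_control(rows95, ratio, sample_seed, alpha_criterion=0.05)
    ds95 = split_train_validation(ds95, train_frac, split_seed)
    picked = ds95.rows[["patient_id", "split"]]
    rows99_ds = rows99.merge(picked, on="patient_id", how="inner")
    train95 = ds95.subset("train")
    val95 = ds95.subset("validation")
    train99 = rows99_ds.loc[rows99_ds["split"] == "train"].reset_index(drop=True)
    val99 = rows99_ds.loc[rows99_ds["split"] == "validation"].reset_index(drop=True)

    models = fit_model_quartet(train95, train99)
    optimal, selection_log = select_optimal(models)
    val = val95 if optimal.spec and optimal.spec.alpha_criterion == 0.05 else val99
    report = evaluate_model(optimal, val, threshold_policy)
    return {
        "ratio": ratio,
        "models": models,
        "optimal": optimal,
        "selection_log": selection_log,
        "report": report,
        "dataset": ds95,
    }


def sensitivity_analysis(
    rows95: pd.DataFrame,
    rows99: pd.DataFrame,
    ratios=(4, 6, 10),
    *,
    sample_seed: int | None = None,
    split_seed: int | None = None,
    train_frac: float = 0.8,
    threshold_policy: str | float = "youden",
) -> dict[int, dict]:
    """Re-run the whole modeling pipeline at each case:control ratio.

    Per-ratio failures (e.g. not enough controls) are reported in-place
    under an ``"error"`` key; other ratios still run.
    """
    out: dict[int, dict] = {}
    for r in ratios:
        try:
            out[r] = run_ratio(
                rows95,
                rows99,
                r,
                sample_seed=sample_seed,
                split_seed=split_seed,
                train_frac=train_frac,
                threshold_policy=threshold_policy,
            )
        except ValueError as exc:
            out[r] = {"ratio": r, "error": str(exc)}
    return out
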