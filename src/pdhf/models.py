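"""Logistic heart-failure prediction models and model selection.

Four candidate models are fit on the training split: models 1 and 2 use
categories from the 95% band criterion, models 3 and 4 from the 99%
criterion; models 1 and 3 enter all candidate variables, models 2 and 4
apply backward elimination keeping only Wald-significant terms.  The
optimal model has the lowest AIC; if it is not also the highest-AUC model
the two are compared with the paired DeLong test and the lowest-AIC model
is kept when the AUC difference is non-significant.

Coding conventions: sex reference = male (female indicator), category
reference = normal (abnormal indicator); age and PD duration enter
untransformed, so odds ratios are per year.  Near-separation (plausible
with tens of cases and rare abnormal categories) is detected from
non-convergence or exploding Wald SEs and handled by refitting with a
small ridge penalty, with the fit flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import expit

from .study import StudyDataset

#: Candidate predictors in canonical order (also the tie-break order).
CANDIDATE_VARIABLES = (
    "sex",
    "age",
    "pd_duration",
    "weight_cat",
    "urine_cat",
    "sbp_cat",
    "dbp_cat",
    "pp_cat",
)

_Z95 = float(stats.norm.ppf(0.975))

#: Thresholds beyond which a Wald fit is treated as (near-)separated.
_SE_BLOWUP = 500.0
_COEF_BLOWUP = 25.0
_RIDGE_PENALTY = 0.5


@dataclass(frozen=True)
class ModelSpec:
    """Identity of one of the four candidate models."""

    id: int
    alpha_criterion: float
    selection: str  # "all_variables" | "backward"

    def __post_init__(self):
        expected = {
            1: (0.05, "all_variables"),
            2: (0.05, "backward"),
            3: (0.01, "all_variables"),
            4: (0.01, "backward"),
        }
        if self.id in expected and expected[self.id] != (
            self.alpha_criterion,
            self.selection,
        ):
            raise ValueError(
                f"model {self.id} must be {expected[self.id]}, got "
                f"({self.alpha_criterion}, {self.selection})"
            )


def design_matrix(rows: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    """Numeric design matrix (no constant): female=1, abnormal=1."""
    cols = {}
    for v in variables:
        if v == "sex":
            cols[v] = (rows["sex"] == "female").astype(float).to_numpy()
        elif v.endswith("_cat"):
            cols[v] = (rows[v] == "abnormal").astype(float).to_numpy()
        else:
            cols[v] = rows[v].astype(float).to_numpy()
    return pd.DataFrame(cols, index=rows.index)


@dataclass
class FittedModel:
    """A fitted logistic model with Wald inference and training metadata."""

    spec: ModelSpec | None
    variables: tuple[str, ...]  # retained variables, candidate order
    params: pd.Series  # includes "const"
    bse: pd.Series
    pvalues: pd.Series
    log_likelihood: float
    aic: float
    n_obs: int
    separation: bool = False
    dropped_constant: tuple[str, ...] = ()
    training_scores: np.ndarray | None = None
    training_labels: np.ndarray | None = None
    training_ids: np.ndarray | None = None
    training_auc: float | None = None

    @property
    def k_params(self) -> int:
        return len(self.params)

    def aor_table(self) -> pd.DataFrame:
        """Adjusted odds ratios with Wald 95% CIs for retained variables."""
        idx = [v for v in self.params.index if v != "const"]
        coef = self.params[idx]
        se = self.bse[idx]
        return pd.DataFrame(
            {
                "aor": np.exp(coef),
                "ci_lower": np.exp(coef - _Z95 * se),
                "ci_upper": np.exp(coef + _Z95 * se),
                "p_value": self.pvalues[idx],
            },
            index=idx,
        )

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        """Predicted HF probabilities for analysis rows."""
        X = design_matrix(rows, self.variables)
        lp = self.params["const"] + X.to_numpy() @ self.params[
            list(self.variables)
        ].to_numpy()
        return expit(lp)

    def to_dict(self) -> dict:
        return {
            "model_id": None if self.spec is None else self.spec.id,
            "alpha_criterion": None if self.spec is None else self.spec.alpha_criterion,
            "selection": None if self.spec is None else self.spec.selection,
            "variables": list(self.variables),
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "standard_errors": {k: float(v) for k, v in self.bse.items()},
            "p_values": {k: float(v) for k, v in self.pvalues.items()},
            "aor": {
                k: {
                    "aor": float(r["aor"]),
                    "ci_lower": float(r["ci_lower"]),
                    "ci_upper": float(r["ci_upper"]),
                }
                for k, r in self.aor_table().iterrows()
            },
            "log_likelihood": float(self.log_likelihood),
            "aic": float(self.aic),
            "n_obs": int(self.n_obs),
            "separation": bool(self.separation),
            "dropped_constant": list(self.dropped_constant),
            "training_auc": None
            if self.training_auc is None
            else float(self.training_auc),
        }


def _bernoulli_llf(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1.0 - eps)
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _ridge_logistic(X: np.ndarray, y: np.ndarray, penalty: float):
    """L2-penalized logistic fit (intercept unpenalized); returns
    (params, cov) where cov is the inverse penalized Hessian."""
    n, k = X.shape
    pen = np.full(k, penalty)
    pen[0] = 0.0  # intercept column

    def nll(beta):
        lp = X @ beta
        # log(1 + exp(lp)) - y*lp, numerically stable
        return float(
            np.sum(np.logaddexp(0.0, lp) - y * lp) + 0.5 * np.sum(pen * beta**2)
        )

    def grad(beta):
        p = expit(X @ beta)
        return X.T @ (p - y) + pen * beta

    res = optimize.minimize(nll, np.zeros(k), jac=grad, method="BFGS")
    beta = res.x
    p = expit(X @ beta)
    W = p * (1.0 - p)
    H = (X * W[:, None]).T @ X + np.diag(pen)
    cov = np.linalg.inv(H)
    return beta, cov


def fit_logistic(
    rows: pd.DataFrame,
    variables: Sequence[str] = CANDIDATE_VARIABLES,
    *,
    spec: ModelSpec | None = None,
    ridge_fallback: bool = True,
) -> FittedModel:
    """Maximum-likelihood logistic fit of the HF label on ``variables``.

    Constant-valued predictors are dropped with a warning.  Requires at
    least one case and one control.  On (near-)separation the fit falls
    back to a small ridge penalty and is marked ``separation=True``; the
    reported log-likelihood and AIC are the unpenalized values at the
    penalized estimate.
    """
    y = rows["hf_label"].to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one case and one control to fit")
    variables = [v for v in CANDIDATE_VARIABLES if v in variables] + [
        v for v in variables if v not in CANDIDATE_VARIABLES
    ]
    X = design_matrix(rows, variables)
    dropped = tuple(c for c in X.columns if X[c].nunique() <= 1)
    if dropped:
        warnings.warn(f"dropping constant predictor(s): {list(dropped)}", stacklevel=2)
        variables = [v for v in variables if v not in dropped]
        X = X.drop(columns=list(dropped))
    Xc = sm.add_constant(X, has_constant="add")

    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        params = res.params
        bse = res.bse
        converged = bool(res.mle_retvals.get("converged", True))
        blown = (
            not converged
            or not np.all(np.isfinite(bse))
            or float(np.max(np.abs(bse))) > _SE_BLOWUP
            or float(np.max(np.abs(params))) > _COEF_BLOWUP
        )
    except Exception:  # PerfectSeparation / singular Hessian
        blown = True
        params = bse = None

    if blown:
        separation = True
        if not ridge_fallback:
            raise RuntimeError("logistic fit did not converge (separation?)")
        beta, cov = _ridge_logistic(Xc.to_numpy(), y, _RIDGE_PENALTY)
        params = pd.Series(beta, index=Xc.columns)
        bse = pd.Series(np.sqrt(np.diag(cov)), index=Xc.columns)
        llf = _bernoulli_llf(y, expit(Xc.to_numpy() @ beta))
    else:
        llf = float(res.llf)

    zstat = params / bse
    pvalues = pd.Series(2.0 * stats.norm.sf(np.abs(zstat)), index=params.index)
    k = len(params)
    aic = 2.0 * k - 2.0 * llf

    # Reorder with const first for readability.
    order = ["const"] + [c for c in params.index if c != "const"]
    params, bse, pvalues = params[order], bse[order], pvalues[order]

    scores = expit(Xc.to_numpy() @ params[Xc.columns].to_numpy())
    from .metrics import mann_whitney_auc  # local import avoids a cycle

    model = FittedModel(
        spec=spec,
        variables=tuple(variables),
        params=params,
        bse=bse,
        pvalues=pvalues,
        log_likelihood=llf,
        aic=aic,
        n_obs=len(y),
        separation=separation,
        dropped_constant=dropped,
        training_scores=scores,
        training_labels=y.astype(int),
        training_ids=rows["patient_id"].to_numpy()
        if "patient_id" in rows.columns
        else None,
        training_auc=mann_whitney_auc(scores, y),
    )
    return model


def backward_select(
    rows: pd.DataFrame,
    variables: Sequence[str] = CANDIDATE_VARIABLES,
    alpha_stay: float = 0.05,
    *,
    spec: ModelSpec | None = None,
) -> FittedModel:
    """Backward elimination on Wald p-values.

    Repeatedly refits, removing the variable with the largest p-value
    >= ``alpha_stay`` until every retained variable is significant.  Exact
    p-value ties are broken by candidate order (the earlier-listed variable
    among the tied maxima is removed first).  If everything is eliminated,
    the intercept-only model is returned with a warning.
    """
    current = [v for v in CANDIDATE_VARIABLES if v in variables] + [
        v for v in variables if v not in CANDIDATE_VARIABLES
    ]
    while current:
        model = fit_logistic(rows, current, spec=spec)
        current = list(model.variables)  # constants may have been dropped
        pvals = model.pvalues.drop("const")
        worst = pvals[current].to_numpy().argmax()
        if pvals[current].iloc[worst] < alpha_stay:
            return model
        del current[worst]
    warnings.warn("backward elimination removed every variable", stacklevel=2)
    # Intercept-only fit.
    y = rows["hf_label"].to_numpy(dtype=float)
    p = y.mean()
    llf = _bernoulli_llf(y, np.full_like(y, p))
    const = float(np.log(p / (1.0 - p)))
    se = float(1.0 / np.sqrt(len(y) * p * (1.0 - p)))
    from .metrics import mann_whitney_auc

    scores = np.full_like(y, p)
    return FittedModel(
        spec=spec,
        variables=(),
        params=pd.Series({"const": const}),
        bse=pd.Series({"const": se}),
        pvalues=pd.Series({"const": 2.0 * stats.norm.sf(abs(const / se))}),
        log_likelihood=llf,
        aic=2.0 - 2.0 * llf,
        n_obs=len(y),
        training_scores=scores,
        training_labels=y.astype(int),
        training_ids=rows["patient_id"].to_numpy()
        if "patient_id" in rows.columns
        else None,
        training_auc=0.5,
    )


def fit_model_quartet(
    train95: pd.DataFrame,
    train99: pd.DataFrame,
    variables: Sequence[str] = CANDIDATE_VARIABLES,
    alpha_stay: float = 0.05,
) -> dict[int, FittedModel]:
    """Fit the four candidate models on the two training builds."""
    return {
        1: fit_logistic(train95, variables, spec=ModelSpec(1, 0.05, "all_variables")),
        2: backward_select(
            train95, variables, alpha_stay, spec=ModelSpec(2, 0.05, "backward")
        ),
        3: fit_logistic(train99, variables, spec=ModelSpec(3, 0.01, "all_variables")),
        4: backward_select(
            train99, variables, alpha_stay, spec=ModelSpec(4, 0.01, "backward")
        ),
    }


def select_optimal(
    models: Sequence[FittedModel] | dict[int, FittedModel],
    alpha: float = 0.05,
) -> tuple[FittedModel, dict]:
    """Pick the optimal model by lowest AIC, arbitrating with AUC.

    If the lowest-AIC model is not also the highest-training-AUC model,
    the two are compared with the paired DeLong test on the training
    scores (models share the same sampled patients); the lowest-AIC model
    is kept when the difference is non-significant, otherwise the
    higher-AUC model wins.  Returns (model, comparison-log dict).
    """
    if isinstance(models, dict):
        models = [models[k] for k in sorted(models)]
    if not models:
        raise ValueError("no models to select from")
    by_aic = min(models, key=lambda m: m.aic)
    by_auc = max(models, key=lambda m: m.training_auc or 0.0)
    log: dict = {
        "aic": {str(m.spec.id if m.spec else i): m.aic for i, m in enumerate(models)},
        "training_auc": {
            str(m.spec.id if m.spec else i): m.training_auc
            for i, m in enumerate(models)
        },
    }
    if by_aic is by_auc or len(models) == 1:
        log["decision"] = "lowest AIC is also highest AUC"
        return by_aic, log

    from .metrics import delong_paired_test

    s1, l1, i1 = by_aic.training_scores, by_aic.training_labels, by_aic.training_ids
    s2, i2 = by_auc.training_scores, by_auc.training_ids
    if i1 is not None and i2 is not None:
        # Align score vectors on shared patients for a paired comparison.
        order = {pid: j for j, pid in enumerate(i2)}
        keep = [pid in order for pid in i1]
        s1 = s1[np.array(keep)]
        l1 = l1[np.array(keep)]
        s2 = s2[[order[pid] for pid in i1[np.array(keep)]]]
    result = delong_paired_test(s1, s2, l1)
    log["paired_auc_test"] = {
        "auc_lowest_aic": result.auc1,
        "auc_highest_auc": result.auc2,
        "p_value": result.p_value,
    }
    if result.p_value < alpha:
        log["decision"] = "AUC difference significant; highest-AUC model chosen"
        return by_auc, log
    log["decision"] = "AUC difference non-significant; lowest-AIC model kept"
    return by_aic, log
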