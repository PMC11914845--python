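"""Personal least-squares bands and discrete-point flagging."""

import datetime as dt

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from pdhf.baseline import (
    EmptyWindowError,
    InsufficientDataError,
    discretize_cohort,
    discretize_patient,
    fit_baseline,
    flag_discrete_points,
    null_flag_rate,
)
from pdhf.cohort import ALL_VARIABLES, generate_cohort, CohortConfig
from pdhf.study import assessment_windows

from conftest import make_series

START = dt.date(2020, 1, 1)


def sm_prediction_band(t, y, alpha):
    """Independent oracle: statsmodels OLS prediction interval."""
    X = sm.add_constant(t)
    res = sm.OLS(y, X).fit()
    pred = res.get_prediction(X)
    frame = pred.summary_frame(alpha=alpha)
    return frame["obs_ci_lower"].to_numpy(), frame["obs_ci_upper"].to_numpy()


def test_noiseless_line_recovered_exactly():
    t = np.arange(30, dtype=float)
    series = make_series({"sbp": 120.0 + 0.5 * t, "dbp": 80.0 + 0.1 * t})
    fit = fit_baseline(series, "sbp", 0.05)
    assert fit.residual_sd == pytest.approx(0.0, abs=1e-9)
    assert fit.slope == pytest.approx(0.5, abs=1e-9)
    assert fit.intercept == pytest.approx(120.0, abs=1e-8)
    np.testing.assert_allclose(fit.lower, fit.fitted, atol=1e-7)
    np.testing.assert_allclose(fit.upper, fit.fitted, atol=1e-7)
    assert flag_discrete_points(fit) == []


def test_single_spike_outside_both_bands():
    """30 points at 100 plus one at 200: flagged at 95% and 99%."""
    y = np.full(31, 100.0) + np.random.default_rng(0).normal(0, 0.5, 31)
    y[15] = 200.0
    series = make_series({"dbp": y, "sbp": y + 50.0})
    for alpha in (0.05, 0.01):
        fit = fit_baseline(series, "dbp", alpha)
        flagged = flag_discrete_points(fit)
        assert START + dt.timedelta(days=15) in flagged
        # agreement with the closed-form oracle
        lo, hi = sm_prediction_band(fit.t, fit.values, alpha)
        oracle = [
            START + dt.timedelta(days=int(d))
            for d in fit.t[(fit.values < lo) | (fit.values > hi)]
        ]
        assert flagged == oracle


@pytest.mark.parametrize("alpha", [0.05, 0.01])
@pytest.mark.parametrize("n", [12, 40, 75])
def test_band_matches_statsmodels_oracle(alpha, n):
    rng = np.random.default_rng(n)
    yr = 50.0 + 0.3 * np.arange(n) + rng.normal(0, 3.0, n)
    series = make_series({"sbp": yr})
    fit = fit_baseline(series, "sbp", alpha)
    lo, hi = sm_prediction_band(fit.t, fit.values, alpha)
    np.testing.assert_allclose(fit.lower, lo, rtol=1e-9, atol=1e-9)
    np.testing.assert_allclose(fit.upper, hi, rtol=1e-9, atol=1e-9)


def test_alpha_nesting_pointwise():
    rng = np.random.default_rng(3)
    series = make_series({"urine": 800 + rng.normal(0, 100, 60)})
    f05 = fit_baseline(series, "urine", 0.05)
    f01 = fit_baseline(series, "urine", 0.01)
    assert (f01.lower <= f05.lower + 1e-12).all()
    assert (f01.upper >= f05.upper - 1e-12).all()
    assert set(flag_discrete_points(f01)) <= set(flag_discrete_points(f05))


@given(shift=st.floats(-500.0, 500.0, allow_nan=False))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_constant_shift_changes_no_flags(shift):
    rng = np.random.default_rng(9)
    base = 100 + rng.normal(0, 5, 40)
    base[7] += 30  # one genuine excursion
    a = make_series({"weight": base})
    b = make_series({"weight": base + shift})
    fa = flag_discrete_points(fit_baseline(a, "weight", 0.05))
    fb = flag_discrete_points(fit_baseline(b, "weight", 0.05))
    assert fa == fb


def test_insufficient_data_raises():
    series = make_series({"sbp": np.full(5, 120.0)})
    with pytest.raises(InsufficientDataError, match="5 observations"):
        fit_baseline(series, "sbp", 0.05)


def test_discretize_patient_single_variable_perturbation():
    """A DBP spike inside the window flags only dbp (and nothing at 99%
    outside); a spike just before the window start leaves dbp normal."""
    n = 60
    rng = np.random.default_rng(1)
    dbp = 85 + rng.normal(0, 2, n)
    sbp = dbp + 50 + rng.normal(0, 2, n)  # keeps pulse pressure quiet
    window = (START + dt.timedelta(days=45), START + dt.timedelta(days=n))

    spiked = dbp.copy()
    spiked[50] += 25
    series = make_series({"dbp": spiked, "sbp": sbp + np.r_[np.zeros(50), [25.0], np.zeros(9)]})
    flags = discretize_patient(series, window)
    assert flags.category("dbp", 0.05) == "abnormal"
    assert flags.category("weight", 0.05) == "normal"
    assert flags.category("urine", 0.05) == "normal"

    early = dbp.copy()
    early[40] += 25  # just before window start
    series2 = make_series({"dbp": early, "sbp": sbp + np.r_[np.zeros(40), [25.0], np.zeros(19)]})
    flags2 = discretize_patient(series2, window)
    assert flags2.category("dbp", 0.05) == "normal"


def test_discretize_patient_nesting_and_quiet_series():
    rng = np.random.default_rng(2)
    series = make_series(
        {
            "dbp": 85 + rng.normal(0, 2, 50),
            "sbp": 135 + rng.normal(0, 2, 50),
            "weight": 60 + rng.normal(0, 0.3, 50),
            "urine": 800 + rng.normal(0, 50, 50),
        }
    )
    window = (START, START + dt.timedelta(days=50))
    flags = discretize_patient(series, window)
    for var in ALL_VARIABLES:
        if flags.category(var, 0.01) == "abnormal":
            assert flags.category(var, 0.05) == "abnormal"
        assert set(flags.dates(var, 0.01)) <= set(flags.dates(var, 0.05))


def test_empty_window_raises():
    series = make_series({"sbp": np.full(20, 120.0)})
    window = (START + dt.timedelta(days=100), START + dt.timedelta(days=115))
    with pytest.raises(EmptyWindowError):
        discretize_patient(series, window)


def test_cohort_vectorized_path_matches_patient_loop():
    cfg = CohortConfig(n_patients=25, hf_prevalence=0.3, follow_up_days=(30, 50), seed=8)
    cohort = generate_cohort(cfg)
    windows = assessment_windows(cohort)
    flags = discretize_cohort(cohort, windows)
    wmap = {
        r.patient_id: (r.start, r.end) for r in windows.itertuples(index=False)
    }
    import pandas as pd

    for series in cohort:
        pid = series.profile.patient_id
        start, end = (pd.Timestamp(wmap[pid][0]).date(), pd.Timestamp(wmap[pid][1]).date())
        fs = discretize_patient(series, (start, end))
        for var in ALL_VARIABLES:
            for alpha in (0.05, 0.01):
                row = flags[
                    (flags["patient_id"] == pid)
                    & (flags["variable"] == var)
                    & (np.isclose(flags["alpha"], alpha))
                ].iloc[0]
                assert row["category"] == fs.category(var, alpha), (pid, var, alpha)
                got = tuple(d for d in row["dates"].split(";") if d)
                want = tuple(d.isoformat() for d in fs.dates(var, alpha))
                assert got == want, (pid, var, alpha)


def test_min_obs_defaults_to_normal_in_cohort_path():
    cfg = CohortConfig(n_patients=8, hf_prevalence=0.0, follow_up_days=(5, 7), seed=1)
    cohort = generate_cohort(cfg)
    flags = discretize_cohort(cohort, assessment_windows(cohort), min_obs=10)
    assert (flags["category"] == "normal").all()


def test_null_calibration_quick():
    """Per-point flag rate ~ alpha on null series (leave-one-out flags)."""
    rate, se = null_flag_rate(300, 60, 0.05, rng=0, leave_one_out=True)
    assert abs(rate - 0.05) < 3 * se
    # default in-fit flagging is slightly conservative, never anti-conservative
    rate_in, _ = null_flag_rate(300, 60, 0.05, rng=0, leave_one_out=False)
    assert 0.5 * 0.05 < rate_in <= 0.055
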