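"""Confusion metrics, Mann-Whitney/DeLong AUC, and decision curves."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdhf.cohort import simulate_analysis_rows
from pdhf.metrics import (
    ConfusionCounts,
    UndefinedMetricError,
    confusion_counts,
    confusion_metrics,
    decision_curve,
    delong_paired_test,
    delong_variance,
    evaluate_model,
    mann_whitney_auc,
    roc_auc,
    sensitivity_analysis,
    youden_threshold,
)
from pdhf.models import fit_logistic
from pdhf.study import sample_case_control


def auc_pair_counting(scores, labels):
    """Brute-force oracle: fraction of case-control pairs correctly ordered."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    x, y = scores[labels == 1], scores[labels == 0]
    wins = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
    return wins / (len(x) * len(y))


def nb_brute_force(scores, labels, pt):
    n = len(labels)
    tp = fp = 0
    for s, l in zip(scores, labels):
        if s >= pt:
            if l == 1:
                tp += 1
            else:
                fp += 1
    return tp / n - (fp / n) * pt / (1 - pt)


class TestConfusion:
    def test_validation_worked_example(self):
        """8 cases / 57 controls with 6 TP and 52 TN: the printed pattern."""
        counts = ConfusionCounts(tp=6, fn=2, fp=5, tn=52)
        m = confusion_metrics(counts)
        assert m.sensitivity == pytest.approx(0.75)
        assert round(m.specificity, 2) == 0.91
        assert m.accuracy == pytest.approx(58 / 65)
        assert round(m.accuracy, 2) == 0.89
        assert round(m.youden, 2) == 0.66

    def test_youden_identity(self):
        m = confusion_metrics(ConfusionCounts(tp=30, fn=10, fp=9, tn=91))
        assert m.youden == pytest.approx(m.sensitivity + m.specificity - 1)

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(tp=10, fn=0, fp=0, tn=40))
        assert (m.sensitivity, m.specificity, m.accuracy, m.youden) == (1, 1, 1, 1)

    def test_empty_class_is_loud(self):
        with pytest.raises(UndefinedMetricError):
            confusion_metrics(ConfusionCounts(tp=0, fn=0, fp=3, tn=7))
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fn=0, fp=0, tn=0)

    def test_counts_partition_rows(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 100)
        scores = rng.random(100)
        c = confusion_counts(labels, scores, 0.4)
        assert c.n == 100


class TestAuc:
    def test_four_point_toy_set(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        assert mann_whitney_auc(scores, labels) == pytest.approx(
            auc_pair_counting(scores, labels)
        )
        assert mann_whitney_auc(scores, labels) == pytest.approx(0.75)

    def test_perfect_separation_auc_one(self):
        assert mann_whitney_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_random_scores_auc_half(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 10000)
        scores = rng.random(10000)
        assert abs(mann_whitney_auc(scores, labels) - 0.5) < 0.02

    def test_tied_scores_use_midranks(self):
        scores = [0.5, 0.5, 0.5, 0.7]
        labels = [0, 1, 0, 1]
        assert mann_whitney_auc(scores, labels) == pytest.approx(
            auc_pair_counting(scores, labels)
        )

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_auc([0.1, 0.2], [1, 1])

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 40)
        labels = np.r_[1, 0, rng.integers(0, 2, n - 2)]
        scores = np.round(rng.random(n), 2)  # coarse grid forces ties
        assert mann_whitney_auc(scores, labels) == pytest.approx(
            auc_pair_counting(scores, labels), rel=1e-12
        )

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        labels = np.r_[1, 0, rng.integers(0, 2, 30)]
        scores = rng.random(32)
        transformed = np.exp(3.0 * scores) + 1.0
        assert mann_whitney_auc(scores, labels) == pytest.approx(
            mann_whitney_auc(transformed, labels)
        )

    def test_delong_ci_and_variance_sane(self):
        rng = np.random.default_rng(7)
        labels = np.r_[np.ones(60, int), np.zeros(240, int)]
        scores = np.r_[rng.normal(1.0, 1.0, 60), rng.normal(0.0, 1.0, 240)]
        res = roc_auc(scores, labels)
        assert 0.0 <= res.ci_lower < res.auc < res.ci_upper <= 1.0
        # variance cross-checked against a bootstrap of the AUC
        boots = []
        for b in range(400):
            idx = rng.integers(0, 300, 300)
            if labels[idx].min() == labels[idx].max():
                continue
            boots.append(mann_whitney_auc(scores[idx], labels[idx]))
        ratio = np.sqrt(res.variance) / np.std(boots, ddof=1)
        assert 0.7 < ratio < 1.4

    def test_paired_test_self_comparison(self):
        rng = np.random.default_rng(3)
        labels = np.r_[np.ones(30, int), np.zeros(90, int)]
        scores = rng.random(120)
        res = delong_paired_test(scores, scores, labels)
        assert res.auc1 == res.auc2
        assert res.p_value == pytest.approx(1.0)

    def test_paired_test_detects_dominant_model(self):
        rng = np.random.default_rng(4)
        labels = np.r_[np.ones(100, int), np.zeros(300, int)]
        good = labels + rng.normal(0, 0.3, 400)
        bad = rng.random(400)
        res = delong_paired_test(good, bad, labels)
        assert res.auc1 > res.auc2
        assert res.p_value < 0.001


class TestDecisionCurve:
    def test_treat_all_closed_form(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 500)
        scores = rng.random(500)
        dca = decision_curve(scores, labels)
        prev = labels.mean()
        pt = dca["threshold"].to_numpy()
        np.testing.assert_allclose(
            dca["net_benefit_all"], prev - (1 - prev) * pt / (1 - pt), rtol=1e-12
        )
        assert (dca["net_benefit_none"] == 0).all()

    def test_perfect_model_net_benefit_equals_prevalence(self):
        labels = np.r_[np.ones(20, int), np.zeros(80, int)]
        scores = labels.astype(float)
        dca = decision_curve(scores, labels)
        np.testing.assert_allclose(dca["net_benefit_model"], 0.2, rtol=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, 80)
        scores = rng.random(80)
        dca = decision_curve(scores, labels, np.array([0.05, 0.25, 0.5, 0.9]))
        for _, row in dca.iterrows():
            assert row["net_benefit_model"] == pytest.approx(
                nb_brute_force(scores, labels, row["threshold"]), rel=1e-12
            )

    def test_model_never_beats_perfect_envelope(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            labels = np.r_[1, 0, rng.integers(0, 2, 60)]
            scores = rng.random(62)
            dca = decision_curve(scores, labels)
            assert (dca["net_benefit_model"] <= labels.mean() + 1e-12).all()

    def test_degenerate_thresholds_excluded(self):
        labels = np.r_[1, 1, 0, 0]
        with pytest.warns(UserWarning, match="outside"):
            dca = decision_curve([0.9, 0.8, 0.2, 0.1], labels, np.array([0.0, 0.5, 1.0]))
        assert list(dca["threshold"]) == [0.5]


@pytest.fixture(scope="module")
def fitted():
    rows = simulate_analysis_rows(6000, target_prevalence=0.15, rng=11)
    model = fit_logistic(rows.iloc[:4000], ("sex", "age", "dbp_cat"))
    val = rows.iloc[4000:].reset_index(drop=True)
    return model, val


class TestEvaluateModel:
    def test_youden_policy_report(self, fitted):
        model, val = fitted
        rep = evaluate_model(model, val, "youden")
        assert rep.youden == pytest.approx(rep.sensitivity + rep.specificity - 1)
        assert rep.auc_ci[0] < rep.auc < rep.auc_ci[1]
        assert rep.auc > 0.7  # planted signal is detectable
        assert rep.counts.n == len(val)
        # ROC is monotone in both coordinates
        assert (np.diff(rep.roc["fpr"]) >= 0).all()
        assert (np.diff(rep.roc["tpr"]) >= 0).all()

    def test_threshold_zero_extreme(self, fitted):
        model, val = fitted
        rep = evaluate_model(model, val, 0.0)
        assert rep.sensitivity == 1.0 and rep.specificity == 0.0

    def test_constant_scores_auc_half(self, fitted):
        _, val = fitted
        rows = val.copy()

        class Dummy:
            training_scores = np.array([0.5, 0.5, 0.4])
            training_labels = np.array([1, 0, 0])

            def predict(self, r):
                return np.full(len(r), 0.3)

        rep = evaluate_model(Dummy(), rows, 0.5)
        assert rep.auc == pytest.approx(0.5)

    def test_empty_or_single_class_validation(self, fitted):
        model, val = fitted
        with pytest.raises(ValueError):
            evaluate_model(model, val.iloc[0:0])
        with pytest.raises(ValueError):
            evaluate_model(model, val[val.hf_label == 0])


class TestSensitivityAnalysis:
    def test_ratio_errors_are_isolated(self):
        rows = simulate_analysis_rows(800, target_prevalence=0.1, rng=21)
        out = sensitivity_analysis(rows, rows, ratios=(4, 50), sample_seed=0, split_seed=1)
        assert "error" not in out[4]
        assert "error" in out[50]  # not enough controls at 1:50

    def test_single_ratio_matches_main_pipeline(self):
        from pdhf.metrics import run_ratio

        rows = simulate_analysis_rows(3000, target_prevalence=0.1, rng=22)
        main = run_ratio(rows, rows, 6, sample_seed=3, split_seed=4)
        sens = sensitivity_analysis(rows, rows, ratios=(6,), sample_seed=3, split_seed=4)
        assert sens[6]["optimal"].variables == main["optimal"].variables
        assert sens[6]["report"].auc == pytest.approx(main["report"].auc)


def test_youden_threshold_known_instance():
    labels = np.array([1, 1, 1, 0, 0, 0, 0])
    scores = np.array([0.9, 0.8, 0.3, 0.4, 0.2, 0.1, 0.05])
    thr = youden_threshold(scores, labels)
    # J maximized at thr=0.3: sens 1, spec 3/4 (J=0.75) beats thr=0.8 (J=2/3)
    pred = scores >= thr
    sens = pred[labels == 1].mean()
    spec = 1 - pred[labels == 0].mean()
    assert sens + spec - 1 == pytest.approx(0.75)
    assert pred.sum() == 4
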