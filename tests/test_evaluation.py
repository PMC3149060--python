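"""Scoring, exact binomial intervals, AUC, calibration and surveillance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from drainsurv.evaluation import (
    ScoringError,
    calibration_table,
    clopper_pearson,
    confusion_from_counts,
    confusion_metrics,
    display_interval,
    predict_probability,
    roc_auc,
    surveillance_summary,
    workload_reduction,
)
from drainsurv.model import PredictionRule

RULE = PredictionRule(intercept=-3.0, coefficients={"x": np.log(13.70)})


# --- scoring --------------------------------------------------------------

def test_logistic_identities():
    rule0 = PredictionRule(intercept=0.0, coefficients={"x": 1.0})
    assert predict_probability(rule0, pd.Series({"x": 0.0})) == pytest.approx(0.5)
    rule = PredictionRule(intercept=-3.0, coefficients={"x": 0.5})
    assert predict_probability(rule, pd.Series({"x": 0.0})) == pytest.approx(
        1 / (1 + np.exp(3))
    )


def test_flipping_binary_predictor_multiplies_odds():
    p0 = predict_probability(RULE, pd.Series({"x": 0.0}))
    p1 = predict_probability(RULE, pd.Series({"x": 1.0}))
    odds = lambda p: p / (1 - p)
    assert odds(p1) / odds(p0) == pytest.approx(13.70)


def test_missing_predictor_raises_scoring_error():
    with pytest.raises(ScoringError, match="missing"):
        predict_probability(RULE, pd.Series({"x": np.nan}))
    with pytest.raises(ScoringError):
        predict_probability(RULE, pd.DataFrame({"y": [1.0]}))


# --- confusion metrics ----------------------------------------------------

def test_confusion_from_printed_counts():
    rep = confusion_from_counts(81, 55, 1, 400)
    assert round(rep.sensitivity * 100, 1) == 98.8
    assert round(rep.specificity * 100, 1) == 87.9
    assert round(rep.ppv * 100, 1) == 59.6
    assert round(rep.npv * 100, 1) == 99.8
    assert rep.n == 537


def test_confusion_internal_consistency():
    rep = confusion_from_counts(78, 41, 4, 414)
    assert rep.sensitivity * (rep.tp + rep.fn) == pytest.approx(rep.tp)
    assert rep.specificity * (rep.tn + rep.fp) == pytest.approx(rep.tn)
    assert rep.ppv * (rep.tp + rep.fp) == pytest.approx(rep.tp)
    assert rep.npv * (rep.tn + rep.fn) == pytest.approx(rep.tn)


def test_confusion_metrics_strict_cutoff_and_perfect_scores():
    p = np.array([0.9, 0.8, 0.107, 0.05])
    y = np.array([1, 1, 0, 0])
    rep = confusion_metrics(p, y, 0.107)
    assert (rep.tp, rep.fp, rep.fn, rep.tn) == (2, 0, 0, 2)  # 0.107 is NOT above itself
    perfect = confusion_metrics(np.array([0.9, 0.1]), np.array([1, 0]), 0.5)
    for m in ("sensitivity", "specificity", "ppv", "npv"):
        assert getattr(perfect, m) == 1.0


def test_confusion_metrics_validation():
    with pytest.raises(ValueError):
        confusion_metrics([], [], 0.5)
    with pytest.raises(ValueError):
        confusion_metrics([0.5], [2], 0.5)
    with pytest.raises(ValueError):
        confusion_metrics([0.5], [1], 1.5)


# --- Clopper-Pearson ------------------------------------------------------

def _cp_bruteforce(x, n, level=0.95):
    """Root-find the binomial tail probabilities directly."""
    from scipy.optimize import brentq

    alpha = 1 - level
    lo = 0.0 if x == 0 else brentq(
        lambda p: stats.binom.sf(x - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12
    )
    hi = 1.0 if x == n else brentq(
        lambda p: stats.binom.cdf(x, n, p) - alpha / 2, 1e-12, 1 - 1e-12
    )
    return lo, hi


@pytest.mark.parametrize("n", [1, 5, 12, 20])
def test_clopper_pearson_matches_tail_inversion_oracle(n):
    for x in range(n + 1):
        lo, hi = clopper_pearson(x, n)
        blo, bhi = _cp_bruteforce(x, n)
        assert lo == pytest.approx(blo, abs=1e-9)
        assert hi == pytest.approx(bhi, abs=1e-9)


def test_clopper_pearson_boundaries_and_validation():
    assert clopper_pearson(0, 10)[0] == 0.0
    assert clopper_pearson(82, 82)[1] == 1.0
    lo, hi = clopper_pearson(5, 10)
    assert lo < 0.5 < hi
    with pytest.raises(ValueError):
        clopper_pearson(-1, 10)
    with pytest.raises(ValueError):
        clopper_pearson(11, 10)
    with pytest.raises(ValueError):
        clopper_pearson(1, 10, level=1.5)


def test_display_interval_never_prints_unattained_boundary():
    assert display_interval(clopper_pearson(81, 82)) == (93.4, 99.9)
    assert display_interval(clopper_pearson(400, 401)) == (98.6, 99.9)
    assert display_interval(clopper_pearson(82, 82)) == (95.6, 100.0)
    assert display_interval((0.0, 0.2)) == (0.0, 20.0)


# --- ROC AUC --------------------------------------------------------------

def _auc_bruteforce(scores, y):
    """O(n^2) pairwise concordance, ties counted one half."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def test_auc_perfect_separation_and_rank_invariance():
    y = np.array([0, 0, 1, 1])
    s = np.array([0.1, 0.2, 0.8, 0.9])
    assert roc_auc(s, y)[0] == pytest.approx(1.0)
    auc1, _ = roc_auc(s, y)
    auc2, _ = roc_auc(np.log(s / (1 - s)), y)  # monotone transform
    assert auc1 == pytest.approx(auc2)


@pytest.mark.parametrize("seed", range(5))
def test_auc_matches_pairwise_oracle(seed):
    rng = np.random.default_rng(seed)
    n = 200
    y = (rng.random(n) < 0.3).astype(int)
    y[:2] = [0, 1]  # both classes present
    s = np.round(rng.random(n), 2)  # rounding forces ties
    auc, ci = roc_auc(s, y)
    assert auc == pytest.approx(_auc_bruteforce(s, y), abs=1e-12)
    assert ci[0] <= auc <= ci[1]


def test_auc_single_class_rejected():
    with pytest.raises(ValueError):
        roc_auc([0.2, 0.4], [1, 1])


# --- calibration ----------------------------------------------------------

def test_calibration_simulated_data_near_diagonal():
    rng = np.random.default_rng(5)
    p = rng.uniform(0.02, 0.9, 4000)
    y = (rng.random(4000) < p).astype(int)
    table = calibration_table(p, y, bins=10)
    assert len(table) == 10
    for _, row in table.iterrows():
        se = np.sqrt(row["mean_predicted"] * (1 - row["mean_predicted"]) / row["n"])
        assert abs(row["observed"] - row["mean_predicted"]) <= 4 * se


def test_calibration_single_bin_is_prevalence():
    rng = np.random.default_rng(6)
    y = (rng.random(500) < 0.3).astype(int)
    p = rng.uniform(0, 1, 500)
    table = calibration_table(p, y, bins=1)
    assert table["observed"].iloc[0] == pytest.approx(y.mean())


def test_calibration_requires_enough_observations():
    with pytest.raises(ValueError):
        calibration_table([0.5, 0.6], [0, 1], bins=10)


# --- surveillance ---------------------------------------------------------

def _episodes_frame(years, days):
    return pd.DataFrame({"year": years, "days_at_risk": days})


def test_expected_count_is_summed_probability():
    eps = _episodes_frame([2005, 2005, 2005], [100, 100, 100])
    (s,) = surveillance_summary([1.0, 0.0, 0.0], eps)
    assert s.expected_infections == pytest.approx(1.0)


def test_rate_per_1000_days():
    eps = _episodes_frame([2005] * 10, [100.0] * 10)
    probs = np.full(10, 0.95)  # expected 9.5 infections over 1000 days at risk
    (s,) = surveillance_summary(probs, eps)
    assert s.predicted_rate == pytest.approx(1000 * 9.5 / 1000.0)


def test_observed_rates_and_poisson_ci():
    eps = _episodes_frame([2004] * 4 + [2005] * 4, [50.0] * 8)
    p = np.array([0.9, 0.1, 0.1, 0.1, 0.8, 0.7, 0.1, 0.1])
    y = np.array([1, 0, 0, 0, 1, 1, 0, 0])
    s04, s05 = surveillance_summary(p, eps, truth=y)
    assert s04.observed_infections == 1 and s05.observed_infections == 2
    lo, hi = s05.observed_ci
    assert lo < 2 < hi
    assert s05.observed_rate == pytest.approx(1000 * 2 / 200.0)
    assert s04.expected_ci[0] <= s04.expected_infections <= s04.expected_ci[1]


def test_zero_days_at_risk_rejected():
    eps = _episodes_frame([2004], [0.0])
    with pytest.raises(ValueError, match="zero days at risk"):
        surveillance_summary([0.5], eps)


def test_workload_reduction():
    p = np.r_[np.full(136, 0.5), np.full(401, 0.01)]
    assert workload_reduction(p, 0.107) * 100 == pytest.approx(25.3, abs=0.05)
    assert workload_reduction([0.01], 0.107) == 0.0
    assert workload_reduction([0.9, 0.8], 0.107) == 1.0
    with pytest.raises(ValueError):
        workload_reduction([], 0.107)
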