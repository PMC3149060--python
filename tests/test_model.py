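"""Model development: screening, logistic fitting (incl. the 2x2 closed-form
oracle and Firth fallback), backward selection with the CRP hierarchy, and
bootstrap optimism correction."""

import numpy as np
import pandas as pd
import pytest

from drainsurv.imputation import ImputationSet
from drainsurv.model import (
    PredictionRule,
    backward_select,
    bootstrap_optimism,
    build_prediction_rule,
    firth_logistic,
    fit_logistic,
    pooled_fit,
    shrink_and_recalibrate,
    univariate_screen,
)
from drainsurv.synth_cohort import generate_model_cohort


def _identity_set(df, m=2):
    return ImputationSet(matrices=[df.copy() for _ in range(m)], seed=0)


# --- univariate screening -------------------------------------------------

def test_screen_two_by_two_strongly_associated():
    """Drain type vs infection at the published group counts is overwhelmingly
    significant."""
    y = np.array([1] * 82 + [0] * 455)
    x = np.array([1] * 71 + [0] * 11 + [1] * 266 + [0] * 189)
    df = pd.DataFrame({"drain_type_evd": x, "drm_flag": y})
    (res,) = univariate_screen(df, "drm_flag", {"drain_type_evd": "binary"})
    assert res.test == "chi-square"
    assert res.p_value < 0.001 and res.selected


def test_screen_null_simulation_rejects_at_alpha():
    """Under no association the selection rate approximates alpha."""
    rng = np.random.default_rng(42)
    hits = 0
    reps = 400
    for _ in range(reps):
        y = (rng.random(300) < 0.3).astype(int)
        x = rng.normal(size=300)
        df = pd.DataFrame({"x": x, "drm_flag": y})
        (res,) = univariate_screen(df, "drm_flag", {"x": "continuous_normal"})
        hits += res.selected
    se = np.sqrt(0.05 * 0.95 / reps)
    assert abs(hits / reps - 0.05) <= 4 * se


def test_screen_constant_variable_flagged():
    df = pd.DataFrame({"x": np.ones(50), "drm_flag": np.r_[np.ones(25), np.zeros(25)]})
    (res,) = univariate_screen(df, "drm_flag", {"x": "continuous_skewed"})
    assert res.test == "degenerate" and not res.selected


# --- logistic fitting -----------------------------------------------------

def test_fit_matches_two_by_two_log_odds_ratio():
    """Single binary predictor with cell counts (81, 55, 1, 400)."""
    x = np.array([1] * 81 + [1] * 55 + [0] * 1 + [0] * 400)
    y = np.array([1] * 81 + [0] * 55 + [1] * 1 + [0] * 400)
    coefs, _, rep = fit_logistic(pd.DataFrame({"x": x}), y)
    expected = np.log((81 * 400) / (55 * 1))
    assert coefs["x"] == pytest.approx(expected, rel=1e-4)
    assert rep["method"] == "mle"


def test_fit_null_coefficients_small():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.normal(size=(10_000, 3)), columns=list("abc"))
    y = (rng.random(10_000) < 0.2).astype(int)
    coefs, cov, _ = fit_logistic(X, y)
    se = np.sqrt(np.diag(cov))
    slopes = coefs.drop("const").to_numpy()  # intercept is not null here
    assert np.all(np.abs(slopes) < 3 * se[1:])


def test_fit_recovers_known_coefficients():
    rng = np.random.default_rng(1)
    n = 5000
    X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
    lp = -1.0 + 0.8 * X["a"] - 0.5 * X["b"]
    y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
    coefs, cov, _ = fit_logistic(X, y)
    se = np.sqrt(np.diag(cov))
    truth = np.array([-1.0, 0.8, -0.5])
    assert np.all(np.abs(coefs.to_numpy() - truth) <= 3 * se)


def test_separation_falls_back_to_firth():
    x = np.r_[np.zeros(20), np.ones(20)]
    y = x.copy()  # perfectly separated
    coefs, cov, rep = fit_logistic(pd.DataFrame({"x": x}), y)
    assert rep["method"] == "firth" and rep["separation"]
    assert np.all(np.isfinite(coefs)) and np.all(np.isfinite(np.diag(cov)))


def test_firth_agrees_with_mle_when_well_behaved():
    rng = np.random.default_rng(3)
    n = 4000
    X = pd.DataFrame({"a": rng.normal(size=n)})
    y = (rng.random(n) < 1 / (1 + np.exp(-0.5 * X["a"]))).astype(int)
    mle, _, _ = fit_logistic(X, y)
    import statsmodels.api as sm

    Xd = sm.add_constant(X.astype(float)).to_numpy()
    firth, _, _ = firth_logistic(Xd, y.to_numpy(dtype=float))
    assert firth == pytest.approx(mle.to_numpy(), abs=0.02)


# --- backward selection ---------------------------------------------------

def _selection_frame(n=3000, seed=0, with_null=True):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        {
            "strong1": rng.normal(size=n),
            "strong2": (rng.random(n) < 0.4).astype(float),
        }
    )
    lp = -1.5 + 1.2 * X["strong1"] + 1.5 * X["strong2"]
    X["drm_flag"] = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
    if with_null:
        X["noise"] = rng.normal(size=n)
    return X


def test_strong_predictors_all_kept():
    df = _selection_frame(with_null=False)
    selected, trace = backward_select(
        _identity_set(df), ["strong1", "strong2"], "drm_flag"
    )
    assert selected == ["strong1", "strong2"] and trace == []


def test_null_predictor_removed_and_fixed_point():
    df = _selection_frame(seed=5)
    imp = _identity_set(df)
    selected, trace = backward_select(imp, ["strong1", "strong2", "noise"], "drm_flag")
    assert "noise" not in selected
    again, trace2 = backward_select(imp, selected, "drm_flag")
    assert again == selected and trace2 == []


def test_selection_output_is_subset_and_empty_candidates_rejected():
    df = _selection_frame()
    imp = _identity_set(df)
    selected, _ = backward_select(imp, ["strong1", "noise"], "drm_flag")
    assert set(selected) <= {"strong1", "noise"}
    with pytest.raises(ValueError):
        backward_select(imp, [], "drm_flag")


def test_linear_crp_protected_while_power_term_remains(published_rule):
    """The linear term survives despite a high p-value as long as a
    significant higher-power term is in the model."""
    X, y, _ = generate_model_cohort(published_rule, 4000, seed=17)
    df = X.copy()
    df["drm_flag"] = y
    imp = _identity_set(df)
    candidates = ["crp", "crp_sq", "crp_cu", "culture_positive", "n_abx_started"]
    selected, trace = backward_select(imp, candidates, "drm_flag")
    removed = [name for name, _ in trace]
    if any(t in selected for t in ("crp_sq", "crp_cu")):
        assert "crp" in selected
    assert "crp" not in removed or not any(
        t in selected for t in ("crp_sq", "crp_cu")
    )


# --- bootstrap optimism ---------------------------------------------------

def test_degenerate_resampler_gives_zero_optimism():
    df = _selection_frame(n=500, seed=8, with_null=False)
    imp = _identity_set(df)
    out = bootstrap_optimism(
        imp, ["strong1", "strong2"], "drm_flag", B=10, seed=0,
        resample_fn=lambda rng, n: np.arange(n),
    )
    assert out["optimism"] == pytest.approx(0.0, abs=1e-12)
    assert out["shrinkage"] == pytest.approx(1.0, abs=1e-6)
    assert out["auc_corrected"] == pytest.approx(out["auc_apparent"])


def test_small_sample_noise_predictors_shrink():
    rng = np.random.default_rng(9)
    n = 100
    X = pd.DataFrame(rng.normal(size=(n, 10)), columns=[f"x{i}" for i in range(10)])
    X["drm_flag"] = (rng.random(n) < 0.3).astype(int)
    imp = _identity_set(X)
    out = bootstrap_optimism(imp, [f"x{i}" for i in range(10)], "drm_flag", B=40, seed=1)
    assert out["shrinkage"] < 1.0
    assert out["auc_corrected"] <= out["auc_apparent"]


def test_bootstrap_rejects_tiny_B():
    df = _selection_frame(n=200)
    with pytest.raises(ValueError):
        bootstrap_optimism(_identity_set(df), ["strong1"], "drm_flag", B=5)


# --- rule assembly --------------------------------------------------------

def test_published_or_to_beta():
    rule = build_prediction_rule({"culture_positive": 13.70}, intercept=-3.0)
    assert rule.coefficients["culture_positive"] == pytest.approx(np.log(13.70))
    assert rule.odds_ratios["culture_positive"] == pytest.approx(13.70)
    assert rule.provenance == "published"


def test_nonpositive_or_rejected():
    with pytest.raises(ValueError):
        build_prediction_rule({"x": 0.0}, intercept=0.0)


def test_all_unit_ors_give_constant_lp():
    rule = build_prediction_rule({"a": 1.0, "b": 1.0}, intercept=-2.0)
    X = pd.DataFrame({"a": [0, 5, 2.0], "b": [1, 0, 3.0]})
    assert np.allclose(rule.linear_predictor(X), -2.0)


def test_intercept_calibration_hits_prevalence(published_rule):
    X, _, _ = generate_model_cohort(published_rule, 20_000, seed=991)
    rule = build_prediction_rule(
        {k: np.exp(v) for k, v in published_rule.coefficients.items()},
        reference_X=X,
        prevalence=0.153,
    )
    assert rule.predict(X).mean() == pytest.approx(0.153, abs=0.001)


def test_shrinkage_applied_multiplicatively_and_exp_beta_is_or():
    df = _selection_frame(n=2000, seed=12, with_null=False)
    coefs, _, _ = fit_logistic(df[["strong1", "strong2"]], df["drm_flag"])
    rule = shrink_and_recalibrate(coefs, 0.8, df[["strong1", "strong2"]], df["drm_flag"])
    assert rule.coefficients["strong1"] == pytest.approx(0.8 * coefs["strong1"])
    assert rule.shrinkage == 0.8
    # the shrunk rule stays calibrated-in-the-large on its own data
    assert rule.predict(df).mean() == pytest.approx(df["drm_flag"].mean(), abs=0.01)


def test_rule_json_roundtrip(tmp_path, published_rule):
    path = tmp_path / "model.json"
    published_rule.to_json(path)
    back = PredictionRule.from_json(path)
    assert back.intercept == published_rule.intercept
    assert back.coefficients == published_rule.coefficients
    assert back.provenance == "published"


def test_pooled_fit_combines_imputations():
    df = _selection_frame(n=800, seed=20, with_null=False)
    dfs = [df.copy(), df.copy()]
    dfs[1]["strong1"] += 0.01  # tiny between-imputation perturbation
    imp = ImputationSet(matrices=dfs, seed=0)
    pooled, rep = pooled_fit(imp, ["strong1", "strong2"], "drm_flag")
    assert pooled.names == ["const", "strong1", "strong2"]
    assert np.all(pooled.T >= pooled.W_bar)
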