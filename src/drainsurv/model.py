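"""Development of the logistic prediction model.

The pipeline mirrors standard clinical prediction-model practice: univariate
screening (chi-square / t / Mann-Whitney, p < 0.05 on the mean imputed
dataset), multivariable logistic regression on each imputed dataset,
backward selection on Rubin-pooled Wald p-values with a polynomial hierarchy
constraint (the linear CRP term is never dropped while one of its power
terms remains), and bootstrap internal validation: the calibration slope of
each bootstrap-refitted model on the original data estimates the optimism of
the apparent fit; its average is applied as a uniform coefficient shrinkage
factor, with the intercept re-estimated, and the apparent AUC is debited by
the mean bootstrap optimism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import brentq
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .imputation import ImputationSet, pool_rubin

__all__ = [
    "ScreeningResult",
    "PredictionRule",
    "univariate_screen",
    "fit_logistic",
    "firth_logistic",
    "backward_select",
    "pooled_fit",
    "pooled_wald_pvalues",
    "bootstrap_optimism",
    "shrink_and_recalibrate",
    "build_prediction_rule",
    "CRP_HIERARCHY",
]

# the linear term is protected while any of its power terms is in the model
CRP_HIERARCHY = {"crp": ("crp_sq", "crp_cu")}

ALPHA_DEFAULT = 0.05


@dataclass
class ScreeningResult:
    variable: str
    test: str  # chi-square | t | mann-whitney | degenerate
    statistic: float
    p_value: float
    selected: bool


@dataclass
class PredictionRule:
    """Intercept + coefficient map on the log-odds scale.

    ``P(DRM) = 1 / (1 + exp(-LP))`` with ``LP = intercept + sum(beta_j x_j)``.
    """

    intercept: float
    coefficients: dict
    shrinkage: float = 1.0
    provenance: str = "fitted"  # or "published"

    def __post_init__(self):
        if not 0 < self.shrinkage <= 1:
            raise ValueError("shrinkage must lie in (0, 1]")

    @property
    def odds_ratios(self) -> dict:
        return {k: float(np.exp(b)) for k, b in self.coefficients.items()}

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        missing_cols = [c for c in self.coefficients if c not in X.columns]
        if missing_cols:
            raise ValueError(f"feature matrix lacks predictors {missing_cols}")
        lp = np.full(len(X), self.intercept, dtype=float)
        for name, beta in self.coefficients.items():
            lp += beta * X[name].to_numpy(dtype=float)
        return lp

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(X)))

    def to_json(self, path) -> None:
        payload = {
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "odds_ratios": self.odds_ratios,
            "shrinkage": self.shrinkage,
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PredictionRule":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            intercept=payload["intercept"],
            coefficients=payload["coefficients"],
            shrinkage=payload.get("shrinkage", 1.0),
            provenance=payload.get("provenance", "fitted"),
        )


# ---------------------------------------------------------------------------
# univariate screening
# ---------------------------------------------------------------------------

def univariate_screen(
    data: pd.DataFrame,
    outcome: str,
    variable_kinds: dict,
    alpha: float = ALPHA_DEFAULT,
) -> list[ScreeningResult]:
    """Per-variable two-group comparison on the mean imputed dataset.

    ``variable_kinds`` maps each candidate to 'binary' (chi-square),
    'continuous_normal' (Welch t) or 'continuous_skewed' (Mann-Whitney U).
    Zero-variance variables are reported as degenerate and never selected.
    """
    y = data[outcome].to_numpy()
    results = []
    for var, kind in variable_kinds.items():
        x = data[var].to_numpy(dtype=float)
        if np.nanstd(x) == 0:
            results.append(ScreeningResult(var, "degenerate", np.nan, 1.0, False))
            continue
        x1, x0 = x[y == 1], x[y == 0]
        if kind == "binary":
            table = pd.crosstab(x, y)
            stat, p, _, _ = stats.chi2_contingency(table.to_numpy())
            test = "chi-square"
        elif kind == "continuous_normal":
            stat, p = stats.ttest_ind(x1, x0, equal_var=False)
            test = "t"
        elif kind == "continuous_skewed":
            stat, p = stats.mannwhitneyu(x1, x0, alternative="two-sided")
            test = "mann-whitney"
        else:
            raise ValueError(f"unknown variable kind {kind!r} for {var!r}")
        results.append(ScreeningResult(var, test, float(stat), float(p), bool(p < alpha)))
    return results


# ---------------------------------------------------------------------------
# logistic fitting (maximum likelihood, Firth fallback under separation)
# ---------------------------------------------------------------------------

def firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-8):
    """Penalised logistic regression with Jeffreys-prior (Firth) correction.

    Finite estimates exist even under complete separation.  Returns
    (coefficients, covariance, n_iter).
    """
    n, p = X.shape
    beta = np.zeros(p)
    for it in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        XW = X * w[:, None]
        info = X.T @ XW
        info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", XW, info_inv, X)  # hat diagonal
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    cov = np.linalg.pinv(X.T @ (X * w[:, None]))
    return beta, cov, it + 1


def fit_logistic(X: pd.DataFrame, y, add_constant: bool = True):
    """Maximum-likelihood logistic fit with separation detection.

    Returns ``(coefficients: Series, covariance: DataFrame, report: dict)``;
    under (quasi-)separation falls back to a Firth-penalised fit, flagged in
    the report.
    """
    Xd = X.astype(float)
    if add_constant:
        Xd = sm.add_constant(Xd, has_constant="add")
    y = np.asarray(y, dtype=float)
    if len(Xd) <= Xd.shape[1]:
        raise ValueError("need more observations than parameters")
    report = {"method": "mle", "converged": True, "separation": False}
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, Xd).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", True))
        se = np.sqrt(np.diag(res.cov_params()))
        suspicious = (not converged) or not np.all(np.isfinite(se)) or np.any(se > 1e3)
        if suspicious:
            raise PerfectSeparationError("unstable maximum-likelihood fit")
        coefs = pd.Series(res.params, index=Xd.columns)
        cov = pd.DataFrame(res.cov_params(), index=Xd.columns, columns=Xd.columns)
        return coefs, cov, report
    except (PerfectSeparationError, np.linalg.LinAlgError):
        beta, cov_arr, n_iter = firth_logistic(Xd.to_numpy(), y)
        report.update(method="firth", separation=True, converged=True, n_iter=n_iter)
        coefs = pd.Series(beta, index=Xd.columns)
        cov = pd.DataFrame(cov_arr, index=Xd.columns, columns=Xd.columns)
        return coefs, cov, report


# ---------------------------------------------------------------------------
# backward selection on Rubin-pooled Wald p-values
# ---------------------------------------------------------------------------

def pooled_fit(imp: ImputationSet, predictors: list, outcome: str):
    """Fit each completed dataset; Rubin-pool coefficients and variances."""
    estimates, variances = [], []
    report = {"separation": False}
    for mat in imp.matrices:
        coefs, cov, rep = fit_logistic(mat[predictors], mat[outcome])
        estimates.append(coefs.to_numpy())
        variances.append(np.diag(cov.to_numpy()))
        report["separation"] |= rep["separation"]
    pooled = pool_rubin(np.vstack(estimates), np.vstack(variances))
    pooled.names = ["const"] + predictors
    return pooled, report


def pooled_wald_pvalues(pooled) -> pd.Series:
    """Two-sided p-values from the Rubin-pooled t reference distribution."""
    t = pooled.q_bar / pooled.se
    df = pooled.df
    p = np.where(
        np.isinf(df),
        2 * stats.norm.sf(np.abs(t)),
        2 * stats.t.sf(np.abs(t), np.maximum(df, 1.0)),
    )
    return pd.Series(p, index=pooled.names)


def backward_select(
    imp: ImputationSet,
    candidates: list,
    outcome: str,
    alpha: float = ALPHA_DEFAULT,
    hierarchy: dict = CRP_HIERARCHY,
) -> tuple[list, list]:
    """Iteratively drop the least significant predictor (pooled Wald p >= alpha).

    A parent term named in ``hierarchy`` is protected while any of its power
    terms is still in the model.  Returns (selected predictors, removal trace).
    """
    if not candidates:
        raise ValueError("empty candidate set")
    current = list(candidates)
    trace = []
    while True:
        pooled, _ = pooled_fit(imp, current, outcome)
        pvals = pooled_wald_pvalues(pooled).drop("const")
        protected = {
            parent
            for parent, children in hierarchy.items()
            if parent in current and any(c in current for c in children)
        }
        removable = pvals.drop(list(protected), errors="ignore")
        if removable.empty or removable.max() < alpha:
            return current, trace
        worst = removable.idxmax()
        trace.append((worst, float(removable.max())))
        current.remove(worst)
        if not current:
            return current, trace


# ---------------------------------------------------------------------------
# bootstrap optimism correction
# ---------------------------------------------------------------------------

def _auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Rank-statistic AUC with tie correction (ties count one half)."""
    ranks = stats.rankdata(scores)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes required")
    return (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def bootstrap_optimism(
    imp: ImputationSet,
    predictors: list,
    outcome: str,
    B: int = 100,
    seed: int = 0,
    resample_fn=None,
):
    """Harrell-style internal validation over every completed dataset.

    For each of the ``B`` bootstrap resamples per imputation the model is
    refitted; its calibration slope on the original data (the coefficient of
    the bootstrap linear predictor in a one-variable logistic refit) estimates
    the shrinkage needed, and the drop in AUC from the bootstrap sample to the
    original data estimates the optimism of the apparent AUC.

    Returns a dict with ``shrinkage``, ``auc_apparent``, ``auc_corrected``,
    ``optimism`` and per-imputation detail.
    """
    if B < 10:
        raise ValueError("at least 10 bootstrap samples required")
    rng = np.random.default_rng(seed)
    if resample_fn is None:
        resample_fn = lambda rng, n: rng.integers(0, n, n)
    slopes, optimisms, apparent = [], [], []
    for mat in imp.matrices:
        X = mat[predictors].astype(float)
        y = mat[outcome].to_numpy(dtype=float)
        n = len(mat)
        coefs, _, _ = fit_logistic(X, y)
        lp_app = sm.add_constant(X, has_constant="add").to_numpy() @ coefs.to_numpy()
        apparent.append(_auc(lp_app, y))
        for _ in range(B):
            idx = resample_fn(rng, n)
            Xb, yb = X.iloc[idx], y[idx]
            if yb.sum() in (0, len(yb)):
                continue  # degenerate resample: one class only
            cb, _, _ = fit_logistic(Xb, yb)
            lp_orig = sm.add_constant(X, has_constant="add").to_numpy() @ cb.to_numpy()
            lp_boot = lp_orig[idx]
            slope_coefs, _, _ = fit_logistic(
                pd.DataFrame({"lp": lp_orig}), y
            )
            slopes.append(slope_coefs["lp"])
            optimisms.append(_auc(lp_boot, yb) - _auc(lp_orig, y))
    shrinkage = float(np.clip(np.mean(slopes), 1e-6, 1.0))
    auc_apparent = float(np.mean(apparent))
    optimism = float(np.mean(optimisms)) if optimisms else 0.0
    return {
        "shrinkage": shrinkage,
        "calibration_slope": float(np.mean(slopes)),
        "auc_apparent": auc_apparent,
        "optimism": max(optimism, 0.0),
        "auc_corrected": auc_apparent - max(optimism, 0.0),
        "n_resamples": len(slopes),
    }


def shrink_and_recalibrate(
    pooled_coefs: pd.Series, shrinkage: float, X: pd.DataFrame, y
) -> PredictionRule:
    """Multiply coefficients by the shrinkage factor and refit the intercept
    (logistic fit of the outcome on the shrunk linear predictor as offset)."""
    betas = {k: float(v) * shrinkage for k, v in pooled_coefs.items() if k != "const"}
    offset = np.zeros(len(X))
    for name, b in betas.items():
        offset += b * X[name].to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    res = sm.GLM(
        y, np.ones((len(X), 1)), family=sm.families.Binomial(), offset=offset
    ).fit()
    return PredictionRule(
        intercept=float(res.params[0]),
        coefficients=betas,
        shrinkage=shrinkage,
        provenance="fitted",
    )


# ---------------------------------------------------------------------------
# rule assembly from published odds ratios
# ---------------------------------------------------------------------------

def build_prediction_rule(
    odds_ratios: dict,
    reference_X: pd.DataFrame = None,
    prevalence: float = 0.153,
    intercept: float = None,
) -> PredictionRule:
    """Rule from a published odds-ratio map: beta = ln(OR).

    When no intercept is given it is calibrated by root-finding so the mean
    predicted probability on ``reference_X`` equals ``prevalence``.
    """
    for name, orr in odds_ratios.items():
        if orr <= 0:
            raise ValueError(f"non-positive odds ratio for {name!r}")
    betas = {k: float(np.log(v)) for k, v in odds_ratios.items()}
    if intercept is None:
        if reference_X is None:
            raise ValueError("need a reference cohort (or explicit intercept)")
        lp0 = np.zeros(len(reference_X))
        for name, b in betas.items():
            lp0 += b * reference_X[name].to_numpy(dtype=float)

        def mean_prob(a: float) -> float:
            return float(np.mean(1.0 / (1.0 + np.exp(-(a + lp0))))) - prevalence

        intercept = brentq(mean_prob, -60, 60)
    return PredictionRule(
        intercept=float(intercept),
        coefficients=betas,
        shrinkage=1.0,
        provenance="published",
    )
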