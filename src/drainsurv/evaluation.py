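"""Scoring, discrimination, calibration and surveillance summaries.

Patient-level classification uses a strict "greater than" cut-off on the
predicted probability.  All proportion confidence intervals are exact
binomial (Clopper-Pearson, via beta-quantile inversion of the binomial
tails).  Group-level surveillance replaces manual confirmation with the sum
of predicted probabilities: the expected number of infections in a period,
convertible to a rate per 1000 drainage days at risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionReport",
    "SurveillanceSummary",
    "ScoringError",
    "predict_probability",
    "confusion_metrics",
    "confusion_from_counts",
    "clopper_pearson",
    "display_interval",
    "roc_auc",
    "calibration_table",
    "surveillance_summary",
    "workload_reduction",
]


class ScoringError(ValueError):
    """A patient cannot be scored (missing predictor: single-patient
    imputation is not possible)."""


@dataclass
class ConfusionReport:
    cutoff: float
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn)

    @property
    def flagged_fraction(self) -> float:
        return (self.tp + self.fp) / self.n

    def ci(self, metric: str, level: float = 0.95) -> tuple[float, float]:
        x, n = {
            "sensitivity": (self.tp, self.tp + self.fn),
            "specificity": (self.tn, self.tn + self.fp),
            "ppv": (self.tp, self.tp + self.fp),
            "npv": (self.tn, self.tn + self.fn),
        }[metric]
        return clopper_pearson(x, n, level)

    def as_dict(self, percent: bool = True) -> dict:
        scale = 100.0 if percent else 1.0
        out = {"cutoff": self.cutoff, "tp": self.tp, "fp": self.fp,
               "fn": self.fn, "tn": self.tn, "n": self.n,
               "flagged_fraction": round(self.flagged_fraction * scale, 1)}
        for metric in ("sensitivity", "specificity", "ppv", "npv"):
            ci = self.ci(metric)
            out[metric] = round(getattr(self, metric) * scale, 1)
            out[f"{metric}_ci"] = display_interval(ci) if percent else ci
        return out


@dataclass
class SurveillanceSummary:
    period: int
    episodes: int
    days_at_risk: float
    expected_infections: float  # sum of predicted probabilities
    expected_ci: tuple
    observed_infections: int | None = None
    observed_ci: tuple | None = None

    @property
    def predicted_rate(self) -> float:
        """Expected infections per 1000 days at risk."""
        return 1000.0 * self.expected_infections / self.days_at_risk

    @property
    def observed_rate(self):
        if self.observed_infections is None:
            return None
        return 1000.0 * self.observed_infections / self.days_at_risk


def predict_probability(rule, features) -> np.ndarray:
    """Score one or many episodes with a prediction rule.

    Raises :class:`ScoringError` if any required predictor is missing:
    probabilities cannot be computed for patients with missing data.
    """
    X = features.to_frame().T if isinstance(features, pd.Series) else features
    cols = list(rule.coefficients)
    missing_cols = [c for c in cols if c not in X.columns]
    if missing_cols:
        raise ScoringError(f"missing predictor column(s): {missing_cols}")
    if X[cols].isna().any().any():
        bad = X[cols].isna().any()
        raise ScoringError(
            f"missing value(s) in predictor(s) {list(bad.index[bad])}; "
            "single-patient imputation is not possible"
        )
    p = rule.predict(X)
    return float(p[0]) if isinstance(features, pd.Series) else p


def clopper_pearson(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial interval by beta-quantile inversion.

    Lower bound is 0 when x = 0 and upper bound is 1 when x = n.
    """
    if n < 1 or not 0 <= x <= n:
        raise ValueError("require 0 <= x <= n and n >= 1")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    alpha = 1.0 - level
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


def display_interval(ci: tuple[float, float], decimals: int = 1) -> tuple[float, float]:
    """Percent-scale rounding for report display that never prints an
    unattained boundary.

    An exact binomial bound with x < n is strictly below 1; rounding 0.9997
    to 100.0 would display a value the interval does not contain, so bounds
    adjacent to 0 or 100 are nudged one display unit inward instead.
    """
    lo, hi = ci
    step = 10.0 ** (-decimals)
    r_lo = round(lo * 100, decimals)
    r_hi = round(hi * 100, decimals)
    if lo > 0 and r_lo == 0.0:
        r_lo = step
    if hi < 1 and r_hi == 100.0:
        r_hi = 100.0 - step
    return r_lo, r_hi


def confusion_from_counts(tp: int, fp: int, fn: int, tn: int, cutoff: float = np.nan) -> ConfusionReport:
    """Report assembled directly from a printed 2x2 table."""
    for v in (tp, fp, fn, tn):
        if v < 0:
            raise ValueError("counts must be non-negative")
    return ConfusionReport(cutoff=cutoff, tp=tp, fp=fp, fn=fn, tn=tn)


def confusion_metrics(probabilities, truth, cutoff: float) -> ConfusionReport:
    """Classify as positive when P > cutoff (strictly) and tabulate."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(truth)
    if p.size == 0:
        raise ValueError("empty input")
    if p.shape != y.shape:
        raise ValueError("length mismatch")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("truth must be binary")
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie in (0, 1)")
    pred = p > cutoff
    return ConfusionReport(
        cutoff=cutoff,
        tp=int(np.sum(pred & (y == 1))),
        fp=int(np.sum(pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
        tn=int(np.sum(~pred & (y == 0))),
    )


# ---------------------------------------------------------------------------
# discrimination
# ---------------------------------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_variance(scores: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """DeLong AUC and its variance via placement values."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n  # placements of positives
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m  # placements of negatives
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(auc), s10 / m + s01 / n


def roc_auc(probabilities, truth, level: float = 0.95, ci_method: str = "delong"):
    """AUC by the tie-corrected rank statistic; DeLong CI by default."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(truth, dtype=int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both outcome classes required")
    auc, var = _delong_variance(p, y)
    if ci_method == "delong":
        z = stats.norm.ppf(0.5 + level / 2)
        half = z * np.sqrt(var)
        ci = (max(auc - half, 0.0), min(auc + half, 1.0))
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(0)
        boots = []
        for _ in range(1000):
            idx = rng.integers(0, len(y), len(y))
            if 0 < y[idx].sum() < len(idx):
                boots.append(_delong_variance(p[idx], y[idx])[0])
        lo, hi = np.percentile(boots, [100 * (0.5 - level / 2), 100 * (0.5 + level / 2)])
        ci = (float(lo), float(hi))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return auc, ci


def calibration_table(probabilities, truth, bins: int = 10) -> pd.DataFrame:
    """Equal-frequency bins of predicted probability vs observed event rate."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(truth, dtype=float)
    if len(p) < bins:
        raise ValueError("fewer observations than bins")
    df = pd.DataFrame({"p": p, "y": y})
    df["bin"] = pd.qcut(df["p"], q=bins, labels=False, duplicates="drop")
    out = (
        df.groupby("bin")
        .agg(mean_predicted=("p", "mean"), observed=("y", "mean"), n=("y", "size"))
        .reset_index(drop=True)
    )
    return out


# ---------------------------------------------------------------------------
# group-level surveillance
# ---------------------------------------------------------------------------

def _poisson_exact_ci(x: int, level: float = 0.95) -> tuple[float, float]:
    alpha = 1.0 - level
    lo = 0.0 if x == 0 else float(stats.chi2.ppf(alpha / 2, 2 * x) / 2)
    hi = float(stats.chi2.ppf(1 - alpha / 2, 2 * x + 2) / 2)
    return lo, hi


def surveillance_summary(
    probabilities, episodes: pd.DataFrame, truth=None, level: float = 0.95
) -> list[SurveillanceSummary]:
    """Per-period expected (sum of p-hat) and observed infection counts/rates.

    ``episodes`` must carry ``year`` and ``days_at_risk`` columns aligned with
    ``probabilities``.  Expected-count CI is normal with variance
    sum(p(1-p)) (Poisson-binomial); observed-count CI is exact Poisson.
    """
    p = np.asarray(probabilities, dtype=float)
    years = episodes["year"].to_numpy()
    days = episodes["days_at_risk"].to_numpy(dtype=float)
    y = None if truth is None else np.asarray(truth, dtype=int)
    z = stats.norm.ppf(0.5 + level / 2)
    out = []
    for period in sorted(pd.unique(years)):
        mask = years == period
        dar = days[mask].sum()
        if dar <= 0:
            raise ValueError(f"zero days at risk in period {period}")
        expected = float(p[mask].sum())
        sd = float(np.sqrt((p[mask] * (1 - p[mask])).sum()))
        exp_ci = (max(expected - z * sd, 0.0), expected + z * sd)
        obs = obs_ci = None
        if y is not None:
            obs = int(y[mask].sum())
            obs_ci = _poisson_exact_ci(obs, level)
        out.append(
            SurveillanceSummary(
                period=int(period),
                episodes=int(mask.sum()),
                days_at_risk=float(dar),
                expected_infections=expected,
                expected_ci=exp_ci,
                observed_infections=obs,
                observed_ci=obs_ci,
            )
        )
    return out


def workload_reduction(probabilities, cutoff: float) -> float:
    """Fraction of episodes flagged for manual review (P > cutoff)."""
    p = np.asarray(probabilities, dtype=float)
    if p.size == 0:
        raise ValueError("empty input")
    return float(np.mean(p > cutoff))
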