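"""Multiple imputation by chained equations and Rubin's-rule pooling.

Missing predictor values are imputed ten times (default) with chained
equations using predictive-mean matching, which draws imputations from the
observed support — binary columns therefore stay binary and skewed labs stay
positive.  The outcome enters the imputation model as a predictor of
missingness.  Per-imputation coefficient estimates are pooled with Rubin's
rules: the pooled point estimate is the mean, and the total variance adds the
between-imputation component inflated by (1 + 1/m).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.imputation.mice import MICEData

__all__ = ["ImputationSet", "PooledEstimate", "impute", "pool_rubin", "mean_dataset"]


@dataclass
class ImputationSet:
    matrices: list  # m completed DataFrames, identical on observed cells
    seed: int
    method: str = "pmm-chained"

    @property
    def m(self) -> int:
        return len(self.matrices)


@dataclass
class PooledEstimate:
    q_bar: float
    W_bar: float  # mean within-imputation variance
    B: float  # between-imputation variance
    m: int
    names: object = None

    @property
    def T(self) -> float:
        return self.W_bar + (1.0 + 1.0 / self.m) * self.B

    @property
    def se(self) -> float:
        return np.sqrt(self.T)

    @property
    def df(self):
        """Rubin's small-sample degrees of freedom (inf when B = 0)."""
        B = np.asarray(self.B, dtype=float)
        W = np.asarray(self.W_bar, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (1.0 + 1.0 / self.m) * B / W
            df = (self.m - 1) * (1.0 + 1.0 / r) ** 2
        return np.where(B <= 0, np.inf, df)


def impute(
    features: pd.DataFrame,
    m: int = 10,
    seed: int = 0,
    *,
    n_burn: int = 10,
    min_observed_fraction: float = 0.10,
    exclude: tuple = ("patient_id", "admission_id", "year"),
) -> ImputationSet:
    """m completed copies of ``features`` via chained-equation imputation.

    Identifier columns listed in ``exclude`` are carried through unchanged and
    kept out of the imputation model.  Each imputation runs an independent
    chain with ``n_burn`` update sweeps, sub-seeded from ``seed``.
    """
    if m < 2:
        raise ValueError("m must be at least 2")
    id_cols = [c for c in exclude if c in features.columns]
    body = features.drop(columns=id_cols)
    frac = body.notna().mean()
    if (frac == 0).any():
        raise ValueError(f"all-missing column(s): {list(frac.index[frac == 0])}")
    low = frac.index[frac < min_observed_fraction]
    if len(low):
        raise ValueError(
            f"column(s) observed in under {min_observed_fraction:.0%} of episodes: {list(low)}"
        )

    if not body.isna().any().any():
        matrices = [features.copy() for _ in range(m)]
        return ImputationSet(matrices=matrices, seed=seed, method="identity")

    sub_seeds = np.random.SeedSequence(seed).generate_state(m) % (2**31 - 1)
    matrices = []
    for i in range(m):
        # MICEData perturbs via the global NumPy RNG; seed it per chain
        np.random.seed(int(sub_seeds[i]))
        md = MICEData(body.copy())
        md.update_all(n_burn)
        completed = md.data.copy()
        completed.index = features.index
        for c in id_cols:
            completed[c] = features[c]
        matrices.append(completed[features.columns.tolist()])
    return ImputationSet(matrices=matrices, seed=seed)


def pool_rubin(estimates, variances) -> PooledEstimate:
    """Pool per-imputation estimates and their squared standard errors.

    Accepts 1-D (one coefficient) or 2-D (m x p) arrays; vectorised over
    coefficients.
    """
    q = np.asarray(estimates, dtype=float)
    w = np.asarray(variances, dtype=float)
    if q.shape != w.shape:
        raise ValueError("estimates and variances must have equal shapes")
    m = q.shape[0]
    if m < 2:
        raise ValueError("need at least two imputations to pool")
    q_bar = q.mean(axis=0)
    W_bar = w.mean(axis=0)
    B = q.var(axis=0, ddof=1)
    return PooledEstimate(q_bar=q_bar, W_bar=W_bar, B=B, m=m)


def mean_dataset(imp: ImputationSet, binary_cols=()) -> pd.DataFrame:
    """Cell-wise mean across completed matrices; majority vote for binaries
    (ties resolved to the positive class)."""
    stacked = np.stack([mat.to_numpy(dtype=float) for mat in imp.matrices])
    mean = stacked.mean(axis=0)
    out = pd.DataFrame(mean, columns=imp.matrices[0].columns, index=imp.matrices[0].index)
    for c in binary_cols:
        if c in out.columns:
            out[c] = (out[c] >= 0.5).astype(float)
    return out
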