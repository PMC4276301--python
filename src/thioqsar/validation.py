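"""Model-quality statistics for QSAR models.

Internal predictivity is the leave-one-out cross-validated coefficient

    q2 = 1 - Σ(y_i - ŷ_i)² / Σ(y_i - y_mean)²

with ŷ_i the LOO prediction and y_mean the training mean.  External
predictivity (pred_r²) has the same form with the summations over the test
set and y_mean still the *training* mean.  Both are at most 1 and may be
negative.  Acceptability follows the Golbraikh–Tropsha conditions: LOO
Q² > 0.5 and test r² > 0.6, with the through-origin slopes k (observed on
predicted) and k' (predicted on observed) reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationStats",
    "GTReport",
    "q2_stat",
    "pred_r2_stat",
    "rmse_se",
    "f_stat",
    "r2_score",
    "golbraikh_tropsha",
    "residual_table",
]


def _pair(y, yhat):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("observed/predicted vectors differ in length")
    if y.size < 2:
        raise ValueError("need at least 2 points")
    return y, yhat


def q2_stat(y, yhat, y_mean: float) -> float:
    """Cross-validated q² of LOO predictions against the training mean."""
    y, yhat = _pair(y, yhat)
    ss_tot = float(((y - y_mean) ** 2).sum())
    if ss_tot <= 0:
        raise ValueError("constant activities: q2 denominator is zero")
    return 1.0 - float(((y - yhat) ** 2).sum()) / ss_tot


def pred_r2_stat(y_test, yhat_test, y_mean_train: float) -> float:
    """External pred_r² over the test set, baselined on the TRAINING mean."""
    return q2_stat(y_test, yhat_test, y_mean_train)


def rmse_se(y, yhat, denominator: int) -> float:
    """Root-mean-square error with an explicit denominator: the residual
    degrees of freedom n-k-1 for a fitted model, or n for LOO / external
    prediction residuals."""
    y, yhat = _pair(y, yhat)
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return float(np.sqrt(((y - yhat) ** 2).sum() / denominator))


def f_stat(r2: float, n: int, k: int) -> float:
    """Overall regression F statistic, (r²/k) / ((1-r²)/(n-k-1))."""
    if not 0.0 <= r2 <= 1.0:
        raise ValueError("r2 must lie in [0, 1]")
    df = n - k - 1
    if df < 1:
        raise ValueError("n - k - 1 must be at least 1")
    if r2 == 1.0:
        warnings.warn("perfect fit: F statistic is infinite", stacklevel=2)
        return float("inf")
    return (r2 / k) / ((1.0 - r2) / df)


def r2_score(y, yhat) -> float:
    """Squared Pearson correlation between observed and predicted."""
    y, yhat = _pair(y, yhat)
    sy, syh = y.std(), yhat.std()
    if sy == 0 or syh == 0:
        raise ValueError("constant vector: correlation undefined")
    r = float(np.corrcoef(y, yhat)[0, 1])
    return r * r


@dataclass
class GTReport:
    """Golbraikh–Tropsha acceptability report for one external test set."""

    q2_train: float
    r2_test: float
    slope_k: float          # observed regressed on predicted, zero intercept
    slope_k_inverse: float  # predicted regressed on observed, zero intercept
    q2_pass: bool = field(init=False)
    r2_pass: bool = field(init=False)
    accept: bool = field(init=False)

    def __post_init__(self):
        self.q2_pass = self.q2_train > 0.5
        self.r2_pass = self.r2_test > 0.6
        self.accept = self.q2_pass and self.r2_pass

    def as_dict(self) -> dict:
        return {
            "q2_train": self.q2_train,
            "r2_test": self.r2_test,
            "slope_k": self.slope_k,
            "slope_k_inverse": self.slope_k_inverse,
            "q2_pass": self.q2_pass,
            "r2_pass": self.r2_pass,
            "accept": self.accept,
        }


def golbraikh_tropsha(y_obs_test, y_pred_test, q2_train: float) -> GTReport:
    """External acceptability: Q² > 0.5, test r² > 0.6, through-origin slopes."""
    y, yhat = _pair(y_obs_test, y_pred_test)
    if y.size < 3:
        raise ValueError("need at least 3 test points")
    denom_k = float((yhat ** 2).sum())
    denom_ki = float((y ** 2).sum())
    if denom_k == 0 or denom_ki == 0:
        raise ValueError("degenerate test vectors (all zero)")
    return GTReport(
        q2_train=float(q2_train),
        r2_test=r2_score(y, yhat),
        slope_k=float((y * yhat).sum() / denom_k),
        slope_k_inverse=float((y * yhat).sum() / denom_ki),
    )


def residual_table(y_obs, y_pred, ids=None, decimals: int = 4) -> pd.DataFrame:
    """Per-compound observed / predicted / residual table (residual =
    observed − predicted), rounded for report output."""
    y, yhat = _pair(y_obs, y_pred)
    if ids is None:
        ids = list(range(1, y.size + 1))
    return pd.DataFrame(
        {
            "id": list(ids),
            "observed": np.round(y, decimals),
            "predicted": np.round(yhat, decimals),
            "residual": np.round(y - yhat, decimals),
        }
    )


@dataclass
class ValidationStats:
    """Full statistics block of a fitted QSAR model."""

    r2: float
    q2: float
    r2_se: float
    q2_se: float
    f_stat: float
    df: int
    n_train: int
    n_test: int = 0
    pred_r2: float | None = None
    pred_r2_se: float | None = None
    gt_report: GTReport | None = None

    def __post_init__(self):
        if not 0.0 <= self.r2 <= 1.0 or self.q2 > 1.0 + 1e-12:
            raise ValueError("invalid r2/q2")
        if min(self.r2_se, self.q2_se) < 0:
            raise ValueError("standard errors must be nonnegative")

    def as_dict(self) -> dict:
        d = {
            "n_train": self.n_train,
            "n_test": self.n_test,
            "df": self.df,
            "r2": self.r2,
            "q2": self.q2,
            "f_stat": self.f_stat,
            "r2_se": self.r2_se,
            "q2_se": self.q2_se,
            "pred_r2": self.pred_r2,
            "pred_r2_se": self.pred_r2_se,
        }
        if self.gt_report is not None:
            d["golbraikh_tropsha"] = self.gt_report.as_dict()
        return d
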