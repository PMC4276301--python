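"""Linear 2D QSAR models: OLS fitting, leave-one-out q² fitness, variable
selection (stepwise / GA / SA) and y-randomization.

The printed model for this series is a 4-term linear equation on raw
descriptor scales, so the estimator is ordinary least squares (equivalent to
full-rank PLS with all components retained); predictors are not standardized
by default.  Leave-one-out predictions for OLS are computed exactly from a
single fit through the PRESS identity e_(i) = e_i / (1 - h_ii) with h the
leverage, which is algebraically identical to refitting n times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import validation
from .selection import SelectionConfig, SearchResult, run_search
from .validation import ValidationStats

logger = logging.getLogger(__name__)

__all__ = [
    "LinearQSARModel",
    "SelectionConfig",
    "ols_fit",
    "loo_predictions",
    "loo_fitness",
    "select_descriptors",
    "select_sw",
    "select_ga",
    "select_sa",
    "y_randomization",
    "YRandomizationReport",
    "correlation_matrix",
]


@dataclass
class LinearQSARModel:
    """A fitted linear QSAR model with its validation-statistics block."""

    selected: list[str]
    coefficients: np.ndarray
    coefficient_se: np.ndarray
    intercept: float
    intercept_se: float
    stats: ValidationStats
    df: int
    search: SearchResult | None = None

    def __post_init__(self):
        if len(self.coefficients) != len(self.selected):
            raise ValueError("one coefficient per selected descriptor required")
        if self.df < 1:
            raise ValueError("residual degrees of freedom must be >= 1")

    def predict(self, X) -> np.ndarray:
        Xarr = self._matrix(X)
        return self.intercept + Xarr @ self.coefficients

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return X[self.selected].to_numpy(dtype=float)
        if hasattr(X, "df"):  # DescriptorMatrix
            return X.df[self.selected].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def equation(self, decimals: int = 4) -> str:
        """Human-readable equation in the field's conventional layout."""
        terms = []
        for c, se, name in zip(self.coefficients, self.coefficient_se, self.selected):
            sign = "-" if c < 0 else "+"
            terms.append(f"{sign} {abs(c):.{decimals}f} (±{se:.{decimals}f}) {name}")
        eq = " ".join(terms).lstrip("+ ")
        return f"pIC50 = {eq} {'+' if self.intercept >= 0 else '-'} {abs(self.intercept):.{decimals}f}"

    def report(self) -> dict:
        return {
            "selected": list(self.selected),
            "coefficients": [float(c) for c in self.coefficients],
            "coefficient_se": [float(s) for s in self.coefficient_se],
            "intercept": float(self.intercept),
            "intercept_se": float(self.intercept_se),
            "equation": self.equation(),
            "stats": self.stats.as_dict(),
        }


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(X.shape[0]), X])


def _check_rank(A: np.ndarray, names: list[str]) -> None:
    u, s, vt = np.linalg.svd(A, full_matrices=False)
    if s[-1] <= max(A.shape) * np.finfo(float).eps * s[0]:
        v = vt[-1][1:]  # skip intercept component
        culprits = [n for n, w in zip(names, v) if abs(w) > 0.1]
        raise np.linalg.LinAlgError(
            f"rank-deficient design; collinear descriptors: {culprits or names}"
        )


def ols_fit(X, y, names: list[str] | None = None) -> LinearQSARModel:
    """Ordinary least squares with intercept; standard errors from the
    residual variance; r² and F filled through the validation module."""
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if names is None:
        names = [f"x{i}" for i in range(k)]
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 (n={n}, k={k})")
    A = _design(X)
    _check_rank(A, names)
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    df = n - k - 1
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(A.T @ A)
    se = np.sqrt(np.diag(cov))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    r2 = min(max(r2, 0.0), 1.0)
    yhat_loo = loo_predictions(X, y)
    q2 = validation.q2_stat(y, yhat_loo, float(y.mean()))
    stats = ValidationStats(
        r2=r2,
        q2=q2,
        r2_se=validation.rmse_se(y, A @ beta, df),
        q2_se=validation.rmse_se(y, yhat_loo, n),
        f_stat=validation.f_stat(r2, n, k) if r2 < 1.0 else float("inf"),
        df=df,
        n_train=n,
    )
    return LinearQSARModel(
        selected=list(names),
        coefficients=beta[1:],
        coefficient_se=se[1:],
        intercept=float(beta[0]),
        intercept_se=float(se[0]),
        stats=stats,
        df=df,
    )


def loo_predictions(X, y) -> np.ndarray:
    """Exact leave-one-out OLS predictions via the PRESS/leverage identity.

    A fold whose reduced design is singular (leverage 1) falls back to the
    training mean, with a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    A = _design(X)
    Q, _ = np.linalg.qr(A)
    h = (Q ** 2).sum(axis=1)
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    yhat = np.empty_like(y)
    singular = 1.0 - h < 1e-10
    if singular.any():
        logger.warning(
            "LOO: %d fold(s) singular; predicting the training mean", singular.sum()
        )
        yhat[singular] = y.mean()
    ok = ~singular
    yhat[ok] = y[ok] - resid[ok] / (1.0 - h[ok])
    return yhat


def loo_fitness(selected, X, y) -> float:
    """Leave-one-out q² of the OLS model on the selected descriptor columns
    — the fitness criterion driving all three selection engines."""
    if isinstance(X, pd.DataFrame):
        Xsel = X[list(selected)].to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        Xsel = X[:, list(selected)]
    y = np.asarray(y, dtype=float).ravel()
    if len(selected) > len(y) - 2:
        raise ValueError("too many descriptors for LOO fitting")
    yhat = loo_predictions(Xsel, y)
    return validation.q2_stat(y, yhat, float(y.mean()))


def _resolve(X):
    if hasattr(X, "df"):  # DescriptorMatrix
        X = X.df
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{i}" for i in range(X.shape[1])]


def select_descriptors(X, y, cfg: SelectionConfig) -> LinearQSARModel:
    """Run the configured search engine over descriptor subsets and fit the
    final OLS model on the winning subset."""
    Xarr, names = _resolve(X)
    y = np.asarray(y, dtype=float).ravel()
    if cfg.max_terms >= len(y) - 1:
        raise ValueError("max_terms must be < n_train - 1")
    if cfg.standardize:
        sd = Xarr.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xarr = (Xarr - Xarr.mean(axis=0)) / sd

    if cfg.fitness == "loo_q2":
        def fitness(subset):
            return loo_fitness(subset, Xarr, y)
    elif cfg.fitness == "r2":
        def fitness(subset):
            return ols_fit(Xarr[:, list(subset)], y).stats.r2
    else:
        raise ValueError(f"unknown fitness {cfg.fitness!r}")

    result = run_search(Xarr.shape[1], fitness, cfg)
    model = ols_fit(
        Xarr[:, list(result.subset)], y, [names[i] for i in result.subset]
    )
    model.search = result
    return model


def select_sw(X, y, cfg: SelectionConfig) -> LinearQSARModel:
    return select_descriptors(X, y, _force(cfg, "SW"))


def select_ga(X, y, cfg: SelectionConfig) -> LinearQSARModel:
    return select_descriptors(X, y, _force(cfg, "GA"))


def select_sa(X, y, cfg: SelectionConfig) -> LinearQSARModel:
    return select_descriptors(X, y, _force(cfg, "SA"))


def _force(cfg: SelectionConfig, method: str) -> SelectionConfig:
    from dataclasses import replace

    return cfg if cfg.method == method else replace(cfg, method=method)


@dataclass
class YRandomizationReport:
    n_perm: int
    true_r2: float
    permuted_r2: list[float] = field(repr=False, default_factory=list)
    fraction_below: float = 0.0
    confidence_pct: float = 0.0


def y_randomization(
    selected,
    X,
    y,
    n_perm: int = 99,
    seed: int = 0,
    reselect_cfg: SelectionConfig | None = None,
) -> YRandomizationReport:
    """Permutation test of model significance.

    Refits (or, when ``reselect_cfg`` is given, re-selects) on activity
    vectors permuted ``n_perm`` times (identity permutations are redrawn)
    and reports the fraction of permuted-model r² values below the true
    model's r², expressed as a confidence percentage.
    """
    if n_perm < 19:
        raise ValueError("need at least 19 permutations")
    Xarr, names = _resolve(X)
    y = np.asarray(y, dtype=float).ravel()
    cols = [names.index(s) if isinstance(s, str) else int(s) for s in selected]
    true_r2 = ols_fit(Xarr[:, cols], y).stats.r2
    rng = np.random.default_rng(seed)
    permuted = []
    for _ in range(n_perm):
        perm = rng.permutation(len(y))
        while np.array_equal(perm, np.arange(len(y))):
            perm = rng.permutation(len(y))
        yp = y[perm]
        if reselect_cfg is not None:
            from dataclasses import replace

            sub_cfg = replace(reselect_cfg, seed=int(rng.integers(2**31 - 1)))
            permuted.append(select_descriptors(Xarr, yp, sub_cfg).stats.r2)
        else:
            permuted.append(ols_fit(Xarr[:, cols], yp).stats.r2)
    frac = float(np.mean([r < true_r2 for r in permuted]))
    return YRandomizationReport(
        n_perm=n_perm,
        true_r2=true_r2,
        permuted_r2=permuted,
        fraction_below=frac,
        confidence_pct=100.0 * frac,
    )


def correlation_matrix(X, y=None, selected=None, decimals: int = 4) -> pd.DataFrame:
    """Pearson correlation matrix between (optionally selected) descriptors
    and, when given, the activity column — the layout of the published
    inter-parameter correlation table."""
    if hasattr(X, "df"):
        X = X.df
    X = pd.DataFrame(X)
    if selected is not None:
        X = X[list(selected)]
    if y is not None:
        X = pd.concat([pd.Series(np.asarray(y, float), index=X.index, name="pIC50"), X], axis=1)
    return X.corr().round(decimals)
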