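"""Trait regressions: which life-history traits shape bet-hedging?

Germination fractions (model-predicted ESSs or field-observed values)
are logit-transformed and regressed on three standardized life-history
traits: the reproductive intercept alpha1 (reproductive success in dry
years), the log-yield slope beta2 (ability to capitalize on wet years)
and dormant-seed survival s_old.  Standardization puts the predictors
on a common scale so the coefficients are directly comparable effect
sizes; fits are ordinary least squares with adjusted R^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "logit",
    "inverse_logit",
    "standardize",
    "RegressionResult",
    "fit_trait_regression",
    "ess_vs_observed_fit",
]

CANONICAL_PREDICTORS = ["alpha1", "beta2", "s_old"]
ALL_PREDICTORS = ["s_old", "s_new", "alpha1", "beta1", "log_alpha2", "beta2", "a"]


def logit(p):
    """ln(p / (1 - p)) for p strictly inside (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1) or not np.all(np.isfinite(p)):
        raise ValueError("logit requires values strictly inside (0, 1)")
    out = np.log(p / (1.0 - p))
    return float(out) if out.ndim == 0 else out


def inverse_logit(x):
    """Logistic function, inverse of :func:`logit`."""
    x = np.asarray(x, dtype=float)
    out = 1.0 / (1.0 + np.exp(-x))
    return float(out) if out.ndim == 0 else out


def standardize(values):
    """(x - mean) / sd with the n-1 sample standard deviation."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to standardize")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize values with zero variance")
    return (x - x.mean()) / sd


@dataclass
class RegressionResult:
    """An OLS fit of logit germination fractions on traits."""

    intercept: float
    coefs: dict[str, float]
    adjusted_r2: float
    r2: float
    residuals: np.ndarray
    n: int
    extra: dict | None = None


def _adjusted_r2(r2: float, n: int, p: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def fit_trait_regression(
    table: pd.DataFrame,
    response: str = "response",
    predictors: list[str] | None = None,
    response_is_logit: bool = False,
) -> RegressionResult:
    """Regress logit germination fractions on standardized traits.

    ``table`` carries one row per species with trait columns and a
    response column of fractions in (0, 1) (or already-logit values
    with ``response_is_logit=True``).  Default predictors are the
    canonical three: alpha1, beta2, s_old.
    """
    predictors = CANONICAL_PREDICTORS if predictors is None else predictors
    missing = [c for c in predictors + [response] if c not in table.columns]
    if missing:
        raise ValueError(f"trait table missing columns: {missing}")
    n = len(table)
    if n < len(predictors) + 2:
        raise ValueError(f"need at least {len(predictors) + 2} species, got {n}")
    y = table[response].to_numpy(float)
    if not response_is_logit:
        y = logit(y)
    Z = np.column_stack([standardize(table[c].to_numpy(float)) for c in predictors])
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        import warnings

        warnings.warn("collinear predictors: design matrix is rank-deficient", stacklevel=2)
    X = sm.add_constant(Z)
    res = sm.OLS(y, X).fit()
    r2 = float(res.rsquared)
    return RegressionResult(
        intercept=float(res.params[0]),
        coefs={c: float(b) for c, b in zip(predictors, res.params[1:])},
        adjusted_r2=_adjusted_r2(r2, n, len(predictors)),
        r2=r2,
        residuals=np.asarray(res.resid),
        n=n,
    )


def ess_vs_observed_fit(predicted, observed) -> RegressionResult:
    """Simple logit-logit regression of observed fractions on predicted.

    OLS of logit(observed) on logit(predicted); reports adjusted R^2
    (one predictor) plus slope/intercept and a count of species whose
    predicted fraction exceeds the observed one.
    """
    xp = logit(np.atleast_1d(predicted))
    yo = logit(np.atleast_1d(observed))
    if xp.shape != yo.shape:
        raise ValueError("predicted and observed must be paired")
    n = xp.size
    if n < 3:
        raise ValueError("need at least 3 species")
    X = sm.add_constant(xp)
    res = sm.OLS(yo, X).fit()
    r2 = float(res.rsquared)
    return RegressionResult(
        intercept=float(res.params[0]),
        coefs={"logit_predicted": float(res.params[1])},
        adjusted_r2=_adjusted_r2(r2, n, 1),
        r2=r2,
        residuals=np.asarray(res.resid),
        n=n,
        extra={"n_overestimated": int(np.sum(np.asarray(predicted) > np.asarray(observed)))},
    )
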