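"""Partial correlations, composites, regressions, and RMSEA-based power.

Covers the association layer of the analysis: within- and cross-paradigm
partial correlations controlling age and IQ, per-paradigm composite
z-scores, descriptive moments, OLS regressions of factor scores on the
paradigm-independent measures (with Cohen's f effect sizes and VIF
collinearity checks), and the a-priori sample size for an RMSEA-based
test of model fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .latent import INDICATORS

__all__ = [
    "partial_correlation",
    "partial_correlation_matrix",
    "composite_scores",
    "descriptives",
    "RegressionResult",
    "regress_factor_scores",
    "vif",
    "required_n_rmsea",
]

PARADIGM_INDICATORS: dict[str, tuple[str, str, str]] = {
    "SquareTown": ("squaretown_efficiency", "squaretown_map_r2", "squaretown_pointing"),
    "VirtualSILCton": ("silcton_map_r2", "silcton_within_pointing", "silcton_between_pointing"),
    "TempleTour": ("temple_map_r2", "temple_pointing", "temple_efficiency"),
}


class AssociationError(ValueError):
    pass


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ coef


def partial_correlation(x, y, covariates=None) -> tuple[float, float]:
    """Pearson correlation of x and y after partialling out the covariates.

    Both variables are residualized on the covariates (plus an intercept)
    by least squares; the p-value is two-sided from a t distribution with
    n - 2 - k degrees of freedom.  With no covariates this is the plain
    Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.size == 0:
            C = np.empty((n, 0))
        elif C.ndim == 1:
            C = C[:, None]
    k = C.shape[1]
    if n <= k + 2:
        raise AssociationError("need n > k + 2 observations")
    Z = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise AssociationError("collinear covariates")
    rx = _residualize(x, Z)
    ry = _residualize(y, Z)
    denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    if denom == 0:
        raise AssociationError("zero residual variance")
    r = float(np.clip(np.sum(rx * ry) / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return r, float(p)


def partial_correlation_matrix(
    table: pd.DataFrame, columns: list[str], control: tuple[str, ...] = ("age", "kbit_iq")
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise partial correlations (and p-values) among ``columns``."""
    C = table[list(control)].to_numpy(dtype=float) if control else None
    k = len(columns)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            rij, pij = partial_correlation(table[columns[i]], table[columns[j]], C)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    return (
        pd.DataFrame(r, index=columns, columns=columns),
        pd.DataFrame(p, index=columns, columns=columns),
    )


def composite_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Per-paradigm composite: mean of its three z-standardized indicators."""
    out = {}
    for paradigm, cols in PARADIGM_INDICATORS.items():
        out[paradigm] = table[list(cols)].mean(axis=1)
    return pd.DataFrame(out, index=table.index)


def descriptives(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Sample moments: mean, sd, min, max, skewness and excess kurtosis.

    Skewness is ``m3 / m2**1.5`` and kurtosis is the excess
    ``m4 / m2**2 - 3`` (zero for a normal distribution).
    """
    cols = columns or [c for c in table.columns if c in INDICATORS]
    rows = []
    for c in cols:
        v = table[c].to_numpy(dtype=float)
        if v.size < 4:
            raise AssociationError("need n >= 4 for moments")
        if np.allclose(v.var(), 0.0):
            raise AssociationError(f"degenerate (constant) column {c!r}")
        rows.append(
            {
                "measure": c,
                "mean": v.mean(),
                "sd": v.std(ddof=1),
                "min": v.min(),
                "max": v.max(),
                "skewness": float(scipy.stats.skew(v)),
                "kurtosis": float(scipy.stats.kurtosis(v)),
            }
        )
    return pd.DataFrame(rows).set_index("measure")


@dataclass
class RegressionResult:
    """OLS summary for one factor-score regression."""

    outcome: str
    beta: pd.Series
    se: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p_values: pd.Series
    r2: float
    adj_r2: float
    f_partial: pd.Series
    vif: pd.Series


def vif(X: pd.DataFrame | np.ndarray) -> pd.Series:
    """Variance inflation factor of each predictor regressed on the others."""
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        A = X.to_numpy(dtype=float)
    else:
        A = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(A.shape[1])]
    if A.shape[1] < 2:
        raise AssociationError("need >= 2 predictors")
    out = []
    for j in range(A.shape[1]):
        others = np.column_stack([np.ones(A.shape[0]), np.delete(A, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, A[:, j], rcond=None)
        resid = A[:, j] - others @ coef
        sst = np.sum((A[:, j] - A[:, j].mean()) ** 2)
        r2j = 1.0 - np.sum(resid**2) / sst if sst > 0 else 1.0
        out.append(np.inf if r2j >= 1.0 - 1e-12 else 1.0 / (1.0 - r2j))
    return pd.Series(out, index=names)


def regress_factor_scores(
    outcome: pd.Series | np.ndarray,
    predictors: pd.DataFrame,
    outcome_name: str = "factor_score",
) -> RegressionResult:
    """OLS of a factor score on the paradigm-independent predictors.

    Continuous variables are expected z-standardized (gender stays 0/1),
    so slopes read as standardized betas.  Cohen's f per predictor is
    ``sqrt((R2_full - R2_without_j) / (1 - R2_full))``; conventional
    bands: > 0.40 large, > 0.25 medium, > 0.10 small.
    """
    y = np.asarray(outcome, dtype=float)
    X = predictors.astype(float)
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise AssociationError("rank-deficient design matrix")
    res = sm.OLS(y, design).fit()
    ci = res.conf_int(alpha=0.05)
    r2_full = res.rsquared
    f_part = {}
    for col in X.columns:
        reduced = sm.add_constant(X.drop(columns=[col]), has_constant="add")
        r2_red = sm.OLS(y, reduced).fit().rsquared
        f2 = max(r2_full - r2_red, 0.0) / max(1.0 - r2_full, 1e-12)
        f_part[col] = float(np.sqrt(f2))
    return RegressionResult(
        outcome=outcome_name,
        beta=res.params,
        se=res.bse,
        ci_low=ci[0],
        ci_high=ci[1],
        p_values=res.pvalues,
        r2=float(r2_full),
        adj_r2=float(res.rsquared_adj),
        f_partial=pd.Series(f_part),
        vif=vif(X),
    )


def rmsea_power(n: int, df: int, epsilon: float, alpha: float, convention: str = "n_minus_1") -> float:
    """Power of the exact-fit chi2 test against misfit RMSEA = epsilon."""
    crit = scipy.stats.chi2.ppf(1.0 - alpha, df)
    mult = (n - 1) if convention == "n_minus_1" else n
    lam = mult * df * epsilon**2
    return float(scipy.stats.ncx2.sf(crit, df, lam))


def required_n_rmsea(
    epsilon: float,
    alpha: float = 0.05,
    power: float = 0.80,
    df: int = 8,
    convention: str = "n_minus_1",
    n_max: int = 10_000_000,
) -> int:
    """Smallest N giving the target power for an RMSEA-based a-priori test.

    The test detects misfit of size ``epsilon`` (RMSEA units) via the
    noncentral chi-square distribution of the ML test statistic with
    noncentrality ``(N - 1) * df * epsilon**2`` (the ``n`` convention uses
    ``N * df * epsilon**2``).  Power is monotone in N, so the minimum is
    found by bisection.
    """
    if not (epsilon > 0 and 0 < alpha < 1 and 0 < power < 1 and df >= 1):
        raise AssociationError("invalid power query")
    lo, hi = 2, n_max
    if rmsea_power(hi, df, epsilon, alpha, convention) < power:
        raise AssociationError("target power unreachable below n_max")
    if rmsea_power(lo, df, epsilon, alpha, convention) >= power:
        return lo
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if rmsea_power(mid, df, epsilon, alpha, convention) >= power:
            hi = mid
        else:
            lo = mid
    return hi
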