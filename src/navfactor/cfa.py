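"""Confirmatory factor analysis by maximum-likelihood covariance fitting.

Fits the hypothesized measurement models for the nine navigation
indicators by minimizing the Wishart ML discrepancy

    F(theta) = ln|Sigma(theta)| - ln|S| + tr(S Sigma(theta)^-1) - p

over free loadings, factor correlations and residual variances, with
factor variances fixed at 1 (so the solution is reported in standardized
form).  The covariate model adds age, gender and IQ as exogenous
correlated predictors with free paths into every factor; its factor
disturbance variances are fixed at 1 for identification and the solution
is standardized afterwards.

chi2 = (N - 1) * F_min; CFI compares against the independence baseline
Sigma = diag(S); RMSEA = sqrt(max(chi2 - df, 0) / (df * N)).  Improper
solutions (negative residual variances, non-positive-definite latent
correlation) are flagged, never silently accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .latent import COVARIATES, FACTORS, INDICATORS

__all__ = [
    "CfaModelSpec",
    "CfaFit",
    "build_indicator_table",
    "candidate_model_specs",
    "fit_cfa",
    "fit_cfa_cov",
    "baseline_model",
    "fit_indices",
    "factor_scores",
    "compare_models",
]

_BIG = 1e10


class CfaError(ValueError):
    pass


@dataclass
class CfaModelSpec:
    """A named confirmatory loading pattern (one factor per indicator)."""

    name: str
    loadings: dict[str, str]  # indicator -> factor
    covariates: tuple[str, ...] = ()

    @property
    def factor_names(self) -> tuple[str, ...]:
        seen: list[str] = []
        for fac in self.loadings.values():
            if fac not in seen:
                seen.append(fac)
        return tuple(seen)

    @property
    def indicator_names(self) -> tuple[str, ...]:
        return tuple(self.loadings)


@dataclass
class CfaFit:
    """Result of one maximum-likelihood CFA fit."""

    spec: CfaModelSpec
    converged: bool
    proper_solution: bool
    fmin: float
    chi2: float
    df: int
    p_value: float
    cfi: float
    rmsea: float
    chi2_baseline: float
    df_baseline: int
    n: int
    loadings_std: pd.Series
    phi_std: pd.DataFrame
    residual_variances_std: pd.Series
    gamma_std: pd.DataFrame | None = None
    # unstandardized internals, needed for factor scores
    lam_raw: np.ndarray | None = None
    phi_raw: np.ndarray | None = None
    theta_raw: np.ndarray | None = None
    sigma: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# table preparation


def build_indicator_table(scored: pd.DataFrame) -> pd.DataFrame:
    """Z-standardize the indicator and continuous covariate columns.

    Uses the sample standard deviation (denominator n - 1); gender is
    passed through as its 0/1 coding.  Raises on zero-variance columns.
    """
    if len(scored) < 3:
        raise CfaError("need at least 3 participants")
    out = scored.copy()
    for col in out.columns:
        if col in ("id", "gender") or not pd.api.types.is_numeric_dtype(out[col]):
            continue
        sd = out[col].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise CfaError(f"zero-variance column {col!r}")
        out[col] = (out[col] - out[col].mean()) / sd
    if out.select_dtypes("number").isna().any().any():
        raise CfaError("missing values in indicator table")
    return out


# ---------------------------------------------------------------------------
# the six hypothesized models


def candidate_model_specs() -> list[CfaModelSpec]:
    """The six hypothesized models for the nine navigation indicators."""
    st = ["squaretown_efficiency", "squaretown_map_r2", "squaretown_pointing"]
    si = ["silcton_map_r2", "silcton_within_pointing", "silcton_between_pointing"]
    tt = ["temple_map_r2", "temple_pointing", "temple_efficiency"]
    paradigm = {i: "SquareTown" for i in st}
    paradigm |= {i: "VirtualSILCton" for i in si}
    paradigm |= {i: "TempleTour" for i in tt}
    specs = [
        CfaModelSpec("unifactorial", {i: "Navigation" for i in INDICATORS}),
        CfaModelSpec(
            "bifactorial_layout",
            {i: ("Gridded" if i in st + tt else "NonGridded") for i in INDICATORS},
        ),
        CfaModelSpec(
            "bifactorial_modality",
            {i: ("Virtual" if i in st + si else "RealWorld") for i in INDICATORS},
        ),
        CfaModelSpec(
            "trifactorial_task",
            {
                i: (
                    "Map"
                    if i.endswith("map_r2")
                    else "Pointing" if "pointing" in i else "Efficiency"
                )
                for i in INDICATORS
            },
        ),
        CfaModelSpec("trifactorial_paradigm", dict(paradigm)),
        CfaModelSpec(
            "trifactorial_paradigm_covariates", dict(paradigm), covariates=COVARIATES
        ),
    ]
    return specs


# ---------------------------------------------------------------------------
# parameter packing


def _tri_indices(k: int) -> tuple[np.ndarray, np.ndarray]:
    return np.tril_indices(k, k=-1)


class _PureCfa:
    """F_ML and analytic gradient for a first-order CFA, factor variances 1."""

    def __init__(self, spec: CfaModelSpec, S: np.ndarray):
        self.spec = spec
        self.S = S
        self.p = S.shape[0]
        self.k = len(spec.factor_names)
        self.fac_of = np.array(
            [spec.factor_names.index(f) for f in spec.loadings.values()]
        )
        self.n_lam = self.p
        self.n_phi = self.k * (self.k - 1) // 2
        self.nparam = self.n_lam + self.n_phi + self.p
        sign, self.logdet_s = np.linalg.slogdet(S)
        if sign <= 0:
            raise CfaError("sample covariance matrix is not positive definite")

    def unpack(self, theta: np.ndarray):
        lam_v = theta[: self.n_lam]
        phi_v = theta[self.n_lam : self.n_lam + self.n_phi]
        th_v = theta[self.n_lam + self.n_phi :]
        lam = np.zeros((self.p, self.k))
        lam[np.arange(self.p), self.fac_of] = lam_v
        phi = np.eye(self.k)
        il, jl = _tri_indices(self.k)
        phi[il, jl] = phi_v
        phi[jl, il] = phi_v
        return lam, phi, th_v

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        lam, phi, th = self.unpack(theta)
        return lam @ phi @ lam.T + np.diag(th)

    def value(self, theta: np.ndarray) -> float:
        return self.value_grad(theta)[0]

    def value_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        lam, phi, th = self.unpack(theta)
        sigma = lam @ phi @ lam.T + np.diag(th)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return _BIG, np.zeros_like(theta)
        sinv = np.linalg.inv(sigma)
        f = logdet - self.logdet_s + float(np.trace(self.S @ sinv)) - self.p
        # dF/dSigma = Sigma^-1 (Sigma - S) Sigma^-1
        w = sinv @ (sigma - self.S) @ sinv
        g_lam_full = 2.0 * w @ lam @ phi  # p x k
        g_lam = g_lam_full[np.arange(self.p), self.fac_of]
        lwl = lam.T @ w @ lam
        il, jl = _tri_indices(self.k)
        g_phi = 2.0 * lwl[il, jl]
        g_th = np.diag(w)
        return f, np.concatenate([g_lam, g_phi, g_th])

    def start(self, rng: np.random.Generator, jitter: float) -> np.ndarray:
        s = np.concatenate(
            [
                np.full(self.n_lam, 0.6),
                np.full(self.n_phi, 0.4),
                np.full(self.p, 0.6),
            ]
        )
        return s + jitter * rng.uniform(-0.15, 0.15, size=s.size)

    def bounds(self):
        return (
            [(-3.0, 3.0)] * self.n_lam
            + [(-0.999, 0.999)] * self.n_phi
            + [(-1.0, 10.0)] * self.p
        )


class _CovariateCfa:
    """F_ML for a CFA whose factors are regressed on exogenous covariates.

    Observed vector z = (y, x): y = Lambda eta + eps, eta = Gamma x + zeta,
    var(zeta) fixed to the identity apart from free off-diagonal
    covariances.  Gradient is numerical (the model is fitted once per
    pipeline run, not in simulation loops).
    """

    def __init__(self, spec: CfaModelSpec, S: np.ndarray):
        self.spec = spec
        self.S = S
        self.p_y = len(spec.loadings)
        self.n_x = len(spec.covariates)
        self.p = self.p_y + self.n_x
        self.k = len(spec.factor_names)
        self.fac_of = np.array(
            [spec.factor_names.index(f) for f in spec.loadings.values()]
        )
        self.n_phi_x = self.n_x * (self.n_x + 1) // 2
        self.n_psi = self.k * (self.k - 1) // 2
        self.nparam = self.p_y + self.p_y + self.k * self.n_x + self.n_phi_x + self.n_psi
        sign, self.logdet_s = np.linalg.slogdet(S)
        if sign <= 0:
            raise CfaError("sample covariance matrix is not positive definite")

    def unpack(self, theta: np.ndarray):
        i = 0
        lam_v = theta[i : i + self.p_y]
        i += self.p_y
        gamma = theta[i : i + self.k * self.n_x].reshape(self.k, self.n_x)
        i += self.k * self.n_x
        phi_x = np.zeros((self.n_x, self.n_x))
        iu = np.triu_indices(self.n_x)
        phi_x[iu] = theta[i : i + self.n_phi_x]
        phi_x = phi_x + phi_x.T - np.diag(np.diag(phi_x))
        i += self.n_phi_x
        psi = np.eye(self.k)
        il, jl = _tri_indices(self.k)
        psi[il, jl] = theta[i : i + self.n_psi]
        psi[jl, il] = theta[i : i + self.n_psi]
        i += self.n_psi
        th_v = theta[i:]
        lam = np.zeros((self.p_y, self.k))
        lam[np.arange(self.p_y), self.fac_of] = lam_v
        return lam, gamma, phi_x, psi, th_v

    def implied(self, theta: np.ndarray):
        lam, gamma, phi_x, psi, th = self.unpack(theta)
        phi_f = gamma @ phi_x @ gamma.T + psi  # factor covariance
        sigma = np.zeros((self.p, self.p))
        sigma[: self.p_y, : self.p_y] = lam @ phi_f @ lam.T + np.diag(th)
        syx = lam @ gamma @ phi_x
        sigma[: self.p_y, self.p_y :] = syx
        sigma[self.p_y :, : self.p_y] = syx.T
        sigma[self.p_y :, self.p_y :] = phi_x
        return sigma, lam, gamma, phi_x, psi, th, phi_f

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        return self.implied(theta)[0]

    def value(self, theta: np.ndarray) -> float:
        sigma = self.sigma(theta)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return _BIG
        sinv = np.linalg.inv(sigma)
        return logdet - self.logdet_s + float(np.trace(self.S @ sinv)) - self.p

    def start(self, rng: np.random.Generator, jitter: float) -> np.ndarray:
        s_xx = self.S[self.p_y :, self.p_y :]
        s = np.concatenate(
            [
                np.full(self.p_y, 0.6),
                np.full(self.k * self.n_x, 0.1),
                s_xx[np.triu_indices(self.n_x)],
                np.full(self.n_psi, 0.3),
                np.full(self.p_y, 0.6),
            ]
        )
        return s + jitter * rng.uniform(-0.1, 0.1, size=s.size)

    def bounds(self):
        iu = np.triu_indices(self.n_x)
        b_phi_x = [
            ((1e-6, None) if i == j else (None, None)) for i, j in zip(*iu)
        ]
        return (
            [(-3.0, 3.0)] * self.p_y
            + [(-5.0, 5.0)] * (self.k * self.n_x)
            + b_phi_x
            + [(-5.0, 5.0)] * self.n_psi
            + [(-1.0, 10.0)] * self.p_y
        )


# ---------------------------------------------------------------------------
# fitting


def _cov2corr(a: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(a))
    return a / np.outer(d, d)


def fit_cfa_cov(
    spec: CfaModelSpec,
    S: np.ndarray,
    n: int,
    n_starts: int = 3,
    seed: int = 0,
) -> CfaFit:
    """Fit a model to a sample covariance matrix ``S`` computed from ``n`` rows.

    ``S`` must be ordered indicators-first, covariates last (when the spec
    has covariates).  Runs ``n_starts`` jittered quasi-Newton starts and
    keeps the best converged solution.
    """
    rng = np.random.default_rng(seed)
    prob = _CovariateCfa(spec, S) if spec.covariates else _PureCfa(spec, S)
    p = S.shape[0]
    candidates = []
    for s_idx in range(n_starts):
        x0 = prob.start(rng, jitter=float(s_idx > 0))
        if isinstance(prob, _PureCfa):
            res = scipy.optimize.minimize(
                prob.value_grad,
                x0,
                jac=True,
                method="L-BFGS-B",
                bounds=prob.bounds(),
                options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-8},
            )
        else:
            res = scipy.optimize.minimize(
                prob.value,
                x0,
                method="L-BFGS-B",
                bounds=prob.bounds(),
                options={"maxiter": 5000, "ftol": 1e-13},
            )
        # a failed line search can report a bogus objective: re-evaluate at
        # the returned point and prefer cleanly converged starts
        fval = prob.value(res.x)
        candidates.append((0 if res.success else 1, fval, res))
    failed, fmin_val, best = min(candidates, key=lambda t: (t[0], t[1]))
    converged = failed == 0 and np.isfinite(fmin_val) and fmin_val < _BIG / 2
    best.fun = fmin_val
    theta = best.x

    # assemble the standardized solution
    if isinstance(prob, _PureCfa):
        lam, phi_f, th = prob.unpack(theta)
        gamma_std = None
        sigma = prob.sigma(theta)
        lam_raw, theta_raw = lam, th
    else:
        sigma, lam, gamma, phi_x, psi, th, phi_f = prob.implied(theta)
        sd_f = np.sqrt(np.clip(np.diag(phi_f), 1e-12, None))
        sd_x = np.sqrt(np.clip(np.diag(phi_x), 1e-12, None))
        gamma_std = pd.DataFrame(
            gamma * sd_x[None, :] / sd_f[:, None],
            index=list(spec.factor_names),
            columns=list(spec.covariates),
        )
        lam_raw, theta_raw = lam, th

    sd_y = np.sqrt(np.clip(np.diag(sigma)[: lam.shape[0]], 1e-12, None))
    sd_f = np.sqrt(np.clip(np.diag(phi_f), 1e-12, None))
    lam_std = np.array(
        [lam[i, prob.fac_of[i]] * sd_f[prob.fac_of[i]] / sd_y[i] for i in range(lam.shape[0])]
    )
    resid_std = 1.0 - lam_std**2
    phi_corr = _cov2corr(phi_f)

    q = prob.nparam
    df = p * (p + 1) // 2 - q
    chi2 = max((n - 1) * best.fun, 0.0)
    chi2_b, df_b = baseline_model_cov(S, n)
    cfi, rmsea, p_value = fit_indices(chi2, df, chi2_b, df_b, n)

    heywood = bool(np.any(theta_raw < -1e-8)) or bool(np.any(resid_std < -1e-8))
    phi_pd = bool(np.linalg.eigvalsh(phi_corr).min() > 1e-10) and bool(
        np.all(np.abs(phi_corr[~np.eye(len(phi_corr), dtype=bool)]) <= 1 + 1e-8)
    )
    proper = converged and not heywood and phi_pd

    ind = list(spec.loadings)
    facs = list(spec.factor_names)
    return CfaFit(
        spec=spec,
        converged=converged,
        proper_solution=proper,
        fmin=float(best.fun),
        chi2=float(chi2),
        df=int(df),
        p_value=float(p_value),
        cfi=float(cfi),
        rmsea=float(rmsea),
        chi2_baseline=float(chi2_b),
        df_baseline=int(df_b),
        n=int(n),
        loadings_std=pd.Series(lam_std, index=ind),
        phi_std=pd.DataFrame(phi_corr, index=facs, columns=facs),
        residual_variances_std=pd.Series(resid_std, index=ind),
        gamma_std=gamma_std,
        lam_raw=lam_raw,
        phi_raw=phi_f,
        theta_raw=np.asarray(theta_raw),
        sigma=sigma,
        diagnostics={"heywood": heywood, "phi_pd": phi_pd, "message": str(best.message)},
    )


def fit_cfa(
    spec: CfaModelSpec, table: pd.DataFrame, n_starts: int = 3, seed: int = 0
) -> CfaFit:
    """Fit a hypothesized model to a (standardized) indicator table."""
    cols = list(spec.loadings) + list(spec.covariates)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise CfaError(f"table lacks columns {missing}")
    n = len(table)
    if n <= len(cols):
        raise CfaError("need more participants than observed variables")
    X = table[cols].to_numpy(dtype=float)
    S = np.cov(X, rowvar=False, ddof=1)
    return fit_cfa_cov(spec, S, n, n_starts=n_starts, seed=seed)


# ---------------------------------------------------------------------------
# fit indices


def baseline_model_cov(S: np.ndarray, n: int) -> tuple[float, int]:
    """Independence-baseline chi2 and df from a sample covariance matrix."""
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        raise CfaError("singular sample covariance matrix")
    f_b = float(np.sum(np.log(np.diag(S))) - logdet)
    p = S.shape[0]
    return (n - 1) * f_b, p * (p - 1) // 2


def baseline_model(table: pd.DataFrame, columns: list[str] | None = None) -> tuple[float, int]:
    """Independence-baseline chi2 and df for the given table columns."""
    cols = columns or [c for c in table.columns if c in INDICATORS]
    S = np.cov(table[cols].to_numpy(dtype=float), rowvar=False, ddof=1)
    return baseline_model_cov(S, len(table))


def fit_indices(
    chi2: float, df: int, chi2_b: float, df_b: int, n: int
) -> tuple[float, float, float]:
    """(CFI, RMSEA, p) from the model and baseline test statistics."""
    if df == 0:
        return 1.0, 0.0, 1.0
    excess = max(chi2 - df, 0.0)
    denom = max(chi2_b - df_b, excess, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - excess / denom
    rmsea = float(np.sqrt(excess / (df * n)))
    p_value = float(scipy.stats.chi2.sf(chi2, df))
    return float(np.clip(cfi, 0.0, 1.0)), rmsea, p_value


# ---------------------------------------------------------------------------
# factor scores and model comparison


def factor_scores(fit: CfaFit, table: pd.DataFrame) -> pd.DataFrame:
    """Regression-method (Thurstone) factor scores, one column per factor.

    Scores are ``(X - mean) Sigma^-1 Lambda Phi`` using the fitted
    indicator-block parameters; they estimate each participant's standing
    on the latent factors relative to the sample.
    """
    if not (fit.converged and fit.proper_solution):
        raise CfaError(
            f"refusing factor scores from an improper or non-converged fit "
            f"({fit.diagnostics})"
        )
    ind = list(fit.spec.loadings)
    X = table[ind].to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    p_y = len(ind)
    sigma_yy = fit.sigma[:p_y, :p_y]
    weights = np.linalg.solve(sigma_yy, fit.lam_raw @ fit.phi_raw)
    scores = Xc @ weights
    return pd.DataFrame(scores, columns=list(fit.spec.factor_names), index=table.index)


def compare_models(fits: list[CfaFit]) -> pd.DataFrame:
    """Rank fitted models: proper solutions first, then CFI desc, RMSEA asc."""
    if not fits:
        raise CfaError("no fits to compare")
    rows = [
        {
            "model": f.spec.name,
            "chi2": f.chi2,
            "df": f.df,
            "p_value": f.p_value,
            "cfi": f.cfi,
            "rmsea": f.rmsea,
            "converged": f.converged,
            "proper_solution": f.proper_solution,
        }
        for f in fits
    ]
    out = pd.DataFrame(rows)
    out = out.sort_values(
        by=["proper_solution", "cfi", "rmsea"], ascending=[False, False, True]
    ).reset_index(drop=True)
    out.index = pd.RangeIndex(1, len(out) + 1, name="rank")
    return out
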