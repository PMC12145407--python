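"""Independent EM-algorithm reference fit for confirmatory factor models.

Maximizes the same Wishart likelihood as the package's quasi-Newton
discrepancy minimization, but by a completely different route: the
expectation-maximization algorithm for the normal common-factor model,
under marker identification (first loading per factor fixed to 1, factor
covariance free).  Because the two identifications parameterize the same
model, the minimized discrepancy (hence chi-square) and the standardized
solution must agree; this serves as the oracle for the CFA fitting path.

Only pure measurement models (no covariates) are supported.
"""

from __future__ import annotations

import numpy as np


def em_fit_cfa(
    loadings: dict[str, str],
    S: np.ndarray,
    max_iter: int = 20000,
    tol: float = 1e-12,
) -> dict:
    """EM fit of a one-factor-per-indicator CFA to a covariance matrix.

    Returns the minimized ML discrepancy and the standardized loadings and
    factor correlation matrix.
    """
    indicators = list(loadings)
    factors = []
    for f in loadings.values():
        if f not in factors:
            factors.append(f)
    p, k = len(indicators), len(factors)
    fac_of = np.array([factors.index(loadings[i]) for i in indicators])
    marker = np.full(k, -1, dtype=int)
    for i in range(p):
        if marker[fac_of[i]] < 0:
            marker[fac_of[i]] = i

    # marker-identified starting values
    lam = np.zeros((p, k))
    lam[np.arange(p), fac_of] = 1.0
    phi = np.eye(k) * np.mean(np.diag(S)) * 0.5
    theta = np.diag(S) * 0.5

    sign, logdet_s = np.linalg.slogdet(S)
    assert sign > 0

    def discrepancy(lam, phi, theta):
        sigma = lam @ phi @ lam.T + np.diag(theta)
        sgn, logdet = np.linalg.slogdet(sigma)
        if sgn <= 0:
            return np.inf
        return logdet - logdet_s + np.trace(S @ np.linalg.inv(sigma)) - p

    prev = discrepancy(lam, phi, theta)
    for _ in range(max_iter):
        sigma = lam @ phi @ lam.T + np.diag(theta)
        sinv = np.linalg.inv(sigma)
        A = phi @ lam.T @ sinv                    # k x p regression of f on x
        Cfx = A @ S                               # E[f x']
        Cff = A @ S @ A.T + (phi - A @ lam @ phi)  # E[f f']
        new_lam = lam.copy()
        new_theta = theta.copy()
        for i in range(p):
            j = fac_of[i]
            if i != marker[j]:
                new_lam[i, j] = Cfx[j, i] / Cff[j, j]
            new_theta[i] = S[i, i] - 2.0 * new_lam[i, j] * Cfx[j, i] + new_lam[i, j] ** 2 * Cff[j, j]
        new_phi = (Cff + Cff.T) / 2.0
        lam, phi, theta = new_lam, new_phi, np.maximum(new_theta, 1e-10)
        cur = discrepancy(lam, phi, theta)
        if abs(prev - cur) < tol:
            prev = cur
            break
        prev = cur

    # standardize: factor sd from phi, indicator sd from implied sigma
    sigma = lam @ phi @ lam.T + np.diag(theta)
    sd_f = np.sqrt(np.diag(phi))
    sd_x = np.sqrt(np.diag(sigma))
    lam_std = np.array([lam[i, fac_of[i]] * sd_f[fac_of[i]] / sd_x[i] for i in range(p)])
    phi_std = phi / np.outer(sd_f, sd_f)
    return {
        "fmin": float(prev),
        "loadings_std": dict(zip(indicators, lam_std)),
        "phi_std": phi_std,
        "factors": factors,
    }
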