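"""Latent trifactor specification for multi-paradigm navigation ability.

The measurement model is a standard confirmatory common-factor model: each of
nine navigation indicators loads on exactly one of three paradigm factors
(Square Town, Virtual SILCton, Temple Tour).  In the standardized solution an
indicator x with loading lambda on factor f satisfies

    x = lambda * f + sqrt(1 - lambda**2) * e,

with e independent standard normal, so the residual variance is forced to
1 - lambda**2 and the population correlation between two indicators loading
on factors j and k is lambda_1 * lambda_2 * Phi[j, k].

Covariates (age, gender, IQ) may carry standardized paths into the factors;
the factor correlation matrix Phi always refers to the *marginal* factor
correlations, so the structured residual of the factor layer absorbs
whatever correlation the covariates do not account for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical order of the nine scored navigation indicators
INDICATORS: tuple[str, ...] = (
    "squaretown_efficiency",
    "squaretown_map_r2",
    "squaretown_pointing",
    "silcton_map_r2",
    "silcton_within_pointing",
    "silcton_between_pointing",
    "temple_map_r2",
    "temple_pointing",
    "temple_efficiency",
)

#: paradigm factor labels, in canonical order
FACTORS: tuple[str, ...] = ("SquareTown", "VirtualSILCton", "TempleTour")

#: covariate columns carried alongside the indicators
COVARIATES: tuple[str, ...] = ("age", "gender", "kbit_iq")


class InvalidLatentSpec(ValueError):
    """Raised when a latent specification violates its invariants."""


@dataclass
class LatentSpec:
    """Generating truth for the navigation factor model.

    Parameters
    ----------
    factor_names
        Labels of the latent factors.
    loadings
        Mapping ``indicator -> (factor, standardized loading)``; every
        indicator loads on exactly one factor and ``|lambda| <= 1``.
    phi
        Marginal factor correlation matrix (symmetric, unit diagonal,
        positive definite), ordered like ``factor_names``.
    covariate_effects
        ``covariate -> {factor: standardized path}``.  Covariates absent
        from the mapping have zero paths.
    """

    factor_names: tuple[str, ...] = FACTORS
    loadings: dict[str, tuple[str, float]] = field(default_factory=dict)
    phi: np.ndarray = field(default_factory=lambda: np.eye(len(FACTORS)))
    covariate_effects: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        k = len(self.factor_names)
        if self.phi.shape != (k, k):
            raise InvalidLatentSpec(f"phi must be {k}x{k}, got {self.phi.shape}")
        if not np.allclose(self.phi, self.phi.T):
            raise InvalidLatentSpec("phi must be symmetric")
        if not np.allclose(np.diag(self.phi), 1.0):
            raise InvalidLatentSpec("phi must have a unit diagonal")
        if np.linalg.eigvalsh(self.phi).min() <= 0:
            raise InvalidLatentSpec("phi must be positive definite")
        for ind, (fac, lam) in self.loadings.items():
            if fac not in self.factor_names:
                raise InvalidLatentSpec(f"{ind} loads on unknown factor {fac!r}")
            if abs(lam) > 1:
                raise InvalidLatentSpec(f"|lambda| > 1 for {ind}")
        for cov, paths in self.covariate_effects.items():
            for fac in paths:
                if fac not in self.factor_names:
                    raise InvalidLatentSpec(f"covariate {cov} targets unknown factor {fac!r}")

    # -- derived structure ------------------------------------------------

    @property
    def indicator_names(self) -> tuple[str, ...]:
        return tuple(self.loadings)

    def residual_variances(self) -> dict[str, float]:
        """Residual variance 1 - lambda**2 of each indicator (standardized)."""
        return {ind: 1.0 - lam**2 for ind, (_, lam) in self.loadings.items()}

    def loading_matrix(self) -> np.ndarray:
        """Dense loading matrix Lambda, indicators x factors."""
        lam = np.zeros((len(self.loadings), len(self.factor_names)))
        for i, (_, (fac, val)) in enumerate(self.loadings.items()):
            lam[i, self.factor_names.index(fac)] = val
        return lam

    def gamma_matrix(self, covariates: tuple[str, ...] = COVARIATES) -> np.ndarray:
        """Covariate-path matrix Gamma, factors x covariates."""
        g = np.zeros((len(self.factor_names), len(covariates)))
        for c, cov in enumerate(covariates):
            for fac, val in self.covariate_effects.get(cov, {}).items():
                g[self.factor_names.index(fac), c] = val
        return g

    def implied_indicator_correlation(self) -> np.ndarray:
        """Population correlation matrix Lambda Phi Lambda' + diag(1 - lambda^2)."""
        lam = self.loading_matrix()
        sigma = lam @ self.phi @ lam.T
        np.fill_diagonal(sigma, 1.0)
        return sigma


def default_latent_spec() -> LatentSpec:
    """The published generating truth for the paradigm-based trifactor model.

    Standardized loadings: Square Town (.64 efficiency, .59 map,
    .69 pointing); Virtual SILCton (.60 map, .60 within-route pointing,
    .90 between-route pointing); Temple Tour (.79 efficiency, .77 map,
    .48 pointing).  Factor correlations: Square Town--SILCton .69, Square
    Town--Temple .57, SILCton--Temple .57.  Covariate paths: gender (female
    = 1) -> SILCton -.24 and Square Town -.31; IQ -> (.51, .44, .45); age
    carries no path in this young-adult sample.
    """
    loadings = {
        "squaretown_efficiency": ("SquareTown", 0.64),
        "squaretown_map_r2": ("SquareTown", 0.59),
        "squaretown_pointing": ("SquareTown", 0.69),
        "silcton_map_r2": ("VirtualSILCton", 0.60),
        "silcton_within_pointing": ("VirtualSILCton", 0.60),
        "silcton_between_pointing": ("VirtualSILCton", 0.90),
        "temple_map_r2": ("TempleTour", 0.77),
        "temple_pointing": ("TempleTour", 0.48),
        "temple_efficiency": ("TempleTour", 0.79),
    }
    phi = np.array(
        [
            [1.00, 0.69, 0.57],
            [0.69, 1.00, 0.57],
            [0.57, 0.57, 1.00],
        ]
    )
    covariate_effects = {
        "gender": {"SquareTown": -0.31, "VirtualSILCton": -0.24},
        "kbit_iq": {"SquareTown": 0.51, "VirtualSILCton": 0.44, "TempleTour": 0.45},
        "age": {},
    }
    return LatentSpec(
        factor_names=FACTORS,
        loadings=loadings,
        phi=phi,
        covariate_effects=covariate_effects,
    )


def phi_lookup(spec: LatentSpec) -> dict[tuple[str, str], float]:
    """Factor correlations keyed by (name, name) pairs, both orders."""
    out: dict[tuple[str, str], float] = {}
    for i, a in enumerate(spec.factor_names):
        for j, b in enumerate(spec.factor_names):
            out[(a, b)] = float(spec.phi[i, j])
    return out
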