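# Methods

## The measurement model

The package treats navigation skill as a set of correlated latent
abilities measured by nine task indicators. The generating and fitted
model is a first-order confirmatory factor model: each indicator loads on
exactly one factor,

    x_i = λ_i f_j(i) + sqrt(1 − λ_i²) e_i,        e_i ~ N(0, 1) iid,

with factor correlation matrix Φ (unit diagonal, positive definite). In
this standardized solution the residual variance is forced to 1 − λ_i²
and the population correlation of two indicators is λ_i λ_k Φ[j(i), j(k)].

Six hypothesized loading patterns are built in: a single general factor;
two bifactor patterns (gridded vs. non-gridded layout; virtual vs.
real-world modality); a task-organized trifactor (map, pointing,
efficiency — sized 3/4/2 because one virtual paradigm has no route
efficiency task); the paradigm-organized trifactor; and the
paradigm-organized trifactor with age, gender and IQ as exogenous
correlated predictors of all three factors.

The default generating truth is the paradigm-organized model with
standardized loadings (.64, .59, .69) for the gridded virtual town,
(.60, .60, .90) for the route-integration environment, (.79, .77, .48)
for the real-world tour, factor correlations (.69, .57, .57), and
covariate paths gender → (−.31, −.24, 0), IQ → (.51, .44, .45), age → 0.

## Estimation

Fitting minimizes the Wishart maximum-likelihood discrepancy

    F(θ) = ln|Σ(θ)| − ln|S| + tr(S Σ(θ)⁻¹) − p

over free loadings, factor correlations and residual variances, with
factor variances fixed at 1 (marker-variable identification is what the
independent EM reference in the test suite uses; the two
identifications give the same likelihood and standardized solution).
Optimization is L-BFGS-B from three jittered starts with an analytic
gradient for pure measurement models (dF/dΣ = Σ⁻¹(Σ−S)Σ⁻¹ pushed through
the model structure) and a numerical gradient for the covariate model.
A failed line search can report a bogus objective, so the objective is
re-evaluated at each returned point and cleanly converged starts are
preferred; non-convergence is reported, never silently retried further.

Test statistic and indices: χ² = (N−1)·F_min; p from the central χ² upper
tail; CFI = 1 − max(χ²−df, 0)/max(χ²_b−df_b, χ²−df, 0) against the
independence baseline (F_b = Σ ln s_ii − ln|S|, df_b = p(p−1)/2);
RMSEA = sqrt(max(χ²−df, 0)/(df·N)). This (N−1)/N pairing reproduces the
published RMSEA values for the optimal (χ²=37.49, df=24, N=94 → 0.077)
and covariate (χ²=66.04, df=42 → 0.078) models. Degrees of freedom follow
standard counting, p(p+1)/2 − q; the single-factor model on nine
indicators therefore has df = 27 (18 free parameters), not the df = 25
some summaries print.

Improper solutions — any negative residual variance (Heywood case) or a
non-positive-definite latent correlation matrix — set
`proper_solution = False`. Model comparison ranks by CFI descending with
RMSEA ascending as tie-breaker, and an improper solution is disqualified
from first place regardless of its indices. Factor scores use the
regression (Thurstone) method, F̂ = (X − x̄) Σ̂⁻¹ Λ̂ Φ̂, from the
indicator block only.

The covariate model keeps the measurement part and adds
η = Γx + ζ with x = (age, gender, IQ) freely correlated, disturbance
variances fixed at 1 for identification, and disturbance covariances
free; the reported solution is standardized afterwards. Its free-parameter
count (36 on 12 observed variables) gives df = 42.

## Power analysis

`required_n_rmsea` returns the smallest integer N for which the central
χ² test of exact fit at level α has power ≥ 1−β against a model whose
misfit is ε in RMSEA units, using the noncentral χ² distribution with
noncentrality λ = (N−1)·df·ε². This (N−1) convention reproduces both
published sample sizes (85 at df = 8 and 31 at df = 42, at ε = .15,
α = .05, power = .80); an N-based convention is available behind a flag.
The minimum is found by bisection on the monotone power curve.

## The synthetic-data generator

The generator's defaults are the study conditions: 94 participants, age
uniform on the integers 18–30 (only mean and SD being reported, a bounded
uniform was chosen), P(female) = 69/94, IQ ~ N(99.64, 11.60²). Latent
abilities are Γz + structured residual, where z are the population-
standardized covariates and the residual covariance Φ − ΓΓ′ is scaled so
the *marginal* factor correlation matrix equals Φ exactly.

Two generation levels are deliberately exposed:

- **Indicator level** draws the nine indicators directly from the
  common-factor equation. This is the exact published structure and is
  what the factor-model recovery and selection tests use.
- **Raw-trial level** inverts every scoring rule. Choices, where the
  underlying studies specify none:
  - *Pointing noise* is wrapped normal with dispersion
    σ = σ₀ exp(−0.55·ability) — a single-parameter family with a clean
    uniform limit (mean folded error → 90° as σ → ∞).
  - *Map placements* are a fixed similarity transform of the true layout
    (the regression is invariant to it) plus isotropic Gaussian jitter
    with SD proportional to layout extent and decaying in ability.
  - *Route traces* follow the shortest path with an ability-dependent
    detour probability per intersection (fixed detour length) and up to
    2% corner-cutting, so sub-1 efficiency ratios occur as observed.
  - *Tour legs* overshoot their minimum object count by a Poisson number
    with ability-decaying rate (shortcuts are impossible by design).
  - The σ₀/rate constants are a fixed lookup calibrated once so that the
    ability-zero cohort means approximate the published descriptives
    (e.g. within-route pointing ≈ −27°, between-route ≈ −55°, efficiency
    ratios ≈ 1.36 and 1.22); they are not fitted at run time.
  - Each task's effective ability is w·f + sqrt(1−w²)·u with a
    task-specific standard normal u. Without this, scored indicators
    would correlate with their paradigm factor near 1 (the trial counts
    are large), collapsing the within-paradigm structure; the weights w
    are set so the score–factor correlations approximate the published
    loadings, floored so every indicator keeps a Spearman correlation
    above 0.5 with its factor.
  - Questionnaire items are generated from latent traits whose loadings
    on the navigation factors encode the observed predictive pattern
    (mental rotation → the two virtual paradigms; perspective taking →
    the paradigms with free route choice; self-reported sense of
    direction weakly → all; strategy preference → none), with item-level
    noise calibrated to the published instrument means and SDs.

What the raw level does *not* emulate: real trial-to-trial learning or
fatigue, spatially structured map distortions (it jitters isotropically),
route-choice topology (detours are length-equivalent, not path-shaped),
response-time distributions, and any non-normal ability distribution.
Passing tests therefore demonstrate that the pipeline recovers structure
faithfully from data with this generative geometry, not that the
published substantive findings would replicate in new human samples.

## Numerical choices and degenerate inputs

- Angles live in degrees in [0, 360), clockwise from reference; folding
  is symmetric and bounded in [0, 180]; 360 normalizes to 0 in the
  chirality correction.
- Bidimensional regression requires ≥ 3 non-collinear pairs and signals
  degenerate (zero-variance) configurations; R² is clipped to [0, 1];
  the Euclidean model is the pipeline default, the affine variant is
  available but unused.
- The efficiency denominator is the mean shortest distance with the
  numerator a mean over routes of per-route mean distance, so a perfect
  navigator scores exactly 1; a literal-sum variant (numerator summed
  over routes) sits behind a flag.
- Z-standardization uses the sample SD (n−1); gender stays 0/1; constant
  columns and missing values are errors, not silently imputed.
- Sample covariance matrices must be positive definite; fits on non-PD
  input signal immediately.
- Partial-correlation p-values are two-sided t with df = n − 2 − k; no
  multiple-testing correction is applied anywhere, matching the source
  analysis.
- Skewness is m₃/m₂^1.5 and kurtosis the excess m₄/m₂² − 3.

## Sizes used by the test suite

Monte-Carlo checks use the smallest sizes at which the quantities are
stable: population-moment checks at n = 10⁴–5·10⁴ draws, parameter
recovery at n = 5000 (bias over 20 replicates), model-selection recovery
over 20 cohorts of n = 2000, the cross-paradigm correlation band over 50
cohorts of n = 94, the guessing baseline at 10⁶ draws, and round-trip
monotonicity at n = 1000 scored participants.

## Known limitations

- The covariate CFA uses a numerical gradient and is an order of
  magnitude slower than pure measurement models (still < 1 s at study
  sizes).
- Robust (non-normal) corrections to χ² and standard errors are not
  implemented; the source analysis used plain ML and the route-efficiency
  indicators are visibly skewed, a caveat that applies here equally.
- The categorical pointing task is scored as if responses were metric
  degrees ({0, 90, 180}); no ordinal measurement model is offered.
- Missing data are rejected rather than handled by FIML or imputation.
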