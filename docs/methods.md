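# Methods

## Model and estimand

All tests address the directional gene-set null H₀: β̄ = (1/m)Σβⱼ = 0 in
the multivariate linear model

    Y = X B + E,        (n subjects × m genes)

where X stacks an intercept, nuisance covariates, and the focal
predictor(s). Columns of Y are sign-oriented (genes whose expected
response opposes the set's direction are negated) and z-scored (mean 0,
variance 1, n−1 denominator); focal predictors are z-scored. Because
each column of B equals the coefficients of a univariate multiple
regression of that gene, β̄ is also the focal coefficient of the
regression of the row-mean outcome on the same design — an identity the
test suite asserts. Orientation and standardization commute (columns are
re-standardized after orientation), so their order is irrelevant; this
is also asserted.

The fit uses a QR decomposition of the design rather than normal
equations: with 17 partially collinear covariates, rank deficiency
should be detected and named, not silently absorbed. t-values use the
per-gene residual variance with df = n − p_total; no variance pooling
happens at this layer (pooling lives in the rotation test's moderated
t).

## Tests

**O'Brien OLS t.** t = Σtⱼ/√(1'R1) where R is the correlation matrix of
residuals from the reduced model (all covariates except the focal one),
referred to t with n − p − 1 df (p = predictors excluding the
intercept, i.e. the full-model residual df). SE of β̄ is reported as
|β̄/t|. Contrasts of two focal effects use per-gene contrast t-values
and an R from the reduced model excluding both.

**Freedman–Lane permutation machinery.** Residuals of Y on the nuisance
block are permuted and added back to the nuisance fit:
Y_π = Ŷ + E^π_{Y|X}. This preserves the covariate structure while
destroying the focal association; residuals under the null are
(approximately) exchangeable where the focal predictor of an
observational design is not. Iteration 0 is always the observed data and
p = #{stat ≥ stat_obs}/B, so p ≥ 1/B and exact-zero p-values are
impossible. Comparisons use exact float ≥.

- *r²F*: squared partial correlation, (Σ E_{π(F)}E_{Z|X})² over the
  product of total sums of squares, the focal-residual term replicated
  per gene (factor m) so the statistic lies in [0,1] and reduces to the
  squared partial correlation at m = 1. (The multivariate summation
  ranges are not fully pinned down in the sources; the per-gene
  replication reading is implemented. An alternative trace-form reading
  rescales all statistics by a constant and cannot change permutation
  p-values.)
- *F_pun*: both the full and reduced models are refit to Y_π each
  iteration; the statistic is (RSS_reduced − RSS_full)/RSS_full summed
  over genes. The df constants of a textbook F are omitted: permutation
  p-values are invariant to them, and omitting them avoids committing to
  any package's internal df bookkeeping.
- *F_ga* (GlobalAncova-style): the outcome is the observed reduced-model
  residual matrix (computed once); each iteration permutes the focal
  predictor's rows instead. This violates exchangeability in
  observational designs; the simulations show the violation is mild
  (null p-value distributions of F_ga and F_pun agree closely).

All permutation statistics are computed in a vectorized form that never
refits models per iteration: with Q an orthonormal nuisance basis,
RSS terms reduce to ‖E‖² − ‖QᵀE_π‖² and cross-products to inner products
with the focal residual, processed in blocks of 512 permutations to
bound memory.

**Rotation z-test.** Y and the focal predictor are projected onto the
(n−q)-dimensional orthocomplement of the nuisance space (complete QR).
Per gene the effect along the unit focal direction and the residual
variance on the remaining n−q−1 dimensions give a moderated t: variances
are shrunk toward a common prior with hyperparameters (d₀, s₀²)
estimated by moment matching on log variances (trigamma inversion by
safeguarded Newton); when the variances show no excess dispersion the
prior df is infinite and all genes share the common variance. t-values
map to z through matched t/normal tail areas; the statistic is the mean
z, and null draws replace the focal direction with random unit Gaussians
(the Gaussian null is rotation-invariant, making the test exact in small
samples). Hyperparameters are estimated once from the observed
iteration; exact numerical agreement with any published moderated-t
implementation is not claimed.

**GEE.** The wide matrix is stacked long (one row per subject × gene)
with gene-specific intercepts and covariate effects shared across genes;
statsmodels' Gaussian GEE with exchangeable working correlation
estimates the population-averaged focal effect, and the default sandwich
covariance clustered by subject gives a robust SE. p is two-sided normal
(Wald z); whether a t reference would be preferable in small samples is
left open, z being standard GEE practice. On balanced designs the GEE
focal estimate coincides with the OLS β̄.

**Legacy coefficient-bootstrap t.** Resamples the m per-gene
coefficients with replacement, uses the SD of the resampled means as an
SE, and refers β̄/SE to t with m−1 df. It ignores the correlation of the
coefficients (SE too small with correlated genes → inflated Type I) and
its df ignore n; at m = 1 it cannot be computed at all. Results carry a
`known_invalid` flag.

## Correlated-error GLS

The long-format model y_i = X_i β + ε_i, ε_i ~ N(0, Σ) is fit by maximum
likelihood with Σ either heterogeneous compound symmetry (gene-specific
σⱼ, one common ρ ∈ (−1/(m−1), 1)) or unstructured. Estimation
alternates:

1. **β step** — exact GLS given Σ. Because covariates are constant
   within subject, the nm-row normal equations collapse to an
   (m+q)-block system in the gene intercepts and shared covariate
   effects; no long-format matrix is ever materialized, making a fit at
   n=122, m=52 take ~20 ms.
2. **Σ step** — for het-CS, joint maximization of the profile
   log-likelihood over (log σ, ρ) by L-BFGS-B with an analytic gradient,
   using the closed forms R(ρ)⁻¹ = aI + bJ and
   log|R| = (m−1)log(1−ρ) + log(1+(m−1)ρ); the step is seeded at the
   current parameters and guarded, so the log-likelihood never
   decreases. (A simpler σⱼ² = mean eⱼ² update is not the ML update
   given ρ ≠ 0 and can decrease the likelihood; it was rejected for that
   reason.) For unstructured, Σ̂ = n⁻¹Σeᵢeᵢᵀ is the exact ML update; a
   ridge jitter retries a non-PD update, and n ≤ m fits are refused
   outright (they do not converge reliably).

Both half-steps are non-decreasing in the log-likelihood, asserted per
iteration. Convergence: max |Δβ| < 1e-6, cap 200 iterations;
hitting the cap is reported as `converged=False`, never as success.
Model-based SEs come from (ΣᵢXᵢᵀΣ̂⁻¹Xᵢ)⁻¹ and p-values from a two-sided
normal — exactly the quantities whose downward bias under misspecified
correlation the wrappers expose:

- **Bootstrap**: subjects resampled with replacement in wide format,
  all columns re-standardized (orientation re-applied implicitly since
  |z| is sign-invariant), model refit; SE = SD of the focal coefficient
  over resampled iterations, excluding the observed iteration 0 (the
  sources are silent on this; excluding it is the conventional choice
  and is documented here). Binary covariates with fewer minority cases
  than a threshold (default 3) in a given resample are dropped for that
  iteration — a resample with a constant dummy is unsolvable. More than
  20% failed iterations flags the summary unreliable.
- **Permutation**: Freedman–Lane in wide format, re-standardize,
  refit; p = #{|t| ≥ |t_obs|}/B including the observed iteration.

With a homoscedastic exchangeable Σ the GLS focal estimate equals the
OLS β̄ exactly (uniform weights); with freely fitted per-gene σ̂ⱼ the
weights differ at O(n^{-1/2}) and the two estimates agree only to ~1e-2
on standardized effects — the test suite asserts the exact identity
under Σ ∝ I and the approximate one for the fitted model.

## Monte Carlo engine

`simulate_dataset` draws X ~ N(0, S_X) (n×17) and Y ~ N(0, S_Y[subset])
with the m-gene subset resampled from the pool each iteration, then adds
β_true·z_focal to every gene. Columns of Y are not re-standardized after
injection: at the study's effect size (0.067) the variance inflation is
< 0.5% and re-standardizing would shrink the true effect being measured.
All non-focal effects are zero. Defaults mirror the motivating study:
n = 122, m ∈ {10, 30, 52}, β_true = 0.067 (the study's estimated
standardized effect), focal-pair regressor correlation 0.74, α = 0.05,
2,000 resamples per test inside the simulation (500 at desk scale).

**Synthetic covariances.** The real S_X/S_Y are not publicly printed, so
the engine accepts user-supplied matrices and otherwise generates:

- S_X: unit diagonal; a random two-factor correlation shrunk so the mean
  absolute nuisance correlation is 0.2 (typical for demographic/immune
  covariate panels); the focal-pair entry set to 0.74 exactly;
  positive-definiteness enforced by shrinking non-focal off-diagonals if
  needed.
- S_Y: low-rank-plus-diagonal with unit diagonal — one dominant
  all-positive factor (loadings U(0.4, 0.9)) for the co-expression of a
  functionally coherent, orientation-corrected gene set, plus two weaker
  mixed-sign factors so the structure is *not* exchangeable (gene pairs
  differ in correlation, which is what misspecifies the compound-symmetry
  GLS); loadings rescaled until the mean pairwise correlation is 0.30
  (moderate co-expression, a deliberate one-time choice), verified
  within ±0.02 at generation.

**Error metrics.** Type I and power are rejection fractions at α (Wald
binomial SEs reported). Type S = P(sign(β̂) wrong | p < α); the
exaggeration ratio is the mean of |β̂|/|β_true| over p ≤ α (absolute
values by default — the sources do not state signed vs absolute; a
signed variant is available via `signed=True`); relative bias averages
over *all* iterations. The strict-vs-non-strict α thresholds for Type S
and ER follow the sources literally; with continuous p-values the
difference is immaterial. Adjusted power evaluates each test at the
largest α whose empirical null rejection rate is ≤ 0.05 (with heavy ties
the cut falls strictly below the smallest null p). Undefined metrics
(no significant iterations) are NaN, never 0.

**Reproducibility.** One root seed; every (gene-set size, effect,
iteration, method) tuple draws from a named `SeedSequence` substream, so
identical configs are bit-identical and enabling/disabling one method
does not perturb the others. Non-converged iterations (GLS/GEE) are
excluded from rates and counted; >5% failures flags the row.

## What the generator does and does not emulate

It reproduces the study's dimensions, the focal-pair collinearity, and
generic correlated-outcome structure. It does not reproduce the real
covariance matrices themselves: with a uniform injected effect and a
Gaussian factor-structured S_Y, the linear-combination tests (O'Brien,
r²F, rotation) are close to optimal, and the permutation-F tests show
the *same* power rather than the large power advantage seen on data
modeled on the real covariances; consequently exaggeration ratios of
the well-calibrated tests also coincide. Conclusions that survive the
synthetic conditions — nominal OLS calibration, GLS Type I inflation
growing with m, GLS model SEs understating the sampling SD, higher sign
error for quadratic-statistic tests, negatively correlated coefficient
pairs for correlated regressors — are structural; quantitative rankings
of power and Type M error depend on the real covariances and should be
re-run with supplied S_X/S_Y (`SimulationConfig(S_X=..., S_Y=...)`)
before being quoted.

## Numerical choices and degenerate inputs

Sample variances use n−1 throughout. Constant columns cannot be
standardized and raise with the column named. Zero focal residual
(focal in the nuisance span) raises. A perfect full-model fit
(RSS_full = 0) raises rather than returning an infinite statistic.
t→z mapping uses tail areas via `sf`/`isf` to stay accurate for |t| up
to the float tail. Permutation arrays may be supplied explicitly
(`permutations=`, identity first) for exhaustive enumeration and for
sharing draws across tests; the simulation engine shares one draw set
across the three permutation tests of an iteration.

## Known limitations

- GEE small-sample corrections (Mancl–DeRouen etc.) and non-identity
  links are out of scope; the GEE reference is z, not t.
- The rotation test's moderated-t hyperparameters are estimated once
  from the observed iteration, not per rotation.
- Competitive (between-set) enrichment, gene-level multiple testing,
  shrinkage regression, and Wilks-type "any coefficient" multivariate
  tests are out of scope.
- REML, random-effects (conditional) mixed models, and AR(1)/spatial
  error structures are not implemented.
- GEO series-matrix support is limited to the numeric-table dialect
  ("!"-prefixed metadata skipped); probe-to-gene mapping and intensity
  normalization are upstream concerns.
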