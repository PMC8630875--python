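# Methods

## Model

For child *j* in region *i*, anaemia status is Bernoulli(p_ij) with

logit(p_ij) = β₀ + z_i'β + Σ_k f_k(u_ik) + f_spatial(S_i),

where the model forms M0–M3 include, respectively, neither, only the
smooths, only the spatial term, or both.

**Fixed effects.** Categorical covariates are deviation (effect) coded: each
non-reference level carries an indicator column and the reference level is
−1 in every column, so coefficients are contrasts against the grand mean and
the reference effect is minus the sum of the listed coefficients. Fixed
effects get an improper flat prior, implemented as a ridge of 1e−8 on the
precision for numerical stability.

**P-spline smooths.** Each continuous covariate gets a B-spline basis of
degree *l* (default cubic) on *s* equally spaced interior segments (default
20) spanning the observed range, giving d = s + l coefficients. The knot
grid is extended by *l* extra knots *at the same spacing* on each side
rather than clamped; this keeps all penalized coefficients exchangeable
under the random-walk prior. The prior on the coefficient vector ε is the
partially improper Gaussian with precision K/τ², K = DᵀD the order-r
difference penalty (default r = 2, so deviations from a straight line are
penalized; constants and linear trends are unpenalized). The covariate
maximum is representable because the basis is right-closed at the final
knot.

**Spatial term.** Two interchangeable constructions over the region set:

* *tensor* (default): marginal cubic B-spline bases over centroid longitude
  and latitude (8 segments each, so 11 × 11 = 121 coefficients for the
  default geography), row-wise Kronecker design, penalty K₁⊗I + I⊗K₂ with
  first-order marginal walks. Its null space is only the constant surface.
* *mrf*: identity design over regions with the graph Laplacian of the
  neighbourhood graph as precision (intrinsic autoregression). The graph
  defaults to the symmetrised four-nearest-neighbour graph under
  great-circle (haversine) distance between centroids, with distance ties
  broken by region order; a user adjacency list overrides it.

Both appear in the literature this model family comes from; the tensor
smooth is the default here because it delivers a continuous surface that can
be read at any coordinate.

**Identifiability.** Every penalized block is column-centered against the
observed data (the spatial block with child weights, i.e. region counts), so
each smooth and the spatial surface carry mean zero and the single global
intercept absorbs the level. No further constraint is imposed; the flat
directions that centering leaves (e.g. the linear trend under an RW2 prior)
are identified by the likelihood.

**Hyperpriors.** Every smoothing variance τ² has an inverse-gamma(a, b)
prior with a = b = 0.001 by default (configurable).

## Sampling

Gibbs with Pólya-Gamma augmentation: ω_i | η ~ PG(1, η_i) makes every
coefficient block conditionally Gaussian,

θ_block | · ~ N(P⁻¹ Xᵀ(κ − Ω η_rest), P⁻¹), P = XᵀΩX + K/τ²,

with κ = y − 1/2, and τ² | ε ~ IG(a + rank(K)/2, b + εᵀKε/2). PG(1, z)
variates come from an exact alternating-series rejection sampler
(Devroye-type, acceptance probability > 0.999), vectorized over
observations; correctness is checked in the tests against the closed-form
moments E = tanh(z/2)/(2z) and an independent truncated sum-of-exponentials
sampler. This sampler is conditionally conjugate and needs no tuning, which
makes runs exactly reproducible from a single seed.

Per-iteration cost is dominated by XᵀΩX per block; the spatial block is
aggregated to region level (Ω region sums via bincount), so a full M3 sweep
at n = 20,000 costs ~18 ms. Initialization: fixed effects at the
ridge-penalized IRLS solution, smooth coefficients at zero, variances at
0.1. Initialization only accelerates burn-in; retained draws follow the
posterior regardless.

The deviance −2 Σ [y_i η_i − log(1 + e^{η_i})] is recorded at every retained
iteration, together with a running mean of η. Because η is linear in all
coefficients, the deviance at the posterior-mean parameters equals the
deviance at the mean η, which gives p_D = D̄ − D(θ̄) and DIC = D̄ + p_D
without storing the full design. (Published tables in this model family
sometimes print columns satisfying Deviance − p_D = DIC; this package
follows the standard definition DIC = D̄ + p_D throughout.)

Convergence tooling: per-parameter autocorrelations (up to lag 50),
effective sample size, and trace export; constant chains are flagged as
degenerate rather than given a meaningless ESS. A drifting mean |η| beyond
25 triggers a perfect-separation warning, not a failure.

## Summaries

* Coefficient tables report posterior mean, SD and the 10%/50%/90%
  quantiles; the significance star is computed from the 95% equal-tailed
  interval (5% alpha) even though the printed quantiles are the 10%/90%
  pair.
* Quantiles use linear interpolation of order statistics (numpy's default),
  and all intervals are equal-tailed, not HPD — matching the credible-
  interval convention of the structured additive regression software
  family.
* Smooth curves are posterior means with pointwise 2.5%/97.5% bands,
  evaluated under the same centering as the fit.
* Spatial classification: per region, the posterior draws of the centered
  surface at its centroid; positive iff the interval's lower bound exceeds
  zero, negative iff the upper bound is below zero, else insignificant, at
  both the 80% and the 95% level. Equal-tailed intervals nest, so the 80%
  map is always at least as "significant" as the 95% map.

## Descriptive stage

Prevalence tables (percent and count anaemic per group plus an overall row)
and a Pearson chi-square screen of each categorical covariate against the
outcome at α = 0.20, without continuity correction (large-sample setting).
The screen is advisory: the model configuration may retain a covariate the
screen would drop, mirroring how such screens are used in practice.

## Synthetic data

The generator emulates the structure of a large national child-health
survey without reproducing any of its microdata:

* 36 regions on a 6×6 lattice of 4°×4° cells over an India-sized
  bounding box (lon 68–92, lat 8–32), string region ids, GeoJSON polygons.
* Eleven categorical covariates with survey-like margins (rural 77.2%,
  mother anaemic 40.9%, wasting 7.7%, ...; see
  `geoadditive.simulate.CATEGORY_FREQS`).
* Continuous covariates uniform on their clinical ranges: child age 6–59
  months, mother's age 15–49 years, breastfeeding 0–59 months — independent
  by default, with an optional Gaussian-copula correlation knob for mother's
  age × breastfeeding.
* Truth functions, analytically mean-centered over the covariate laws:
  f_age(a) = 0.8·exp(−(a−6)/10) − c₁ (risk decays fastest over 6–15
  months), f_mage(m) = 0.0022·(m−31)² − c₂ (U-shape declining to 31),
  f_bf(b) = 0.0012·(b−29)² − c₃ (minimum at 29 months), and the surface
  0.7·sin(πx̃)cos(πỹ) in map-normalized coordinates, centered over region
  centroids.
* Fixed-effect truth on the logit scale with magnitudes typical of such
  surveys (mother anaemic +0.27, stunting +0.10, higher education −0.184,
  ...), and an intercept of 0.3786 calibrated once by large-sample Monte
  Carlo so the marginal prevalence is ≈ 57.6%.
* Children are allocated uniformly across regions (the real survey's
  within-state allocation is unknown); outcomes are Bernoulli(logistic(η)).

What the generator does **not** emulate: the two-stage cluster design,
sampling weights, nonresponse, covariate dependence beyond the optional
copula, and within-region covariate geography (all children in a region sit
at its centroid spatially). Passing recovery tests therefore demonstrates
correctness of the estimator under the model's own assumptions, not
robustness to survey-design artefacts.

## Problem sizes used in the checks

The reference study runs at 20,000 children with 8,000 iterations / 2,000
burn-in for all four forms — large enough that posterior means pin the truth
(fixed effects within ±0.1, curve RMSE < 0.08) yet a full four-model run
stays under ten minutes on one CPU. The null-scenario DIC check uses 10,000
children and a 3,000/1,000 chain; interval-coverage replicates use 5,000
children with reduced bases (8 segments, spatial 4) and 1,500/500 chains,
to which the posterior of a fixed-effect coefficient is insensitive. The
demo configuration is smaller still (5,000 children, 800/300) and is meant
for smoke-testing, not inference.

## Numerical choices and edge cases

* Basis evaluation outside the knot range raises; no silent extrapolation.
* Degenerate covariates (min = max) raise with the covariate named.
* Duplicate region centroids raise with the offending region ids.
* Missing covariate values: complete-case per fitted model, with the
  dropped-row count logged (missingness itself is tabulated but not
  modelled).
* The haemoglobin cutoff is strict: anaemic iff Hb < 11 g/dL.
* Negative p_D is reported with a warning, never clipped.
* Cholesky factorizations carry a 1e−8 ridge; random-walk null spaces are
  handled by centering plus the likelihood, not by extra constraints.

## Known limitations

* Single-chain sampler; between-chain diagnostics (R̂) are out of scope.
* Logit link only.
* The tensor spatial smooth treats centroid coordinates as plane-like;
  for continent-scale geographies a projected CRS would be preferable.
* DIC is the only model-comparison criterion (no WAIC/LOO).
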