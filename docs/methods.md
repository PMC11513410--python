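# Methods

## The model

`isdm_change` fits, per species, a Bayesian integrated species
distribution model (ISDM) on an equal-area grid (default 100×100 km,
Lambert azimuthal equal-area projection on the authalic sphere, centred
at 0°, −73.125°) across two time periods, and derives biodiversity-change
summaries from the posterior.

**Latent state.** The true distribution is an inhomogeneous Poisson
point process with piecewise-constant intensity per cell *i* and period
*t* (individuals·km⁻²):

    log λ_it = β₀ + x_iᵀβ + β_D·D_i + B_i·g + 1[t=2]·(τ + B_i·g₂)

* `x_i` — four screened, standardized environmental covariates;
* `D_i` — distance (in 1000 km) from the cell centroid to the expert
  range polygon, 0 inside it, with a *free* coefficient β_D so the data
  decide how strongly the expert map penalises predictions outside the
  range;
* `B` — a tensor-product cubic B-spline surface over the projected
  coordinates (K = 16 columns by default, knots on a ⌈√K⌉×⌈√K⌉ lattice,
  columns centred; when K is not a perfect square the K lowest-order
  tensor columns are kept so the basis is exactly cells × K). It absorbs
  residual spatial autocorrelation and missing covariates;
* `τ` and the interaction field `g₂` — a scalar period effect plus a
  spatially varying period-2 offset, so range change need not be
  spatially uniform. `g₂` carries its own (typically smaller) scale.

**Observation processes.** Two data types see the latent state:

* *Presence-only counts.* Records are filtered (≥3 coordinate decimals,
  uncertainty ≤ 25 km), deduplicated on (species, date, lat, lon), and
  aggregated to per-cell, per-period counts `n_it`. These follow
  `n_it ~ Poisson(λ_it · A_i · p_i · ρ_t)` with a retention (thinning)
  probability `p_i = expit(α₀ + α_a·access_i + c_j(i))` driven by
  accessibility and a sum-to-zero country effect, and a *fixed*
  effort-ratio constant ρ = (1, ρ₂). ρ₂ is the ratio of pooled period-2
  to period-1 records over all study species. Placing ρ inside the
  period-2 observation mean — rather than rescaling predictions post
  hoc — is what stops growth in sampling effort from masquerading as
  range expansion; the package demonstrates this with a
  with/without-ρ contrast in its acceptance checks.
* *Presence–absence blobs.* Camera-trap surveys are buffered to discs
  of radius √(area/π); overlapping discs within a period are unioned
  into "blobs" with summed effort E_b (camera-trap days) and union area
  A_b. Detection is `y_b ~ Bernoulli(π_b)` with the presence × detection
  factorisation

      π_b = (1 − exp(−λ̄_b·A_b)) · (1 − exp(−q·E_b)),

  where λ̄_b is the area-weighted mean cell intensity over the blob for
  its period and q a per-camera-day detection rate. The first factor is
  the cloglog link between a cell-integrated intensity and a presence
  probability; the second is a standard exposure model for effort.
  Surveys spanning the period boundary go to the period containing
  their temporal midpoint.

**Priors.** Normal(0, 10²) on β₀, β, τ, β_D, α₀, α_a and the
(sum-to-zero) country effects; the spline fields are non-centred,
g = σ_g·g̃ with g̃ ~ N(0, 1) and Half-Normal(1) on σ_g and σ_g₂;
Exponential(1) on q. These are deliberately weak; with desk-scale data
the thinning intercept and q are only weakly identified (see
*Limitations*).

## Inference

The joint log posterior and its exact gradient are evaluated
analytically (`likelihood.JointModel`); a gradient check against finite
differences is part of the test suite. Sampling is Hamiltonian Monte
Carlo with

* L-BFGS initialisation at the posterior mode,
* a **dense** inverse-mass matrix seeded from the finite-difference
  Hessian at the mode and refined from warmup draws (the
  β₀/α₀/q ridge — the intensity level trades off against the thinning
  level — defeats a diagonal preconditioner),
* dual-averaging step-size adaptation (target acceptance 0.85) and a
  jittered number of leapfrog steps (1..64 by default),
* 4 chains × 2000 iterations (half warmup) by default; every fit is
  bit-reproducible given `random_state`.

Convergence is assessed with split-chain R̂ and effective sample size
(Geyer initial-monotone estimator), both implemented in-package and
tested against longhand oracles. A fit with any R̂ ≥ 1.1 keeps its
posterior but is labelled `not converged`, and the pipeline's change
stage excludes such species.

Fit quality: AUC and Tjur's R² on the blob detections (posterior-median
π_b), and randomized-quantile (PIT) residuals of the gridded counts
against the posterior predictive, with a Kolmogorov–Smirnov uniformity
statistic. The residual `u = (#{pred<obs} + V·(#{pred=obs}+1))/(m+1)`
is exactly Uniform(0,1) when the observation is exchangeable with the
predictive draws, which makes the calibration experiment sharp: data
simulated from the predictive's own model reject at the nominal rate.

## Covariate screening

A random forest is fitted to the raw blob presence/absence (both
periods pooled); candidates are ranked by permutation importance
(fixed seed) and accepted greedily in rank order, skipping any
candidate with |Pearson r| > 0.6 against an accepted one, until four
are kept. Permutation importance was chosen because it is
model-agnostic and reproducible at fixed seed; the screen is a
computational shortcut, not an inferential step.

## Change metrics

* **Occupancy.** P_it = 1 − exp(−λ_it·A_i) per posterior draw.
* **Area of occupancy.** A_t = Σ_i P_it per draw (in cells; ×10⁴ km² at
  the 100-km grain); ΔA = A₂ − A₁ within each draw, summarised by the
  median and central 95% credible interval. Intervals on changes are
  always computed from per-draw differences, never by differencing two
  marginal intervals.
* **Change classes.** Sign from the median ΔP per cell; *certain* when
  the 95% interval excludes 0; *no change* when |median ΔP| < 0.01
  (configurable). These feed bivariate change/uncertainty maps.
* **Stacked richness.** 1000 posterior draws are subsampled per species
  (models may differ in draw counts), the per-cell median occupancy
  taken, and medians summed over species; ΔSR = SR₂ − SR₁. The
  median-then-sum order follows the stacked-SDM convention.
* **Whittaker multiplicative beta.** ᾱ = mean over cells of Σ_s P_si;
  γ = Σ_s (1 − Π_i (1 − P_si)), the *expected pooled richness*, which
  reduces to a plain species count when occupancies are 0/1; β_W = γ/ᾱ.
* **Růžička dissimilarity.** R = 1 − Σ min/Σ max over paired occupancy
  vectors; per-cell between periods (temporal), and between sampled
  cell pairs within a period binned by distance (spatial distance
  decay; default 50,000 seeded pairs rather than all O(n²) pairs, since
  the summary is a binned median).

## The synthetic-data generator

The generator emulates the full observation chain with known
parameters: smooth covariate and accessibility fields are
Gaussian-process draws (squared-exponential kernel, exact Cholesky) on
the cell centroids, standardized; countries are 2–4 contiguous vertical
bands; the latent intensity follows the model equation with a smooth
residual field s (sd 0.3, range 600 km) the model does *not* see
explicitly; the pseudo-expert range is the union of cells above the
median of the period-1 intensity computed *before* the range-distance
feedback, after which D enters the final intensity — mimicking an
expert map drawn from historical knowledge of the core range. Counts
are scattered uniformly within cells and dated uniformly within
periods to produce a realistic records table; surveys are placed at
jittered random cells, merged into blobs by the same union machinery
the pipeline uses, and detected through the same presence × detection
law.

Default effect sizes describe a moderately common Neotropical-scale
species on a 20×20 grid of 100-km cells: β₀ = −8.8 (per-km² scale, so
λ·A ≈ 1.5 per cell), β = (0.8, −0.5, 0.3, 0.0) including a null effect,
τ = −0.3 (a declining species), β_D = −1.5 per 1000 km, α₀ = −0.5,
α_a = 0.5, country effects (0.4, −0.4, 0), q = 0.002 day⁻¹, 30 surveys
of 200–2000 camera-days over 1000–5000 km², and ρ₂ = 1.27 (27% more
period-2 sampling). This yields a few hundred presence-only records per
period and ~10 detections among ~30 blobs.

What the generator does **not** emulate: real bioclimatic covariate
structure (correlated, anisotropic, non-Gaussian), temporal drift in
covariates, observer-level heterogeneity beyond the accessibility/
country thinning, spatially clustered (non-Poisson) point patterns, and
taxonomic/georeferencing error beyond the uncertainty column. Passing
tests therefore demonstrate the *estimator's* correctness and
calibration under the model's own assumptions, not robustness to the
many ways real occurrence data violate them.

## Numerical choices

* Distances are rescaled to 1000-km units before entering the linear
  predictor, keeping β_D on the same magnitude as the other effects.
* σ_c for the country effects is fixed at 10, matching the other weak
  priors, rather than hyper-parameterised; the sum-to-zero constraint
  (last effect = −Σ others) keeps the thinning intercept identifiable.
* Linear-predictor values above 60 short-circuit to log-posterior −∞
  (the Poisson mean would overflow); π_b is clipped to
  [1e−12, 1−1e−12] inside the sampler only.
* The quantile defining the pseudo-range uses strict exceedance; for a
  degenerate constant field the whole support becomes the range.
* Blob membership of cells uses exact polygon-intersection areas,
  normalised over the in-grid overlap.
* Ties in screening importance break by rank position, then name.

## Known limitations

* **Weak identification of the observation level.** Only the blob data
  anchor the absolute intensity; the thinning intercept α₀ and the
  detection rate q have broad, one-sided posterior plateaus under the
  weak priors. The dense-mass HMC mixes them (R̂ < 1.1 at default
  settings) but their marginals are prior-dominated. Slope parameters
  (β, τ, α_a) are unaffected.
* **Posterior-median shift of β_D.** The pseudo-range is a level set of
  the period-1 intensity, so the distance covariate is endogenous and
  partially confounded with the spline field. The posterior *mode* of
  β_D is unbiased in simulation, but the marginal posterior is skewed
  and its median sits below the generating value by roughly half a
  posterior standard deviation at the default study size (confirmed
  against an independent ensemble sampler; unchanged with a K = 36
  basis). Interval coverage remains nominal. Users comparing point
  estimates of the range-map effect should prefer the mode or report
  the full interval.
* Per-cell intensity is piecewise constant (no within-cell point
  process integration), matching the 100-km analysis grain.
* The ± reported alongside Whittaker β is the posterior dispersion of
  per-draw β_W when draws are available; it is not a spatial standard
  error.
* Runtime scales with cells × iterations; the defaults (400 cells,
  4×2000 iterations, dense mass) fit in about a minute on one CPU, and
  the replicate experiments in the test-suite use 700-iteration fits,
  which mix the slope parameters (ESS > 100) but not the plateaued
  observation intercepts.
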