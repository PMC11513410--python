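# isdm-change

Bayesian **integrated species distribution models** (ISDMs) and the
biodiversity-change metrics built on them, for macroecologists tracking
range dynamics on coarse equal-area grids. One model per species fuses
three lines of evidence over two time periods:

* **presence-only records** (opportunistic occurrences, e.g. a GBIF
  download) — filtered, deduplicated, and aggregated to counts on a
  100×100 km Lambert-azimuthal-equal-area grid;
* **presence–absence camera-trap surveys** — buffered, merged into
  "blobs" with summed camera-trap-day effort, with non-detections used
  as informed absences;
* **an expert range map** — entering as a distance covariate whose
  coefficient is estimated from the data.

## The model

The latent state is an inhomogeneous Poisson point process with
per-cell, per-period intensity (km⁻²)

    log λ_it = β₀ + x_iᵀβ + β_D·D_i + B_i g + 1[t=2](τ + B_i g₂)

with screened environmental covariates x, distance to the expert range
D, a low-rank spatial spline field B g, a period effect τ, and a shrunk
period-interaction field g₂. Two observation processes see this state:

    n_it ~ Poisson(λ_it · A_i · p_i · ρ_t),   p_i = expit(α₀ + α_a·access_i + c_j(i))
    y_b  ~ Bernoulli((1 − e^{−λ̄_b A_b}) · (1 − e^{−q E_b}))

The thinning p corrects presence-only sampling bias (accessibility +
country); ρ = (1, ρ₂) is the pooled ratio of period-2 to period-1
records over all study species, and carrying it in the period-2
observation mean is what stops growth in recording effort from looking
like range expansion. The posterior is sampled by an in-package
Hamiltonian Monte Carlo sampler (analytic gradients, dense mass matrix,
MAP initialisation) with split-R̂/ESS convergence checks, AUC/Tjur R²
for the survey data and randomized-quantile residuals for the counts.

From the posterior the package derives: occupancy surfaces
P = 1 − e^{−λA}, area-of-occupancy change ΔA with 95% credible
intervals (in cells and km²; per-draw differencing), per-cell
change/uncertainty classes, stacked species richness, Whittaker
multiplicative beta diversity β_W = γ/ᾱ, and Růžička dissimilarity in
time (per cell) and space (distance decay). A fully parameterised
synthetic-data generator emulates all inputs with known truth, so every
stage is testable and parameter recovery verifiable. See
`docs/methods.md` for the complete account.

## Worked example

```python
import numpy as np
from isdm_change import (SimulationConfig, IntegratedSDM, assemble_isdm_data,
                         area_of_occupancy, simulate_po, simulate_surveys)
from isdm_change.synthetic import default_truth

cfg = SimulationConfig(seed=3)                      # one declining species, 20x20 grid
truth = default_truth(cfg)
counts, records = simulate_po(truth, cfg)
surveys, blobs, detections = simulate_surveys(truth, cfg)
data = assemble_isdm_data(truth.grid, counts, blobs, cfg.species,
                          cfg.effort_ratio_true, cfg.period_split_year)

est = IntegratedSDM(random_state=1).fit(data)
print(f"status: {est.posterior_.status}  (max Rhat {est.rhat_.max():.3f})")
print(f"PA discrimination: AUC {est.auc_:.3f}, Tjur R2 {est.tjur_r2_:.3f}")
summary = est.posterior_.summary()
print(summary.loc[["beta_0", "beta_1", "tau", "beta_dist"], ["median", "q2.5", "q97.5"]].round(2))

change = area_of_occupancy(est.predict_occupancy(thin_to=1000))
lo, hi = change.ci_delta_cells
print(f"AOO change: {change.median_delta_cells:.1f} cells "
      f"({change.median_delta_km2:,.0f} km2), 95% CI [{lo:.1f}, {hi:.1f}] cells")
```

prints (about a minute on one CPU):

```
status: converged  (max Rhat 1.087)
PA discrimination: AUC 0.780, Tjur R2 0.210
           median  q2.5  q97.5
parameter
beta_0       0.71  0.53   0.88
beta_1      -0.59 -0.84  -0.34
tau         -0.31 -0.50  -0.07
beta_dist   -2.44 -4.46  -0.45
AOO change: -25.9 cells (-258,798 km2), 95% CI [-39.9, -11.1] cells
```

The generating values here were β = (0.8, −0.5, …), τ = −0.3: the
credible intervals cover them, the convergence contract (R̂ < 1.1)
holds, and the estimated range loss of 25.9 grid cells (at the 100-km
grain, 10,000 km² per cell) brackets the true decline of 23.6 cells.
The negative τ and β_D say the species declined between periods and is
unlikely far outside its expert range.

## Command-line pipeline

The same workflow runs as six reproducible stages, each leaving a
manifest (config echo, seed, input checksums):

```sh
isdm-change simulate   --config config.yaml
isdm-change prepare    --config config.yaml
isdm-change covariates --config config.yaml
isdm-change fit        --config config.yaml
isdm-change diagnose   --config config.yaml
isdm-change change     --config config.yaml
```

Species whose fit violates R̂ < 1.1 are marked `not converged` and
excluded from the change stage.

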