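# Methods

This note documents the statistical models in `beescale`, the choices
made where the design was genuinely open, and what the synthetic
validation does and does not establish.

## The interspecific model

Dry weight is modelled as lognormal around a power law of the ITD:

```
ln(W_i) = x_iᵀβ + a_region(i) + b_unit(i) + ε_i,   ε_i ~ N(0, σ²)
```

* `x_i` holds an intercept, `ln(ITD_i)`, and optional treatment-coded
  offsets and slope interactions for taxonomic group (bee family or
  hoverfly subfamily) and sex. Baselines are the alphabetically first
  levels (in practice: female, and the first family).
* Random intercepts are nested: one per biogeographic region
  (`a_r ~ N(0, σ_r²)`), and one per species-within-region *unit*
  (`b ~ N(0, σ_s² Σ)`). A species sampled in two regions contributes
  two units, matching the `(1 | region/species)` nesting of mixed-model
  formula notation.
* The phylogenetic variant sets `Σ` to the tip correlation of a
  chronogram (shared root-to-MRCA path length, normalized to unit
  diagonal); the taxonomic variant uses `Σ = I`. On a star tree the two
  coincide, which the tests verify draw-for-draw.

### Priors

The model is fully Bayesian with weakly-informative defaults, all
overridable through the `priors` argument:

| parameter | prior | default |
|---|---|---|
| ln-scale intercept | Normal(0, `intercept_sd`²) | `intercept_sd = 5` |
| slopes/offsets | Normal(0, `coef_sd`²) | `coef_sd = 2` |
| σ, σ_r, σ_s | half-Normal(0, `sd_scale`²) | `sd_scale = 1` |

These scales dominate nothing at the data sizes involved (ln dry weight
spans roughly −2…6; allometric exponents sit near 1–3).

### Inference

Gaussian likelihood plus Gaussian coefficient priors means everything
except the SDs integrates out in closed form. Writing
`W = [X | Z_region | Z_unit L]` (with `L` the Cholesky factor of `Σ`)
and `D` the diagonal of prior variances, the marginal likelihood of
`ln y ~ N(0, σ²I + W D Wᵀ)` is evaluated through an m×m Woodbury
factorization (m = number of columns of `W`, typically < 100), so one
evaluation costs microseconds after the one-off Gram-matrix
precomputation.

The 1–3 log-SD parameters are sampled with an affine-invariant ensemble
sampler (emcee; differential-evolution plus snooker moves, which mix
markedly better than the default stretch move here). The chain default
mirrors the common 2000-iteration / 1000-burn-in split with 4 chains of
4 walkers each. For each stored SD draw, the coefficients and random
intercepts are drawn exactly from their Gaussian conditional
`N(A⁻¹Wᵀy/σ², A⁻¹)` with `A = WᵀW/σ² + D⁻¹` — so the stored joint
draws are exact posterior samples, there are no divergent transitions,
and the only approximation is Monte Carlo error.

Convergence is assessed with split-R̂ treating each walker as a chain;
a fit with any R̂ > 1.05 is flagged (warning plus `converged = False`),
never silently returned. `MCMCSettings` retains `adapt_delta` and
`max_tree_depth` for interface compatibility with gradient-based
samplers; the ensemble sampler ignores them.

### Prediction

Per posterior draw, the ln-scale linear predictor is formed and
exponentiated; the point estimate is the posterior **median** on the mg
scale (invariant under the exp transform), the SE is the posterior SD,
and the 90% interval the 5%/95% quantiles. Unseen species are
integrated over `N(0, σ_s²)` — or, in the phylogenetic model, over
their Brownian conditional given the sampled effects of the training
species when the new species is a tip of the tree. Unseen regions are
integrated over the region distribution with a warning. Unseen *fixed*
levels (group, sex) are errors: a fixed effect has no population to
integrate over. Registry-equation predictions use lognormal quantiles
from the equation's residual SD when one is recorded; otherwise they
are point-only and flagged as such. An optional `exp(σ²/2)` smearing
(mean) correction exists for equations, off by default.

## Model selection

* **Bayesian R²**: per draw, `Var(η)/(Var(η) + σ²)` with `η` the full
  linear predictor including fitted random intercepts.
* **Grouped K-fold CV**: folds partition *species* (seeded permutation
  dealt round-robin, fold sizes differing by ≤ 1), so every held-out
  specimen belongs to a species unseen in training. The score is
  −2 × Σ held-out log predictive density (deviance scale, lower
  better), with the held-out species' intercept integrated analytically
  into the predictive variance (times the Brownian conditional variance
  factor for phylogenetic fits). The per-specimen score is a declared
  convention: log predictive density rather than squared error.
* **RMSE** on the mg scale from posterior-median predictions.
  Comparison tables carry all three plus Δ(K-CV) versus the best model.

## Phylogenetic pipeline

* **Grafting**: each genus tip with S ≥ 2 assigned species becomes a
  polytomy; species tip length = `fraction` (default 0.5) of the genus
  terminal edge, stem shortened by the same amount, so all root-to-tip
  depths are preserved exactly and congeners are equidistant. The
  phrase "equal branch length relative to the genus branch" admits
  several readings; the depth-preserving one keeps the tree ultrametric
  and the genus-level covariance untouched, which is why it is the
  default (and the fraction is exposed). Phylogenetic structure below
  the genus level is deliberately flat.
* **Chronogram**: penalized likelihood with correlated rates — Poisson
  branch-length log-likelihood `Σ x_j ln(r_j t_j) − r_j t_j` minus
  `smoothing ×` the sum of squared rate differences between adjacent
  edges (plus the variance of the root's child-edge rates). Node ages
  are parametrized as per-node fractions of the parent age (root fixed
  at 1, so output lengths are relative time and the result is exactly
  ultrametric); rates are log-parametrized; L-BFGS-B optimizes both,
  initialized clock-like. `smoothing` defaults to 1.0 and is exposed —
  the right value is data-dependent and published analyses rarely
  report it. Failures raise with the objective trace attached.
* **Pagel's λ**: ML under `V(λ) = λC + (1−λ) diag(C)` with the
  ancestral mean and Brownian rate profiled analytically and λ
  maximized on [0, 1] by bounded Brent search (endpoints checked). The
  LR test against λ = 0 uses χ²(1) by default; a 50:50 boundary mixture
  is available by flag since λ = 0 lies on the parameter boundary. A
  non-ultrametric tree is an explicit error (the diagonal-preserving
  rescaling would conflate depth variation with signal), so the
  chronogram step is required first. The implementation matches an
  independent ML implementation (phytools' `phylosig`) to ~1e-5 in λ
  and log-likelihood on a frozen fixture.
* A tiny ridge (1e-9 × mean tip depth) stabilizes the Cholesky at
  λ = 1, where near-zero branch lengths make tips numerically
  identical.

## Intraspecific analyses

Per-species, per-sex OLS of ln W on ln ITD (≥ 4 specimens required —
fewer leaves the slope F-test with ≤ 1 residual df). The adequacy curve
resamples n = 1…N subsamples *without replacement* (100 replicates,
seeded): the adequate sample size is the smallest n from which the
2.5–97.5% envelope of subsample means stays inside the full-sample
95% t-interval for every larger n. The envelope, not the replicate
average, carries the information — the average of many subsample means
is near the grand mean at any n, so a criterion on it would declare a
single specimen adequate. Under lognormal noise with CV ≈ 0.3 and
N = 60 the criterion lands at n ≈ 31, consistent with the 20–30
specimens reported for real bee traits.

## Synthetic data

`GeneratorTruth` defines a study: species grouped into families, each
species endemic to one region, per-species lognormal ITD (median 2 mm,
ln-SD 0.45, specimen jitter ln-SD 0.08), and
`ln W = ln α(group, sex) + β(group, sex) ln ITD + region + species +
noise` with defaults β = 2.6, male offset −0.3, and region/species/
residual SDs 0.2/0.4/0.3 — inside the exponent and variability ranges
seen in real bee data. Defaults are 3 regions × 4 families ×
10 species × 10 specimens (40 species, 400 records). Named substreams
(assignment, ITD, effects, noise, body length) keep draws stable when
fields are added. Trees come from a unit-depth pure-birth genus
backbone with grafted polytomies; traits evolve as λ-scaled Brownian
motion.

What the generator does *not* emulate: measurement error in ITD,
specimen damage or pollen-load contamination, unbalanced real-world
abundances (1–201 specimens per species), taxonomic misidentification,
and any mismatch between taxonomy and phylogeny. Passing validation
therefore establishes correctness of the machinery under its own
assumptions, not the field accuracy of any particular coefficient
table; those require fitting the real deposited specimen data.

## Validation studies and problem sizes

`beescale.validation` (run by the tests and by `scripts/acceptance.py`)
uses: 20 recovery seeds at the default 40 × 10 condition with
1200/600-iteration chains; 10 CV-ranking replicates (2 families ×
10 species × 6 specimens, k = 4, 400/200 chains) comparing the model
with vs without the generative sex effect; calibration over 10
independent worlds × 100 unseen-species predictions (coverage measured
against each record's true noise-free conditional mean); 20 λ-recovery
replicates on 100-tip trees; and 100/1000-instance oracle checks.
Chains are shortened relative to the production default to keep a full
run in the minutes range; the recovery and calibration results are
insensitive to this because the marginalized posterior is 3-dimensional
and mixes quickly.

## Known limitations

* Lognormal residuals only; no gamma or heteroscedastic alternatives.
* The sampler is exact for this model family but would not extend to
  non-Gaussian likelihoods without replacing the marginalization.
* Unsexed specimens are not a third sex level; sex-models require
  known sex.
* Pin-weight standard errors are recorded but not propagated into
  model uncertainty.
* The chronogram optimizer uses numerical gradients; very large trees
  (thousands of tips) would need an analytic-gradient implementation.
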