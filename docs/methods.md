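# Methods

## The harmonization model

Observed features follow a location/scale model per site: for subject *j*
at site *i* and feature *v*,

    y_ijv = α_v + X_ij β_v + γ_iv + δ_iv ε_ijv,   ε_ijv ~ N(0, σ_v²).

Site effects are assumed exchangeable across features within a site, with
parametric priors γ_iv ~ N(γ_i, τ_i²) and δ_iv² ~ InverseGamma(λ_i, θ_i)
(shape/scale; mean θ/(λ−1)). Empirical Bayes exploits this: thousands of
noisy per-feature estimates inform site-level priors, and the per-feature
estimates are shrunk toward them, trading a little bias for a large
variance reduction when per-site sample sizes are small.

Assumptions worth keeping in mind: additive + multiplicative site action
(no feature-by-site interactions beyond location/scale), Gaussian noise,
linear covariate effects shared across sites, and site memberships known
exactly.

## Fitting conventions

Several numerical conventions are unstated in most descriptions of the
method; this package fixes them as follows.

- **Identifiability.** The design codes sites by cell means (one indicator
  per site, no intercept) plus covariate columns. The overall level α̂_v is
  the n_i/N-weighted mean of the site intercepts, i.e. site effects are
  constrained to a zero weighted mean. Covariates are uncentered (the
  back-transform adds X β̂ directly, so centering would only relabel α̂).
- **Pooled σ̂_v.** σ̂_v² = (1/N) Σ_ij (y_ijv − α̂_v − X_ij β̂_v)² — the
  pooled variance of the standardization numerator, denominator N. This
  makes standardized data satisfy pooled mean 0 and pooled variance 1
  exactly (a property the test suite asserts at 1e-8). Note this pools the
  site-effect variance into σ̂; conventions that subtract γ̂ first differ
  from it by a per-feature scale factor common to all sites, which cancels
  in every cross-site comparison.
- **Variance denominators.** δ̂²_iv uses the unbiased within-site variance
  (n_i − 1); τ̂_i² the across-feature variance of γ̂_iv with V − 1.
- **Moment inversion.** From the across-feature mean m and variance s² of
  δ̂²_iv: λ = (m² + 2s²)/s², θ = (m³ + m s²)/s². If s² = 0 the prior is
  degenerate; the site falls back to its per-feature estimates with a
  warning.
- **EB iteration.** Starting at (γ̂, δ̂²), alternate
  γ* = (n τ² γ̂ + δ²* γ̄)/(n τ² + δ²*) and
  δ²* = (θ + ½ Σ_j (z_j − γ*)²)/(n/2 + λ − 1), where the inner sum uses
  the identity Σ(z−γ*)² = (n−1)δ̂² + n(γ̂−γ*)². Convergence: maximum
  relative change of both arrays < 1e-4 (floor 1e-8 on the denominator),
  cap 1000 iterations; a long-iteration oracle in the tests confirms the
  fixed point to 1e-3. At the fixed point γ* is a convex combination of
  γ̂ and γ̄, so shrinkage never overshoots.
- **Constant features.** Features whose pooled residual SD is below
  1e-12 × max(|α̂|, 1) are flagged, excluded from standardization and EB,
  and passed through the transform unchanged.
- **Degenerate site counts.** Fitting needs ≥ 2 subjects per site. A
  single-site fit is permitted with a warning — the transform is then a
  near no-op (only shrinkage noise), which the tests verify — because it
  is occasionally useful as a sanity check.

## Transfer (saved-parameter application)

`fit_combat` returns its harmonized training data by applying the
just-fitted model through the same code path as `apply_transfer`, so
transfer on the training data reproduces the training output bit-exactly.
New subjects are standardized with the saved (α̂, β̂, σ̂) and transformed
with the saved (γ*, δ*) of their site; an unseen site label is a hard
error (a transfer model is never silently refit), and covariate values
outside the training range are allowed — the linear covariate model
extrapolates.

The archive is one `.npz` file: a `manifest` entry holding a JSON string
(format name, version, site registry in order, covariate schema with
codings, feature ids, fit options) plus one named float64 array per model
field (`alpha` (V,), `beta` (C,V), `sigma` (V,), `constant_feature_mask`
(V,), `gamma_bar`/`tau2`/`lambda_`/`theta`/`degenerate` (S,),
`gamma_star`/`delta_star` (S,V), `eb_iterations`/`eb_converged` (S,)).
Arrays round-trip value-exactly; no subject-level data is ever stored, so
archives can be shared across institutions.

## Evaluation metrics

- **Site-difference rate**: percentage of features whose two-sided
  two-sample t-test across the two sites has p < α (default 0.05,
  pooled-variance Student by default, Welch behind a flag). No
  multiple-comparison correction — the rate itself, compared with the
  nominal α, is the quantity of interest. Features with zero variance in
  both groups are excluded with a warning.
- **PwFC**: fraction of one performance distribution's samples strictly
  below the 95th percentile (linear interpolation) of a reference
  distribution; ≈ 0.95 for a continuous distribution against itself.
- **Overlap index η**: both samples get a Gaussian KDE (Scott bandwidth),
  evaluated on a shared 4096-point grid spanning the union of supports
  padded by 3 bandwidths; each density is renormalized by trapezoidal
  integration and η = ∫ min(f̂_a, f̂_b), clipped to [0, 1]. KDE details
  differ across software, so η comparisons carry a ±0.02 tolerance; the
  implementation reproduces the equal-variance normal closed form
  2Φ(−d/2) within that tolerance at 1e5 draws.
- **Cohort statistics**: Pearson chi-squared independence (no continuity
  correction), Welch t from summary statistics (Satterthwaite df),
  pooled-z two-proportion test (Fisher exact behind a flag), Wilcoxon
  rank-sum (exact enumeration when n₁+n₂ ≤ 12 and tie-free, otherwise the
  tie-corrected normal approximation without continuity correction, so the
  two branches agree in the limit), OLS coefficient reports, and the
  partial F test F = ((RSS_r − RSS_f)/q)/(RSS_f/df_f).

## In-sample versus held-out assessment

Harmonization estimates site means from the very data it adjusts, so the
site-difference rate measured *on the training data itself* collapses far
below the nominal α even when no true site effect exists (the fitted
residual site mean is only (1−w) of the empirical one, and the empirical
one was rarely significant to begin with). This is a property of the
method, not a defect of an implementation. Calibration claims in this
package are therefore stated on held-out subjects: a model is fitted on a
training cohort and applied by transfer to fresh subjects from the same
generative world, whose rate is then compared to the nominal level. On a
null world this held-out rate is α plus a small inflation from the
shrinkage noise injected by the transferred parameters, vanishing as the
training cohort grows (≈ 5.5% at 100 training subjects per site, α = 5%).
The acceptance script reports the in-sample rate alongside, so the
deflation is visible rather than hidden.

For the full-refit ("full ComBat") ceiling, held-out assessment is
impossible by definition; following the study protocol, groups of
`n_test` per site are resampled from the harmonized pool. Such groups are
partially in-sample: their rate is deflated by roughly √(1 − n_test/N_pool)
on the t scale. The synthetic sweep world therefore uses 300 subjects per
site so that 20-per-site resampled groups are effectively fresh (≈ 3%
deflation on t); with small pools the ceiling would read artificially low.

## Monte-Carlo protocols and seeding

`run_train_sweep` varies the training size over a grid; each iteration
draws a disjoint stratified train/test split, fits on the training group,
transfers to the test group, and records the rate (voxel level, or ROI
level after atlas averaging). The unharmonized baseline uses raw
test-size groups; the ceiling resamples from the full-refit harmonized
pool. `run_combined_sweep` escalates the test size and applies the
full-harmonization criterion — at least 95% of iterations with under 5%
of features significant — on the pooled train+test subjects, reporting
the largest contiguously passing test size. `run_within_site_baseline`
draws two disjoint groups from one site (the chance level) and compares
the resulting distribution to the ceiling by rank-sum test.
`unharmonized_frequency_map` accumulates per-feature rejection
frequencies across transfer iterations.

Every driver takes a `master_seed`; iteration k of stream s uses
`SeedSequence(master_seed, spawn_key=(s, k))`, so full runs are exactly
reproducible and any single iteration can be replayed in isolation.
Defaults mirror the study-scale protocol (training grid 50–110 per site,
test groups of 20 per site, 1000 sweep / 500 combined / 5000 baseline
iterations); tests and the acceptance script run scaled-down versions
(grids of 3 sizes, 10–50 iterations, 300–2000 features), which keeps every
Monte-Carlo comparison to trend and band assertions rather than tight
point estimates.

## Synthetic worlds

The generator draws data from the model above — it is the model's own
generative form, so parameter-recovery tests are well-posed. Named
two-site worlds provide calibrated regimes, anchored to magnitudes
observed in real two-site adolescent DTI cohorts (FA baseline ≈ 0.456,
site coefficient ≈ 0.02, age slope ≈ 0.002/yr, sex offset ≈ 0.008, ages
uniform on 12–21, balanced sex):

| world | additive γ_i | τ_i | δ² prior (λ, mean) | covariates |
|---|---|---|---|---|
| `null` | 0 / 0 | 0 | (400, 1.0) both | none (β = 0) |
| `moderate` | +0.010 / −0.010 | 0.005 | (30, 1.15) vs (30, 0.87) | age, sex |
| `strong` | +0.025 / −0.025 | 0.010 | (20, 1.30) vs (20, 0.75) | age, sex |
| `prior_violating` | as moderate | 0.005 | as moderate | age, sex |

α_v ~ U(0.1, 0.8), σ_v ~ U(0.04, 0.06) per feature. The `strong` gap of
0.05 against within-site noise ≈ 0.05 yields a per-feature effect size
d ≈ 1, so a majority of features reject at 30 subjects per site — the
regime in which harmonization matters. `prior_violating` plants 1% of
features at 6 prior SDs from the site mean; these resist shrinkage-based
harmonization and surface in the frequency map, illustrating the EB
prior's failure mode. Inverse-gamma draws use reciprocal Gamma(λ, 1/θ)
variates.

Realized multiplicative effects are only identified up to a per-feature
scale common to all sites (it is absorbed by σ̂), so recovery reports
score δ* on the across-site log scale after removing the per-feature mean;
additive effects are scored in data units (σ̂ γ*) against the
weighted-centered truth.

What the generator does **not** emulate: spatial autocorrelation between
voxels (features are independent given the priors), partial-volume mixing
at tissue boundaries, registration error, site-by-covariate interactions,
non-Gaussian noise, or realistic covariate–site confounding. Passing
tests therefore demonstrate correctness and calibration of the method
under its own assumptions, not performance on real acquisitions.

## Known limitations

- Linear covariate model only; no GAM/nonlinear age effects, no
  longitudinal or reference-batch variants, no refitting at transfer time
  (all out of scope by design).
- Transfer to a site absent from the registry is refused rather than
  approximated.
- η depends mildly on KDE bandwidth; values are comparable within this
  package but only approximately across toolkits.
- The EB prior assumes exchangeable site effects across features; features
  whose true effects sit far outside the prior are under-corrected (see
  the `prior_violating` world).
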