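# tcombat

Transferable ComBat harmonization of multisite imaging feature matrices.

Measurements pooled across MRI scanners — voxel-wise fractional anisotropy
(FA) or mean diffusivity (MD) maps, ROI averages, radiomics features —
carry systematic scanner/site effects that can dwarf the biological signal.
ComBat removes them with an empirical-Bayes location/scale model.
`tcombat` implements the full chain and, crucially, makes it
*transferable*: the fitted harmonization parameters are saved to a small
archive (no subject data inside) and applied unchanged to new subjects
scanned at the same sites, so a study can harmonize incoming data without
refitting on — or even having access to — the original cohort.

## Model

For subject *j* at site *i* and feature *v*:

```
y_ijv = α_v + X_ij β_v + γ_iv + δ_iv ε_ijv ,   ε_ijv ~ N(0, σ_v²)
```

with α_v the overall level, X_ij β_v covariate effects (age, sex), γ_iv an
additive and δ_iv a multiplicative site effect. Fitting proceeds by

1. OLS for (α̂_v, β̂_v, σ̂_v) under the constraint that site effects have
   zero n_i/N-weighted mean;
2. standardization `z_ijv = (y_ijv − α̂_v − X_ij β̂_v)/σ̂_v`;
3. method-of-moments hyperpriors `γ_iv ~ N(γ_i, τ_i²)`,
   `δ_iv² ~ InvGamma(λ_i, θ_i)` pooled across features;
4. empirical-Bayes posterior means (γ*_iv, δ*_iv), iterated to a fixed
   point;

and the harmonized value is

```
y_ijv^ComBat = σ̂_v / δ*_iv · (z_ijv − γ*_iv) + α̂_v + X_ij β_v̂ .
```

Transfer application re-runs steps 2 and the final transform on new
subjects using only the saved parameters.

The package also ships the evaluation toolkit used to judge harmonization:
feature-wise site-difference rates (two-sample t-tests at α = 0.05),
ROI averaging against an integer atlas, the PwFC statistic and the
distribution-overlap index η, Monte-Carlo sweep drivers, cohort
comparability statistics, a synthetic two-site generator with known ground
truth, and a NIfTI bridge for voxel-wise use.

## Worked example

```python
import tcombat as tc

params = tc.default_world("strong", n_per_site=30, n_features=2000)
data, truth = tc.simulate_dataset(params, seed=7)

before = tc.site_difference_rate(data, alpha=0.05)
model, harmonized = tc.fit_combat(data, tc.CovariateSchema(names=("age", "sex")))
after = tc.site_difference_rate(harmonized, alpha=0.05)
print(f"before {before:.1f}%  after {after:.1f}%")
```

prints

```
before 88.3%  after 0.7%
```

88.3% of the 2000 simulated features differed significantly across sites
before harmonization (the "strong" world's site effect dominates); after
harmonization essentially none do — below the nominal 5% because the test
is applied to the same subjects the site effects were estimated from.
Assessed on *held-out* subjects harmonized by transfer, the rate settles
near the nominal 5% (see `examples/transfer_to_new_subjects.py`, which
prints `78.1% -> 7.6%` for a 20-per-site test group with 100 training
subjects per site).

Each script in `examples/` demonstrates one capability end to end:
simulation + fitting, archive save/load + transfer, the training-size
sweep, cohort comparability statistics, and NIfTI volume handling. A thin
CLI covers the shell workflow: `tcombat fit`, `tcombat apply`,
`tcombat simulate`.

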