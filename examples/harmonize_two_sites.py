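"""Fit ComBat harmonization on a simulated two-site cohort.

Simulates an FA-like dataset with a strong additive/multiplicative site
effect, fits the empirical-Bayes harmonization, and reports the percentage
of features significantly different across sites before and after.  A rate
far above 5% before and near or below 5% after means the site effect
dominated the raw data and was removed.
"""

import tcombat as tc

params = tc.default_world("strong", n_per_site=30, n_features=2000)
data, truth = tc.simulate_dataset(params, seed=7)

before = tc.site_difference_rate(data, alpha=0.05)
model, harmonized = tc.fit_combat(data, tc.CovariateSchema(names=("age", "sex")))
after = tc.site_difference_rate(harmonized, alpha=0.05)

print(f"features significantly different across sites (p < 0.05):")
print(f"  before harmonization: {before:.1f}%")
print(f"  after harmonization:  {after:.1f}%")
print(f"EB iterations per site: {model.eb.iterations.tolist()}")
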