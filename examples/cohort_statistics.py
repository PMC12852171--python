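"""Demographic comparability tests for a two-site cohort.

Before harmonizing, one checks that the two site cohorts are demographically
similar: a two-sample t-test on age (from summary statistics), a pooled-z
two-proportion test on sex, and a chi-squared independence test on the
ethnicity table.  p > 0.05 means no detectable difference.
"""

import numpy as np

import tcombat as tc

# per-site summaries: (mean age, sd, n) and male counts
t, p_age = tc.welch_t_summary(16.0, 2.4, 180, 16.2, 2.6, 134)
p_sex = tc.two_proportion_test(93, 180, 67, 134)
ethnicity = np.array([[1, 1], [18, 11], [0, 3], [11, 1], [128, 111], [22, 7]])
stat, df, p_eth = tc.chi2_independence(ethnicity)

print(f"age:       t = {t:.3f}, p = {p_age:.3f}  ({'ok' if p_age > 0.05 else 'differs'})")
print(f"sex:       p = {p_sex:.3f}  ({'ok' if p_sex > 0.05 else 'differs'})")
print(f"ethnicity: chi2 = {stat:.2f}, df = {df}, p = {p_eth:.3f}"
      f"  ({'ok' if p_eth > 0.05 else 'differs'})")
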