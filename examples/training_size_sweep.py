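"""How transfer harmonization quality depends on training-group size.

Runs a scaled-down Monte-Carlo sweep: for each training size, repeatedly
split the pool, fit on the training group, transfer to a fresh 20-per-site
test group, and measure the site-difference rate.  The unharmonized
baseline and the full-refit ceiling bracket the transfer results; PwFC and
the overlap index eta quantify how close transfer comes to the ceiling
(both 1 when indistinguishable).
"""

import tcombat as tc

params = tc.default_world("strong", n_per_site=300, n_features=1000)
data, _ = tc.simulate_dataset(params, seed=3)

cfg = tc.SweepConfig(
    n_train_grid=(20, 40, 80),
    n_test=20,
    iterations=30,
    baseline_iterations=30,
    master_seed=3,
)
res = tc.run_train_sweep(data, cfg)

print(f"unharmonized median rate: {res.unharmonized.median():.1f}%")
print(f"full-refit ceiling median: {res.full_combat.median():.1f}%")
for n in cfg.n_train_grid:
    m = res.metrics[n]
    print(
        f"n_train={n:3d}: median {res.transfer[n].median():5.1f}%  "
        f"PwFC {m.pwfc:.2f}  eta {m.eta:.2f}"
    )
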