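import numpy as np
import pandas as pd
import pytest

import tcombat as tc


@pytest.fixture
def schema():
    return tc.CovariateSchema(names=("age", "sex"))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_random_dataset(
    rng, n_per_site=(12, 10), n_features=5, sites=("A", "B"), site_gap=0.02
):
    """Small two-site dataset with covariate and site effects plus noise."""
    rows_y, rows_s, rows_age, rows_sex = [], [], [], []
    alpha = rng.uniform(0.2, 0.7, n_features)
    for s, n, g in zip(sites, n_per_site, (site_gap / 2, -site_gap / 2)):
        age = rng.uniform(12, 21, n)
        sex = (rng.random(n) < 0.5).astype(float)
        y = (
            alpha
            + 0.002 * age[:, None]
            + 0.008 * sex[:, None]
            + g
            + rng.normal(0, 0.05, (n, n_features))
        )
        rows_y.append(y)
        rows_s.append(np.full(n, s))
        rows_age.append(age)
        rows_sex.append(sex)
    return tc.FeatureDataset(
        values=np.vstack(rows_y),
        site=np.concatenate(rows_s),
        covariates=pd.DataFrame(
            {"age": np.concatenate(rows_age), "sex": np.concatenate(rows_sex)}
        ),
        feature_ids=tuple(f"f{v}" for v in range(n_features)),
    )


@pytest.fixture
def small_dataset(rng):
    return make_random_dataset(rng)


@pytest.fixture
def moderate_fit(schema):
    """A moderate-world simulation plus its fitted model and harmonized data."""
    params = tc.default_world("moderate", n_per_site=30, n_features=300)
    data, truth = tc.simulate_dataset(params, 77)
    model, harmonized = tc.fit_combat(data, schema)
    return params, data, truth, model, harmonized
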