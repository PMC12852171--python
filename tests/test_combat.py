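import numpy as np
import pandas as pd
import pytest

import tcombat as tc
from tcombat.combat import invgamma_moments
from tcombat.dataset import build_design

from conftest import make_random_dataset


def _fit_parts(dataset, schema):
    design = build_design(dataset, schema)
    ls = tc.fit_ls_model(dataset, design)
    std = tc.standardize(dataset, design, ls)
    se = tc.estimate_site_effects(std, design)
    return design, ls, std, se


class TestLSFit:
    def test_constant_data_flagged(self):
        d = tc.FeatureDataset(
            values=np.full((6, 2), 5.0),
            site=np.full(6, "A"),
            covariates=pd.DataFrame(index=range(6)),
            feature_ids=("a", "b"),
        )
        design = build_design(d, tc.CovariateSchema())
        ls = tc.fit_ls_model(d, design)
        np.testing.assert_allclose(ls.alpha, 5.0)
        np.testing.assert_allclose(ls.sigma, 0.0, atol=1e-12)
        assert ls.constant_feature_mask.all()

    def test_translation_equivariance(self, small_dataset, schema):
        design = build_design(small_dataset, schema)
        ls = tc.fit_ls_model(small_dataset, design)
        shifted = tc.FeatureDataset(
            values=small_dataset.values + 3.7,
            site=small_dataset.site,
            covariates=small_dataset.covariates,
            feature_ids=small_dataset.feature_ids,
        )
        ls2 = tc.fit_ls_model(shifted, build_design(shifted, schema))
        np.testing.assert_allclose(ls2.alpha, ls.alpha + 3.7, atol=1e-10)
        np.testing.assert_allclose(ls2.beta, ls.beta, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng, schema):
        d = make_random_dataset(rng, n_per_site=(7, 5), n_features=4)
        design, ls, _, _ = _fit_parts(d, schema)
        # independent oracle: per-feature normal equations on the raw
        # cell-means design, then the weighted-zero site-effect constraint
        X = design.matrix
        XtX_inv = np.linalg.inv(X.T @ X)
        w = np.asarray(design.n_per_site) / d.n_subjects
        for v in range(d.n_features):
            coef = XtX_inv @ X.T @ d.values[:, v]
            alpha_v = w @ coef[:2]
            beta_v = coef[2:]
            resid = d.values[:, v] - alpha_v - design.covariate_block @ beta_v
            sigma_v = np.sqrt(np.mean(resid**2))
            assert abs(ls.alpha[v] - alpha_v) <= 1e-10 * max(1, abs(alpha_v))
            np.testing.assert_allclose(ls.beta[:, v], beta_v, rtol=1e-10)
            assert abs(ls.sigma[v] - sigma_v) <= 1e-10 * sigma_v

    def test_rank_deficient_design_errors(self, small_dataset):
        schema = tc.CovariateSchema(names=("age", "age2"))
        cov = small_dataset.covariates.copy()
        cov["age2"] = cov["age"] * 2.0  # exactly collinear
        d = tc.FeatureDataset(
            values=small_dataset.values,
            site=small_dataset.site,
            covariates=cov,
            feature_ids=small_dataset.feature_ids,
        )
        with pytest.raises(ValueError, match="rank deficient"):
            tc.fit_ls_model(d, build_design(d, schema))


class TestStandardize:
    def test_zero_residual_gives_zero_z(self, small_dataset, schema):
        design, ls, _, _ = _fit_parts(small_dataset, schema)
        fitted = ls.alpha[None, :] + design.covariate_block @ ls.beta
        exact = tc.FeatureDataset(
            values=fitted,
            site=small_dataset.site,
            covariates=small_dataset.covariates,
            feature_ids=small_dataset.feature_ids,
        )
        z = tc.standardize(exact, design, ls).z
        np.testing.assert_allclose(z, 0.0, atol=1e-12)

    def test_self_standardization_pooled_moments(self, rng, schema):
        d = make_random_dataset(rng, n_per_site=(20, 15), n_features=8)
        _, _, std, _ = _fit_parts(d, schema)
        assert np.abs(std.z.mean(axis=0)).max() <= 1e-8
        assert np.abs((std.z**2).mean(axis=0) - 1.0).max() <= 1e-8

    def test_matches_elementwise_oracle(self, small_dataset, schema):
        design, ls, std, _ = _fit_parts(small_dataset, schema)
        for j in range(small_dataset.n_subjects):
            for v in range(small_dataset.n_features):
                expect = (
                    small_dataset.values[j, v]
                    - ls.alpha[v]
                    - design.covariate_block[j] @ ls.beta[:, v]
                ) / ls.sigma[v]
                assert abs(std.z[j, v] - expect) <= 1e-10


class TestSiteEffects:
    def test_constant_within_site(self):
        z = np.vstack([np.full((3, 2), 1.0), np.full((4, 2), -1.0)])
        d = tc.FeatureDataset(
            values=z,
            site=np.array(["A"] * 3 + ["B"] * 4),
            covariates=pd.DataFrame(index=range(7)),
            feature_ids=("a", "b"),
        )
        design = build_design(d, tc.CovariateSchema())
        se = tc.estimate_site_effects(tc.StandardizedData(z=z), design)
        np.testing.assert_allclose(se.gamma_hat[0], 1.0)
        np.testing.assert_allclose(se.gamma_hat[1], -1.0)
        np.testing.assert_allclose(se.delta2_hat, 0.0)

    def test_matches_groupby_oracle(self, rng, schema):
        d = make_random_dataset(rng, n_per_site=(9, 6), n_features=4)
        design, _, std, se = _fit_parts(d, schema)
        for i, s in enumerate(design.site_order):
            zi = std.z[np.asarray(d.site) == s]
            np.testing.assert_allclose(se.gamma_hat[i], zi.mean(axis=0), atol=1e-12)
            np.testing.assert_allclose(
                se.delta2_hat[i], zi.var(axis=0, ddof=1), atol=1e-12
            )

    def test_single_subject_site_errors(self):
        z = np.ones((3, 2))
        d = tc.FeatureDataset(
            values=z,
            site=np.array(["A", "A", "B"]),
            covariates=pd.DataFrame(index=range(3)),
            feature_ids=("a", "b"),
        )
        design = build_design(d, tc.CovariateSchema())
        with pytest.raises(ValueError, match="fewer than 2 subjects"):
            tc.estimate_site_effects(tc.StandardizedData(z=z), design)


class TestHyperparameters:
    def test_moment_inversion_closed_form(self):
        lam, theta = invgamma_moments(2.0, 1.0)
        assert lam == pytest.approx(6.0, abs=1e-12)
        assert theta == pytest.approx(10.0, abs=1e-12)
        # plug back into the inverse-gamma mean and variance
        assert theta / (lam - 1) == pytest.approx(2.0, abs=1e-12)
        assert theta**2 / ((lam - 1) ** 2 * (lam - 2)) == pytest.approx(1.0, abs=1e-12)

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(12)
        d2 = 1.0 / rng.gamma(shape=4.0, scale=1.0 / 6.0, size=100_000)
        lam, theta = invgamma_moments(d2.mean(), d2.var(ddof=1))
        # 3 Monte-Carlo standard errors at this sample size
        assert abs(lam - 4.0) < 3 * 0.062
        assert abs(theta - 6.0) < 3 * 0.121

    def test_equal_gamma_hat_gives_zero_tau2(self):
        se = tc.SiteEffectEstimates(
            gamma_hat=np.full((2, 5), 0.3),
            delta2_hat=np.tile(np.array([1.0, 2.0, 3.0, 1.5, 2.5]), (2, 1)),
            n_per_site=np.array([10, 10]),
        )
        pr = tc.estimate_hyperparameters(se)
        np.testing.assert_allclose(pr.gamma_bar, 0.3)
        np.testing.assert_allclose(pr.tau2, 0.0)

    def test_degenerate_prior_flagged(self):
        se = tc.SiteEffectEstimates(
            gamma_hat=np.array([[0.1, 0.2, 0.3]]),
            delta2_hat=np.full((1, 3), 2.0),
            n_per_site=np.array([10]),
        )
        with pytest.warns(UserWarning, match="degenerate prior"):
            pr = tc.estimate_hyperparameters(se)
        assert pr.degenerate[0]


class TestEBPosterior:
    def test_zero_tau2_forces_prior_mean(self, rng, schema):
        d = make_random_dataset(rng, n_per_site=(10, 10), n_features=6)
        design, _, std, se = _fit_parts(d, schema)
        pr = tc.estimate_hyperparameters(se)
        pr0 = tc.PriorHyperparameters(
            gamma_bar=pr.gamma_bar,
            tau2=np.zeros_like(pr.tau2),
            lambda_=pr.lambda_,
            theta=pr.theta,
            degenerate=pr.degenerate,
        )
        eb = tc.eb_posterior_means(std, se, pr0)
        for i in range(2):
            np.testing.assert_allclose(eb.gamma_star[i], pr.gamma_bar[i], atol=1e-12)

    def test_shrinkage_between_empirical_and_prior(self, moderate_fit):
        _, data, _, model, _ = moderate_fit
        design, _, std, se = _fit_parts(data, tc.CovariateSchema(names=("age", "sex")))
        lo = np.minimum(se.gamma_hat, model.priors.gamma_bar[:, None])
        hi = np.maximum(se.gamma_hat, model.priors.gamma_bar[:, None])
        assert np.all(model.eb.gamma_star >= lo - 1e-12)
        assert np.all(model.eb.gamma_star <= hi + 1e-12)

    def test_agrees_with_long_iteration_oracle(self, rng, schema):
        d = make_random_dataset(rng, n_per_site=(15, 12), n_features=20)
        design, ls, std, se = _fit_parts(d, schema)
        pr = tc.estimate_hyperparameters(se)
        eb = tc.eb_posterior_means(std, se, pr, tc.FitOptions(eb_tol=1e-4))
        # brute-force oracle: 10000 fixed-count iterations of the same updates
        for i in range(2):
            n = se.n_per_site[i]
            g = se.gamma_hat[i].copy()
            d2 = se.delta2_hat[i].copy()
            ss0 = (n - 1) * se.delta2_hat[i]
            for _ in range(10_000):
                g = (n * pr.tau2[i] * se.gamma_hat[i] + d2 * pr.gamma_bar[i]) / (
                    n * pr.tau2[i] + d2
                )
                d2 = (pr.theta[i] + 0.5 * (ss0 + n * (se.gamma_hat[i] - g) ** 2)) / (
                    n / 2 + pr.lambda_[i] - 1
                )
            assert np.abs(eb.gamma_star[i] - g).max() <= 1e-3
            assert np.abs(eb.delta_star[i] ** 2 - d2).max() <= 1e-3


class TestHarmonize:
    def test_shape_and_metadata_preserved(self, moderate_fit):
        _, data, _, _, harmonized = moderate_fit
        assert harmonized.values.shape == data.values.shape
        assert harmonized.feature_ids == data.feature_ids
        assert list(harmonized.site) == list(data.site)

    def test_constant_features_pass_through(self, rng, schema):
        d = make_random_dataset(rng, n_per_site=(10, 10), n_features=6)
        values = d.values.copy()
        values[:, 2] = 0.42
        d2 = tc.FeatureDataset(
            values=values,
            site=d.site,
            covariates=d.covariates,
            feature_ids=d.feature_ids,
        )
        _, harmonized = tc.fit_combat(d2, schema)
        np.testing.assert_array_equal(harmonized.values[:, 2], values[:, 2])

    def test_single_site_is_near_identity(self, schema):
        params = tc.SimulationParams(
            n_features=1000,
            n_per_site={"s1": 50},
            site_priors={"s1": tc.SitePrior(0.0, 0.0, 400.0, 399.0)},
        )
        data, _ = tc.simulate_dataset(params, 9)
        with pytest.warns(UserWarning, match="single site"):
            model, harmonized = tc.fit_combat(data, schema)
        change = np.abs(harmonized.values - data.values).mean()
        assert change < 0.1 * np.median(model.ls.sigma)


class TestFitCombat:
    def test_deterministic(self, rng, schema):
        d = make_random_dataset(rng, n_per_site=(15, 15), n_features=30)
        m1, h1 = tc.fit_combat(d, schema)
        m2, h2 = tc.fit_combat(d, schema)
        assert np.array_equal(h1.values, h2.values)
        assert np.array_equal(m1.eb.gamma_star, m2.eb.gamma_star)

    def test_transfer_reproduces_training_output(self, moderate_fit):
        _, data, _, model, harmonized = moderate_fit
        again = tc.apply_transfer(model, data)
        assert np.abs(again.values - harmonized.values).max() <= 1e-12

    def test_refit_on_harmonized_output_is_contraction(self, schema):
        params = tc.default_world("strong", n_per_site=30, n_features=500)
        data, _ = tc.simulate_dataset(params, 31)
        _, h1 = tc.fit_combat(data, schema)
        _, h2 = tc.fit_combat(h1, schema)
        first = np.abs(h1.values - data.values).mean()
        second = np.abs(h2.values - h1.values).mean()
        assert second < first

    def test_covariate_effect_preserved(self, schema):
        # true age slope recovered within its 95% CI in >= 90% of replicates
        params = tc.default_world("moderate", n_per_site=30, n_features=100)
        covered = 0
        n_rep = 100
        for r in range(n_rep):
            rng = np.random.default_rng(np.random.SeedSequence(55, spawn_key=(r,)))
            data, truth = tc.simulate_dataset(params, rng)
            _, harmonized = tc.fit_combat(data, schema)
            rep = tc.covariate_regression(
                harmonized.values.mean(axis=1),
                pd.DataFrame(
                    {
                        "age": data.covariates["age"],
                        "sex": data.covariates["sex"],
                    }
                ),
            )
            ci = rep.coef("age") + np.array([-1.96, 1.96]) * float(
                rep.table.loc["age", "se"]
            )
            if ci[0] <= truth.beta[0].mean() <= ci[1]:
                covered += 1
        assert covered >= 0.9 * n_rep
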