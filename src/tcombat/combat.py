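"""ComBat empirical-Bayes harmonization: model fit and transform.

The observed measurement for subject ``j`` at site ``i`` and feature ``v`` is
modelled as

    y_ijv = alpha_v + X_ij beta_v + gamma_iv + delta_iv * eps_ijv

with ``eps_ijv ~ N(0, sigma_v^2)``: ``alpha_v`` the overall level,
``beta_v`` covariate effects, ``gamma_iv`` an additive and ``delta_iv`` a
multiplicative site effect.  Fitting proceeds in four stages:

1. ordinary least squares for (alpha, beta, sigma) with site effects
   constrained to a zero n_i/N-weighted mean;
2. standardization z_ijv = (y_ijv - alpha_v - X_ij beta_v) / sigma_v;
3. method-of-moments hyperparameters for the site-effect priors
   gamma_iv ~ N(gamma_i, tau_i^2), delta_iv^2 ~ InverseGamma(lambda_i,
   theta_i), pooling information across features;
4. empirical-Bayes site-effect estimates (gamma*, delta*) as the fixed point
   of the coupled conditional-posterior-mean updates.

The harmonized value removes the shrunken site effects and restores the
biological signal:

    y_ijv^ComBat = sigma_v / delta*_iv * (z_ijv - gamma*_iv)
                   + alpha_v + X_ij beta_v

``sigma_v`` here is the pooled standard deviation of the standardization
numerator (denominator N), so that z has pooled mean 0 and pooled variance 1
by construction when fit and standardization use the same data.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .dataset import CovariateSchema, DesignMatrix, FeatureDataset, build_design

__all__ = [
    "LSEstimates",
    "StandardizedData",
    "SiteEffectEstimates",
    "PriorHyperparameters",
    "EBEstimates",
    "FitOptions",
    "CombatModel",
    "fit_ls_model",
    "standardize",
    "estimate_site_effects",
    "estimate_hyperparameters",
    "eb_posterior_means",
    "harmonize",
    "fit_combat",
]

# Features whose pooled residual SD falls below this (relative to the data
# scale) are treated as constant: excluded from standardization/EB and passed
# through the transform unchanged.
_CONSTANT_REL_TOL = 1e-12


@dataclasses.dataclass(frozen=True)
class LSEstimates:
    """Least-squares stage output: per-feature alpha, beta and pooled sigma."""

    alpha: np.ndarray            # (V,)
    beta: np.ndarray             # (C, V)
    sigma: np.ndarray            # (V,) pooled residual SD, denominator N
    constant_feature_mask: np.ndarray  # (V,) bool, True = flagged constant

    @property
    def residual_variance(self) -> np.ndarray:
        return self.sigma**2


@dataclasses.dataclass(frozen=True)
class StandardizedData:
    z: np.ndarray  # (N, V); zero in flagged columns


@dataclasses.dataclass(frozen=True)
class SiteEffectEstimates:
    gamma_hat: np.ndarray    # (S, V) within-site mean of z
    delta2_hat: np.ndarray   # (S, V) within-site variance of z (ddof=1)
    n_per_site: np.ndarray   # (S,)


@dataclasses.dataclass(frozen=True)
class PriorHyperparameters:
    """Per-site prior hyperparameters estimated by the method of moments.

    ``gamma_bar``/``tau2`` are the across-feature mean and variance of the
    additive effects; ``lambda_``/``theta`` solve the inverse-gamma moment
    equations for the multiplicative effects.  ``degenerate`` flags sites
    whose delta2_hat had zero across-feature variance (no EB pooling there).
    """

    gamma_bar: np.ndarray  # (S,)
    tau2: np.ndarray       # (S,)
    lambda_: np.ndarray    # (S,)
    theta: np.ndarray      # (S,)
    degenerate: np.ndarray  # (S,) bool

    def __post_init__(self):
        finite_var = self.lambda_ > 2
        if not np.all(finite_var | self.degenerate):
            warnings.warn(
                "inverse-gamma shape lambda <= 2 for some site: the prior has "
                "no finite variance; EB shrinkage may be weak",
                stacklevel=2,
            )


@dataclasses.dataclass(frozen=True)
class EBEstimates:
    gamma_star: np.ndarray   # (S, V)
    delta_star: np.ndarray   # (S, V) posterior multiplicative effect (SD scale)
    iterations: np.ndarray   # (S,)
    converged: np.ndarray    # (S,) bool


@dataclasses.dataclass(frozen=True)
class FitOptions:
    eb_tol: float = 1e-4
    eb_max_iter: int = 1000
    # variance denominators: sigma^2 uses N; delta2_hat uses n_i - 1; tau2
    # uses V - 1 (documented convention; see the methods note)

    def to_dict(self) -> dict:
        return {"eb_tol": self.eb_tol, "eb_max_iter": self.eb_max_iter}


@dataclasses.dataclass(frozen=True)
class CombatModel:
    """Everything needed to harmonize new subjects from known sites."""

    ls: LSEstimates
    priors: PriorHyperparameters
    eb: EBEstimates
    site_registry: tuple[str, ...]
    covariate_schema: CovariateSchema
    feature_ids: tuple[str, ...]
    fit_options: FitOptions

    def __post_init__(self):
        s = len(self.site_registry)
        v = len(self.feature_ids)
        if self.eb.gamma_star.shape != (s, v):
            raise ValueError("eb arrays inconsistent with registry/features")
        if self.ls.alpha.shape != (v,):
            raise ValueError("ls arrays inconsistent with features")


def fit_ls_model(dataset: FeatureDataset, design: DesignMatrix) -> LSEstimates:
    """OLS for the location model; sigma is the pooled SD of y - alpha - X beta.

    The design's site block is cell-means coded, so the raw solution carries
    one intercept per site; the identifiability constraint (site effects have
    zero n_i/N-weighted mean) reduces it to a single overall level alpha.
    """
    X = design.matrix
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} subjects for {p} parameters")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError("design matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(X, dataset.values, rcond=None)
    n_sites = len(design.site_order)
    site_coef = coef[:n_sites]                      # per-site intercepts
    beta = coef[n_sites:]
    weights = np.asarray(design.n_per_site, float) / n
    alpha = weights @ site_coef
    fitted = alpha[None, :] + design.covariate_block @ beta
    resid = dataset.values - fitted
    sigma = np.sqrt(np.mean(resid**2, axis=0))      # denominator N
    scale = np.maximum(np.abs(alpha), 1.0)
    constant = sigma <= _CONSTANT_REL_TOL * scale
    return LSEstimates(
        alpha=alpha, beta=beta, sigma=sigma, constant_feature_mask=constant
    )


def standardize(
    dataset: FeatureDataset, design: DesignMatrix, ls: LSEstimates
) -> StandardizedData:
    """z_ijv = (y_ijv - alpha_v - X_ij beta_v) / sigma_v; flagged columns -> 0."""
    keep = ~ls.constant_feature_mask
    if np.any((ls.sigma == 0) & keep):
        raise ValueError("sigma is zero for an unflagged feature")
    fitted = ls.alpha[None, :] + design.covariate_block @ ls.beta
    z = np.zeros_like(dataset.values)
    z[:, keep] = (dataset.values[:, keep] - fitted[:, keep]) / ls.sigma[keep]
    return StandardizedData(z=z)


def estimate_site_effects(
    std: StandardizedData, design: DesignMatrix
) -> SiteEffectEstimates:
    """Within-site mean and unbiased variance of z for every site × feature."""
    idx = design.site_index()
    n_sites = len(design.site_order)
    V = std.z.shape[1]
    gamma_hat = np.empty((n_sites, V))
    delta2_hat = np.empty((n_sites, V))
    counts = np.empty(n_sites, dtype=int)
    for i in range(n_sites):
        zi = std.z[idx == i]
        if zi.shape[0] < 2:
            raise ValueError(
                f"site {design.site_order[i]!r} has fewer than 2 subjects"
            )
        counts[i] = zi.shape[0]
        gamma_hat[i] = zi.mean(axis=0)
        delta2_hat[i] = zi.var(axis=0, ddof=1)
    return SiteEffectEstimates(
        gamma_hat=gamma_hat, delta2_hat=delta2_hat, n_per_site=counts
    )


def invgamma_moments(mean: float, variance: float) -> tuple[float, float]:
    """Inverse-gamma (shape, scale) matching a given mean and variance.

    Solves theta/(lambda-1) = mean and theta^2/((lambda-1)^2 (lambda-2)) =
    variance: lambda = (m^2 + 2 s^2)/s^2, theta = (m^3 + m s^2)/s^2.
    """
    if variance <= 0:
        raise ValueError("variance must be positive for moment inversion")
    lam = (mean**2 + 2.0 * variance) / variance
    theta = (mean**3 + mean * variance) / variance
    return lam, theta


def estimate_hyperparameters(
    se: SiteEffectEstimates,
    constant_feature_mask: np.ndarray | None = None,
) -> PriorHyperparameters:
    """Method-of-moments priors from the across-feature spread of the effects."""
    keep = (
        np.ones(se.gamma_hat.shape[1], bool)
        if constant_feature_mask is None
        else ~constant_feature_mask
    )
    if keep.sum() < 2:
        raise ValueError("need at least 2 non-constant features for priors")
    g = se.gamma_hat[:, keep]
    d2 = se.delta2_hat[:, keep]
    gamma_bar = g.mean(axis=1)
    tau2 = g.var(axis=1, ddof=1)
    m = d2.mean(axis=1)
    s2 = d2.var(axis=1, ddof=1)
    n_sites = len(gamma_bar)
    lam = np.empty(n_sites)
    theta = np.empty(n_sites)
    degenerate = s2 <= 0
    for i in range(n_sites):
        if degenerate[i]:
            warnings.warn(
                "across-feature variance of delta2_hat is zero for site index "
                f"{i}: degenerate prior, falling back to per-feature estimates",
                stacklevel=2,
            )
            lam[i] = np.inf
            theta[i] = np.inf
        else:
            lam[i], theta[i] = invgamma_moments(m[i], s2[i])
    return PriorHyperparameters(
        gamma_bar=gamma_bar, tau2=tau2, lambda_=lam, theta=theta,
        degenerate=degenerate,
    )


def eb_posterior_means(
    std: StandardizedData,
    se: SiteEffectEstimates,
    pr: PriorHyperparameters,
    options: FitOptions = FitOptions(),
    constant_feature_mask: np.ndarray | None = None,
) -> EBEstimates:
    """Iterate the coupled conditional-posterior-mean updates to a fixed point.

    Starting from the empirical (gamma_hat, delta2_hat), alternate

        gamma* = (n tau^2 gamma_hat + delta2* gamma_bar) / (n tau^2 + delta2*)
        delta2* = (theta + 0.5 sum_j (z_j - gamma*)^2) / (n/2 + lambda - 1)

    until the maximum relative change of both arrays drops below ``eb_tol``.
    At the fixed point gamma* is a convex combination of gamma_hat and the
    prior mean, so it always lies weakly between them.
    """
    S, V = se.gamma_hat.shape
    keep = (
        np.ones(V, bool) if constant_feature_mask is None else ~constant_feature_mask
    )
    gamma_star = se.gamma_hat.copy()
    delta2_star = se.delta2_hat.copy()
    iters = np.zeros(S, dtype=int)
    converged = np.zeros(S, dtype=bool)
    n = se.n_per_site.astype(float)
    # sum_j (z_j - g)^2 = (n-1) delta2_hat + n (gamma_hat - g)^2
    ssd0 = (n[:, None] - 1.0) * se.delta2_hat
    for i in range(S):
        if pr.degenerate[i]:
            # no pooling possible across features: keep empirical estimates
            converged[i] = True
            continue
        g = gamma_star[i, keep]
        d2 = delta2_star[i, keep]
        g_hat = se.gamma_hat[i, keep]
        ss0 = ssd0[i, keep]
        ni, t2 = n[i], pr.tau2[i]
        gb, lam, th = pr.gamma_bar[i], pr.lambda_[i], pr.theta[i]
        for it in range(1, options.eb_max_iter + 1):
            g_new = (ni * t2 * g_hat + d2 * gb) / (ni * t2 + d2)
            d2_new = (th + 0.5 * (ss0 + ni * (g_hat - g_new) ** 2)) / (
                ni / 2.0 + lam - 1.0
            )
            change = max(
                np.max(np.abs(g_new - g) / np.maximum(np.abs(g), 1e-8)),
                np.max(np.abs(d2_new - d2) / np.maximum(np.abs(d2), 1e-8)),
            )
            g, d2 = g_new, d2_new
            if change < options.eb_tol:
                converged[i] = True
                break
        iters[i] = it
        gamma_star[i, keep] = g
        delta2_star[i, keep] = d2
        if not converged[i]:
            warnings.warn(
                f"EB updates did not converge for site index {i} within "
                f"{options.eb_max_iter} iterations",
                stacklevel=2,
            )
    delta_star = np.sqrt(np.maximum(delta2_star, 0.0))
    return EBEstimates(
        gamma_star=gamma_star, delta_star=delta_star, iterations=iters,
        converged=converged,
    )


def harmonize(
    dataset: FeatureDataset, design: DesignMatrix, model: CombatModel
) -> FeatureDataset:
    """Apply the harmonization transform using the model's saved parameters.

    y^ComBat = sigma_v / delta*_iv * (z_ijv - gamma*_iv) + alpha_v + X beta_v.
    Constant (flagged) features pass through unchanged.
    """
    if tuple(dataset.feature_ids) != tuple(model.feature_ids):
        raise ValueError("feature_ids do not match the fitted model")
    ls = model.ls
    std = standardize(dataset, design, ls)
    idx = design.site_index()
    keep = ~ls.constant_feature_mask
    gamma = model.eb.gamma_star[idx][:, keep]       # (N, Vk)
    delta = model.eb.delta_star[idx][:, keep]
    fitted = ls.alpha[None, :] + design.covariate_block @ ls.beta
    out = dataset.values.copy()
    out[:, keep] = (
        ls.sigma[keep][None, :] / delta * (std.z[:, keep] - gamma)
        + fitted[:, keep]
    )
    return FeatureDataset(
        values=out,
        site=dataset.site.copy(),
        covariates=dataset.covariates.copy(),
        feature_ids=dataset.feature_ids,
        subject_ids=dataset.subject_ids,
    )


def fit_combat(
    dataset: FeatureDataset,
    schema: CovariateSchema = CovariateSchema(),
    options: FitOptions = FitOptions(),
) -> tuple[CombatModel, FeatureDataset]:
    """Fit the full chain and return (model, harmonized training data).

    Deterministic: the fit path involves no randomness.  The harmonized
    training data is produced by the same transform later used for transfer,
    so applying the model back to its training data reproduces it exactly.
    """
    dataset.validate_for_fit(min_sites=1)
    if len(dataset.sites) < 2:
        warnings.warn(
            "fitting on a single site: harmonization is a near no-op",
            stacklevel=2,
        )
    design = build_design(dataset, schema)
    ls = fit_ls_model(dataset, design)
    std = standardize(dataset, design, ls)
    se = estimate_site_effects(std, design)
    priors = estimate_hyperparameters(se, ls.constant_feature_mask)
    eb = eb_posterior_means(std, se, priors, options, ls.constant_feature_mask)
    model = CombatModel(
        ls=ls,
        priors=priors,
        eb=eb,
        site_registry=design.site_order,
        covariate_schema=schema,
        feature_ids=dataset.feature_ids,
        fit_options=options,
    )
    harmonized = harmonize(dataset, design, model)
    return model, harmonized
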