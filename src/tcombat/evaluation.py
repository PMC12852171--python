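"""Harmonization-quality metrics and the study's supporting statistics.

The central quality measure is the *site-difference rate*: the percentage of
features whose values differ significantly between the two sites by a
two-sample t-test at a given alpha, without multiple-comparison correction
(the rate itself, compared to the nominal alpha, is the quantity of
interest: well-harmonized null data should reject at about alpha).

Two distribution-comparison metrics summarise how close a transfer-
harmonization performance distribution comes to the full-refit ceiling:

* ``pwfc`` — the proportion of performance samples below the 95th percentile
  of the reference (full-refit) performance distribution;
* ``overlap_index`` — eta, the integral of the pointwise minimum of two
  kernel density estimates (1 = identical distributions, 0 = disjoint).

The remaining functions are the cohort-level statistics used to establish
demographic comparability and covariate relevance: chi-squared independence,
two-sample t from summaries, two-proportion z, Wilcoxon rank-sum, multiple
linear regression reports and the partial F test.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.stats.proportion import proportions_ztest

from .dataset import FeatureDataset

__all__ = [
    "PerformanceDistribution",
    "AtlasLabels",
    "OverlapMetrics",
    "site_difference_rate",
    "two_group_rate",
    "roi_average",
    "pwfc",
    "overlap_index",
    "chi2_independence",
    "welch_t_summary",
    "two_proportion_test",
    "rank_sum_test",
    "covariate_regression",
    "RegressionReport",
    "partial_f_test",
]


@dataclasses.dataclass(frozen=True)
class PerformanceDistribution:
    """Per-iteration percentages of significantly different features."""

    values: np.ndarray
    level: str = "voxel"  # "voxel" or "roi"

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, float))
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a nonempty 1-D array")
        if np.any((self.values < 0) | (self.values > 100)):
            raise ValueError("percentages must lie in [0, 100]")

    @property
    def n_iterations(self) -> int:
        return self.values.size

    def median(self) -> float:
        return float(np.median(self.values))


@dataclasses.dataclass(frozen=True)
class AtlasLabels:
    """Per-feature non-negative integer ROI id; 0 = background/excluded."""

    labels: np.ndarray
    roi_names: dict[int, str] | None = None

    def __post_init__(self):
        object.__setattr__(self, "labels", np.asarray(self.labels, int))
        if np.any(self.labels < 0):
            raise ValueError("ROI labels must be non-negative")
        if not np.any(self.labels > 0):
            raise ValueError("atlas has no nonzero ROI labels")

    def roi_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclasses.dataclass(frozen=True)
class OverlapMetrics:
    eta: float
    pwfc: float

    def __post_init__(self):
        if not (0 <= self.eta <= 1 and 0 <= self.pwfc <= 1):
            raise ValueError("eta and pwfc must lie in [0, 1]")


def two_group_rate(
    a: np.ndarray,
    b: np.ndarray,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> float:
    """Percentage of features with p < alpha in a feature-wise two-sample t-test.

    ``a`` and ``b`` are group × feature matrices.  Features with zero
    variance in both groups have an undefined t statistic and are excluded
    with a warning.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 subjects")
    degenerate = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
    if degenerate.any():
        warnings.warn(
            f"excluding {int(degenerate.sum())} zero-variance feature(s) from "
            "the site-difference rate",
            stacklevel=2,
        )
        a = a[:, ~degenerate]
        b = b[:, ~degenerate]
    if a.shape[1] == 0:
        raise ValueError("no testable features remain")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = st.ttest_ind(a, b, axis=0, equal_var=equal_var)
    p = np.asarray(res.pvalue)
    return float(np.mean(p < alpha) * 100.0)


def site_difference_rate(
    data: FeatureDataset, alpha: float = 0.05, equal_var: bool = True
) -> float:
    """Percentage of features significantly different between the two sites."""
    sites = data.sites
    if len(sites) != 2:
        raise ValueError(f"expected exactly 2 sites, found {len(sites)}")
    mask = data.site.astype(str) == sites[0]
    return two_group_rate(
        data.values[mask], data.values[~mask], alpha=alpha, equal_var=equal_var
    )


def roi_average(data: FeatureDataset, atlas: AtlasLabels) -> FeatureDataset:
    """Average features within each nonzero ROI; one output column per ROI."""
    if len(atlas.labels) != data.n_features:
        raise ValueError("atlas length must match the number of features")
    ids = atlas.roi_ids()
    cols = np.empty((data.n_subjects, ids.size))
    names = []
    for k, rid in enumerate(ids):
        member = atlas.labels == rid
        cols[:, k] = data.values[:, member].mean(axis=1)
        if atlas.roi_names and int(rid) in atlas.roi_names:
            names.append(atlas.roi_names[int(rid)])
        else:
            names.append(f"roi_{int(rid)}")
    return FeatureDataset(
        values=cols,
        site=data.site.copy(),
        covariates=data.covariates.copy(),
        feature_ids=tuple(names),
        subject_ids=data.subject_ids,
    )


def pwfc(
    tc: PerformanceDistribution | np.ndarray,
    fc: PerformanceDistribution | np.ndarray,
) -> float:
    """Proportion of ``tc`` samples strictly below the 95th percentile of ``fc``.

    The percentile uses linear interpolation; "below" is a strict
    inequality.  For a continuous distribution compared with itself the
    result is therefore about 0.95.
    """
    tcv = tc.values if isinstance(tc, PerformanceDistribution) else np.asarray(tc, float)
    fcv = fc.values if isinstance(fc, PerformanceDistribution) else np.asarray(fc, float)
    if tcv.size == 0 or fcv.size == 0:
        raise ValueError("empty performance distribution")
    q95 = np.percentile(fcv, 95.0)
    return float(np.mean(tcv < q95))


def overlap_index(a: Sequence[float], b: Sequence[float]) -> float:
    """Overlap index eta between two samples via Gaussian KDEs.

    Both densities are estimated with a Gaussian kernel (Scott's automatic
    bandwidth), evaluated on a shared grid spanning the union of supports
    padded by 3 bandwidths (4096 points), renormalized to integrate to 1 by
    the trapezoid rule, and eta = integral of the pointwise minimum, clipped
    to [0, 1].
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 10 or b.size < 10:
        raise ValueError("need at least 10 samples in each set")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("degenerate (zero-variance) sample set")
    kde_a = st.gaussian_kde(a)
    kde_b = st.gaussian_kde(b)
    bw_a = np.sqrt(kde_a.covariance[0, 0])
    bw_b = np.sqrt(kde_b.covariance[0, 0])
    lo = min(a.min() - 3 * bw_a, b.min() - 3 * bw_b)
    hi = max(a.max() + 3 * bw_a, b.max() + 3 * bw_b)
    grid = np.linspace(lo, hi, 4096)
    fa = kde_a(grid)
    fb = kde_b(grid)
    fa /= np.trapezoid(fa, grid)
    fb /= np.trapezoid(fb, grid)
    eta = np.trapezoid(np.minimum(fa, fb), grid)
    return float(np.clip(eta, 0.0, 1.0))


def chi2_independence(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on an r × c count table.

    Returns (statistic, degrees of freedom, upper-tail p); no continuity
    correction.
    """
    table = np.asarray(table, float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has a zero row or column sum")
    stat, p, df, _ = st.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)


def welch_t_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, float]:
    """Two-sided two-sample t-test from summary statistics (Welch/Satterthwaite df)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")
    res = st.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def two_proportion_test(
    k1: int, n1: int, k2: int, n2: int, exact: bool = False
) -> float:
    """Two-sided test of equal proportions; pooled-variance z by default.

    ``exact=True`` uses Fisher's exact test on the 2 x 2 table instead.
    """
    if n1 == 0 or n2 == 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    if exact:
        table = [[k1, n1 - k1], [k2, n2 - k2]]
        return float(st.fisher_exact(table, alternative="two-sided")[1])
    _, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    return float(p)


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p value.

    Exact enumeration when n1 + n2 <= 12 and there are no ties; otherwise
    the normal approximation with tie correction (and continuity correction
    disabled so the exact and asymptotic branches agree in the limit).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= 12 and no_ties) else "asymptotic"
    res = st.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.pvalue)


@dataclasses.dataclass(frozen=True)
class RegressionReport:
    """Per-predictor OLS coefficient table plus fit summaries."""

    table: pd.DataFrame       # index: predictor; columns: coef, se, t, p
    rss: float
    df_resid: int
    n: int
    predictors: tuple[str, ...]

    def coef(self, name: str) -> float:
        return float(self.table.loc[name, "coef"])


def covariate_regression(
    y: Sequence[float], covariates: pd.DataFrame
) -> RegressionReport:
    """OLS of a per-subject scalar on covariates, with a coefficient report.

    Two-level non-numeric columns are coded 0/1 (sorted order).  The report
    gives the coefficient, standard error, t statistic and two-sided p for
    each predictor including the intercept.
    """
    y = np.asarray(y, float)
    X = pd.DataFrame(index=range(len(covariates)))
    for c in covariates.columns:
        col = covariates[c].reset_index(drop=True)
        if not pd.api.types.is_numeric_dtype(col):
            levels = sorted(col.unique())
            if len(levels) != 2:
                raise ValueError(
                    f"non-numeric covariate {c!r} must have exactly 2 levels"
                )
            col = col.map({levels[0]: 0.0, levels[1]: 1.0})
        X[c] = col.astype(float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    Xd = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xd.to_numpy()) < Xd.shape[1]:
        raise ValueError("collinear predictors")
    fit = sm.OLS(y, Xd).fit()
    table = pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    return RegressionReport(
        table=table,
        rss=float(fit.ssr),
        df_resid=int(fit.df_resid),
        n=len(y),
        predictors=tuple(Xd.columns),
    )


def partial_f_test(full: RegressionReport, reduced: RegressionReport) -> tuple[float, float]:
    """Partial F test of a reduced model nested within a full model.

    F = ((RSS_r - RSS_f)/q) / (RSS_f / df_f) with q the number of dropped
    predictors; returns (F, upper-tail p).
    """
    if full.n != reduced.n:
        raise ValueError("models were fit on different subject counts")
    q = reduced.df_resid - full.df_resid
    if q <= 0 or not set(reduced.predictors) <= set(full.predictors):
        raise ValueError("reduced model is not nested in the full model")
    if full.rss <= 0:
        raise ValueError("full model has zero residual sum of squares")
    F = ((reduced.rss - full.rss) / q) / (full.rss / full.df_resid)
    p = float(st.f.sf(F, q, full.df_resid))
    return float(F), p
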