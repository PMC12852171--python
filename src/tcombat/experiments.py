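"""Monte-Carlo drivers for the harmonization evaluation protocols.

Four protocols, all built on repeated stratified subsampling of a two-site
pool:

* :func:`run_train_sweep` — vary the training-group size, fit on the
  training group, transfer to a fresh test group, and record the
  site-difference rate per iteration; compare the resulting performance
  distributions against an unharmonized baseline and a full-refit
  ("full ComBat") ceiling via PwFC and the overlap index.
* :func:`run_combined_sweep` — grow the test group and ask how large it can
  get while the combined (training + test) pool still meets the
  harmonization criterion (at least 95% of iterations with under 5% of
  features significantly different).
* :func:`run_within_site_baseline` — the chance level: two groups drawn
  from the *same* site, establishing the rate distribution attributable to
  sampling alone.
* :func:`unharmonized_frequency_map` — per-feature frequency (over
  iterations) of remaining significantly different after transfer, the
  map-level view of which features resist harmonization.

Reproducibility: every driver takes a ``master_seed``; iteration ``k`` of a
driver uses ``numpy.random.SeedSequence(master_seed, spawn_key=(stream,
k))`` where ``stream`` indexes the driver's independent random streams, so
runs are reproducible and individual iterations can be replayed.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .combat import CovariateSchema, FitOptions, fit_combat
from .dataset import FeatureDataset
from .evaluation import (
    AtlasLabels,
    OverlapMetrics,
    PerformanceDistribution,
    overlap_index,
    pwfc,
    rank_sum_test,
    roi_average,
    site_difference_rate,
)
from .transfer import apply_transfer

__all__ = [
    "SweepConfig",
    "SweepResult",
    "make_split",
    "run_train_sweep",
    "run_combined_sweep",
    "run_within_site_baseline",
    "unharmonized_frequency_map",
    "meets_harmonization_criterion",
]


@dataclasses.dataclass(frozen=True)
class SweepConfig:
    """Protocol configuration; defaults follow the study-scale protocol."""

    n_train_grid: tuple[int, ...] = (50, 60, 70, 80, 90, 100, 110)
    n_test: int = 20
    n_test_grid: tuple[int, ...] = (2, 5, 10, 15, 20, 25)
    iterations: int = 1000
    baseline_iterations: int = 5000
    combined_iterations: int = 500
    alpha: float = 0.05
    master_seed: int = 0
    level: str = "voxel"           # "voxel" or "roi"
    criterion_proportion: float = 0.95
    criterion_rate: float = 5.0    # percent of features
    covariates: tuple[str, ...] = ("age", "sex")
    fit_options: FitOptions = FitOptions()

    def __post_init__(self):
        if any(n <= 0 for n in self.n_train_grid) or any(
            np.diff(self.n_train_grid) < 0
        ):
            raise ValueError("n_train_grid must be positive and non-decreasing")
        if self.iterations < 1 or self.baseline_iterations < 1:
            raise ValueError("iteration counts must be >= 1")

    def schema(self) -> CovariateSchema:
        return CovariateSchema(names=self.covariates)


@dataclasses.dataclass(frozen=True)
class SweepResult:
    """Per-grid-point performance distributions and overlap metrics."""

    n_train_grid: tuple[int, ...]
    transfer: dict[int, PerformanceDistribution]
    metrics: dict[int, OverlapMetrics]
    unharmonized: PerformanceDistribution
    full_combat: PerformanceDistribution
    level: str


def _rng(master_seed: int, stream: int, k: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(stream, k))
    )


def make_split(
    dataset: FeatureDataset,
    n_train: int,
    n_test: int,
    rng: np.random.Generator,
) -> tuple[FeatureDataset, FeatureDataset]:
    """Disjoint per-site stratified random train/test split of exact sizes."""
    sites = np.asarray(dataset.site, dtype=str)
    train_rows: list[np.ndarray] = []
    test_rows: list[np.ndarray] = []
    for s in dataset.sites:
        pool = np.flatnonzero(sites == s)
        if pool.size < n_train + n_test:
            raise ValueError(
                f"site {s!r} has {pool.size} subjects; "
                f"{n_train}+{n_test} requested"
            )
        pick = rng.permutation(pool)[: n_train + n_test]
        train_rows.append(pick[:n_train])
        test_rows.append(pick[n_train:])
    return (
        dataset.subset(np.concatenate(train_rows)),
        dataset.subset(np.concatenate(test_rows)),
    )


def _rate(data: FeatureDataset, config: SweepConfig, atlas: AtlasLabels | None) -> float:
    if config.level == "roi":
        if atlas is None:
            raise ValueError("ROI-level assessment requires an atlas")
        data = roi_average(data, atlas)
    return site_difference_rate(data, alpha=config.alpha)


def _sample_groups(
    dataset: FeatureDataset, per_site: int, rng: np.random.Generator
) -> FeatureDataset:
    """Random per-site subsample of exact size from every site."""
    sites = np.asarray(dataset.site, dtype=str)
    rows = []
    for s in dataset.sites:
        pool = np.flatnonzero(sites == s)
        if pool.size < per_site:
            raise ValueError(f"site {s!r} pool smaller than {per_site}")
        rows.append(rng.permutation(pool)[:per_site])
    return dataset.subset(np.concatenate(rows))


def full_combat_baseline(
    dataset: FeatureDataset,
    config: SweepConfig,
    atlas: AtlasLabels | None = None,
) -> tuple[FeatureDataset, PerformanceDistribution]:
    """Refit on the whole pool, then resample test-size groups from it.

    Returns the pool harmonized by a full refit and the rate distribution of
    ``baseline_iterations`` random groups of ``n_test`` per site drawn from
    that pool — the performance ceiling transfer harmonization is judged
    against.
    """
    _, harmonized = fit_combat(dataset, config.schema(), config.fit_options)
    rates = np.empty(config.baseline_iterations)
    for k in range(config.baseline_iterations):
        group = _sample_groups(harmonized, config.n_test, _rng(config.master_seed, 1, k))
        rates[k] = _rate(group, config, atlas)
    return harmonized, PerformanceDistribution(rates, level=config.level)


def run_train_sweep(
    dataset: FeatureDataset,
    config: SweepConfig,
    atlas: AtlasLabels | None = None,
) -> SweepResult:
    """Transfer performance as a function of training-group size."""
    counts = dataset.site_counts()
    need = max(config.n_train_grid) + config.n_test
    short = {s: c for s, c in counts.items() if c < need}
    if short:
        raise ValueError(f"insufficient per-site pool for the sweep: {short}")

    # unharmonized baseline: rate on raw test-size groups
    un = np.empty(config.iterations)
    for k in range(config.iterations):
        group = _sample_groups(dataset, config.n_test, _rng(config.master_seed, 0, k))
        un[k] = _rate(group, config, atlas)

    _, fc = full_combat_baseline(dataset, config, atlas)

    transfer: dict[int, PerformanceDistribution] = {}
    metrics: dict[int, OverlapMetrics] = {}
    for g, n_train in enumerate(config.n_train_grid):
        rates = np.empty(config.iterations)
        for k in range(config.iterations):
            rng = _rng(config.master_seed, 10 + g, k)
            train, test = make_split(dataset, n_train, config.n_test, rng)
            model, _ = fit_combat(train, config.schema(), config.fit_options)
            rates[k] = _rate(apply_transfer(model, test), config, atlas)
        tc = PerformanceDistribution(rates, level=config.level)
        transfer[n_train] = tc
        metrics[n_train] = OverlapMetrics(
            eta=overlap_index(tc.values, fc.values), pwfc=pwfc(tc, fc)
        )
    return SweepResult(
        n_train_grid=config.n_train_grid,
        transfer=transfer,
        metrics=metrics,
        unharmonized=PerformanceDistribution(un, level=config.level),
        full_combat=fc,
        level=config.level,
    )


def meets_harmonization_criterion(
    rates: Sequence[float],
    proportion: float = 0.95,
    rate_threshold: float = 5.0,
) -> bool:
    """True when at least ``proportion`` of iteration rates fall below
    ``rate_threshold`` percent of features."""
    rates = np.asarray(rates, float)
    if rates.size == 0:
        raise ValueError("empty rate list")
    return bool(np.mean(rates < rate_threshold) >= proportion)


def run_combined_sweep(
    dataset: FeatureDataset,
    config: SweepConfig,
    atlas: AtlasLabels | None = None,
) -> dict[int, int | None]:
    """Largest test-group size keeping the combined pool fully harmonized.

    For each training size, every test size on the grid is evaluated (the
    whole grid is run even after a failure, and non-monotone pass patterns
    are reported via the contiguous rule): ``combined_iterations`` trials of
    split → fit on train → transfer to test → rate on the pooled
    train + test subjects.  The returned value per training size is the
    largest grid value reachable through contiguously passing sizes, or
    ``None`` if even the smallest fails.
    """
    out: dict[int, int | None] = {}
    for g, n_train in enumerate(config.n_train_grid):
        passed: list[bool] = []
        for t, n_test in enumerate(config.n_test_grid):
            rates = np.empty(config.combined_iterations)
            for k in range(config.combined_iterations):
                rng = _rng(config.master_seed, 100 + 10 * g + t, k)
                train, test = make_split(dataset, n_train, n_test, rng)
                model, train_h = fit_combat(
                    train, config.schema(), config.fit_options
                )
                test_h = apply_transfer(model, test)
                combined = FeatureDataset(
                    values=np.vstack([train_h.values, test_h.values]),
                    site=np.concatenate([train_h.site, test_h.site]),
                    covariates=pd.concat(
                        [train_h.covariates, test_h.covariates],
                        ignore_index=True,
                    ),
                    feature_ids=dataset.feature_ids,
                    subject_ids=train_h.subject_ids + test_h.subject_ids,
                )
                rates[k] = _rate(combined, config, atlas)
            passed.append(
                meets_harmonization_criterion(
                    rates, config.criterion_proportion, config.criterion_rate
                )
            )
        best: int | None = None
        for t, ok in enumerate(passed):
            if ok:
                best = config.n_test_grid[t]
            else:
                break
        out[n_train] = best
    return out


def run_within_site_baseline(
    dataset: FeatureDataset,
    config: SweepConfig,
    full_combat: PerformanceDistribution | None = None,
    atlas: AtlasLabels | None = None,
) -> dict[str, dict]:
    """Rate distribution for two same-site groups, per site.

    The chance-level baseline: how often do two groups of ``n_test``
    subjects drawn from one site differ, with no site effect at all in
    play?  If a full-refit ceiling distribution is supplied, each site's
    baseline is compared against it with a two-sided Wilcoxon rank-sum
    test.
    """
    from .evaluation import two_group_rate

    sites = np.asarray(dataset.site, dtype=str)
    out: dict[str, dict] = {}
    for si, s in enumerate(dataset.sites):
        pool = np.flatnonzero(sites == s)
        if pool.size < 2 * config.n_test:
            raise ValueError(
                f"site {s!r} needs at least {2 * config.n_test} subjects"
            )
        rates = np.empty(config.baseline_iterations)
        for k in range(config.baseline_iterations):
            rng = _rng(config.master_seed, 200 + si, k)
            pick = rng.permutation(pool)[: 2 * config.n_test]
            g1 = dataset.values[pick[: config.n_test]]
            g2 = dataset.values[pick[config.n_test:]]
            if config.level == "roi":
                if atlas is None:
                    raise ValueError("ROI-level assessment requires an atlas")
                ids = atlas.roi_ids()
                g1 = np.column_stack(
                    [g1[:, atlas.labels == r].mean(axis=1) for r in ids]
                )
                g2 = np.column_stack(
                    [g2[:, atlas.labels == r].mean(axis=1) for r in ids]
                )
            rates[k] = two_group_rate(g1, g2, alpha=config.alpha)
        dist = PerformanceDistribution(rates, level=config.level)
        entry: dict = {"distribution": dist}
        if full_combat is not None:
            entry["rank_sum_p"] = rank_sum_test(dist.values, full_combat.values)
        out[s] = entry
    return out


def unharmonized_frequency_map(
    dataset: FeatureDataset,
    config: SweepConfig,
    n_train: int | None = None,
) -> np.ndarray:
    """Per-feature percentage of iterations remaining significantly different.

    Each iteration draws a train/test split, fits on the training group,
    transfers to the test group, and records which features' across-site
    t-test rejects at ``alpha``.  Returns per-feature frequencies in
    [0, 100]; features frequently above chance resist harmonization (e.g.
    because their site effect sits far outside the shrinkage prior).
    """
    import scipy.stats as st

    if n_train is None:
        n_train = config.n_train_grid[-1]
    hits = np.zeros(dataset.n_features)
    for k in range(config.iterations):
        rng = _rng(config.master_seed, 300, k)
        train, test = make_split(dataset, n_train, config.n_test, rng)
        model, _ = fit_combat(train, config.schema(), config.fit_options)
        test_h = apply_transfer(model, test)
        sites = np.asarray(test_h.site, dtype=str)
        mask = sites == test_h.sites[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            res = st.ttest_ind(
                test_h.values[mask], test_h.values[~mask], axis=0
            )
        hits += np.where(np.asarray(res.pvalue) < config.alpha, 1.0, 0.0)
    return hits / config.iterations * 100.0
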