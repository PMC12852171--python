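"""Feature-matrix container and design-matrix construction.

The central object is :class:`FeatureDataset`: a subjects × features numeric
matrix (e.g. voxel-wise FA or MD values) together with a per-subject site
label and a covariate table (age in years, sex as a 0/1 indicator).  All
harmonization and evaluation code operates on this container; imaging input
is converted to it by :mod:`tcombat.imaging`.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureDataset",
    "CovariateSchema",
    "DesignMatrix",
    "build_design",
    "read_table",
    "write_table",
]


@dataclasses.dataclass(frozen=True)
class CovariateSchema:
    """Names and coding of the biological covariates entering the model.

    Parameters
    ----------
    names
        Ordered covariate names; each must be a column of the dataset's
        covariate table.
    codings
        Optional per-covariate mapping from category label to numeric code,
        for covariates stored non-numerically (e.g. ``{"sex": {"M": 0,
        "F": 1}}``).  Numeric covariates need no entry.
    """

    names: tuple[str, ...] = ()
    codings: Mapping[str, Mapping[str, float]] = dataclasses.field(
        default_factory=dict
    )

    def encode(self, covariates: pd.DataFrame) -> np.ndarray:
        """Return the subjects × covariates numeric matrix for this schema."""
        cols = []
        for name in self.names:
            if name not in covariates.columns:
                raise KeyError(f"unknown covariate {name!r}")
            col = covariates[name]
            if name in self.codings:
                coding = self.codings[name]
                unknown = set(col.unique()) - set(coding)
                if unknown:
                    raise ValueError(
                        f"covariate {name!r} has values {sorted(map(str, unknown))} "
                        f"absent from its declared coding"
                    )
                col = col.map(coding)
            values = pd.to_numeric(col, errors="coerce").to_numpy(float)
            if np.isnan(values).any():
                raise ValueError(
                    f"covariate {name!r} is non-numeric and has no declared coding"
                )
            cols.append(values)
        if not cols:
            return np.empty((len(covariates), 0))
        return np.column_stack(cols)

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "codings": {k: dict(v) for k, v in self.codings.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CovariateSchema":
        return cls(tuple(d["names"]), {k: dict(v) for k, v in d["codings"].items()})


@dataclasses.dataclass
class FeatureDataset:
    """Subjects × features values with site labels and covariates.

    ``values[j, v]`` is the measurement of feature ``v`` (a voxel or an ROI
    average) for subject ``j`` acquired at site ``site[j]``.
    """

    values: np.ndarray
    site: np.ndarray
    covariates: pd.DataFrame
    feature_ids: tuple[str, ...]
    subject_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D subjects × features matrix")
        self.site = np.asarray(self.site)
        self.feature_ids = tuple(map(str, self.feature_ids))
        n, v = self.values.shape
        if len(self.site) != n:
            raise ValueError("site labels must match the number of subjects")
        if len(self.covariates) != n:
            raise ValueError("covariate rows must match the number of subjects")
        if len(self.feature_ids) != v:
            raise ValueError("feature_ids must match the number of features")
        if self.subject_ids is None:
            self.subject_ids = tuple(f"sub{j:05d}" for j in range(n))
        else:
            self.subject_ids = tuple(map(str, self.subject_ids))
            if len(self.subject_ids) != n:
                raise ValueError("subject_ids must match the number of subjects")
        if not np.isfinite(self.values).all():
            raise ValueError("values contain missing or non-finite entries")
        self.covariates = self.covariates.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def sites(self) -> tuple[str, ...]:
        """Distinct site labels in order of first appearance."""
        return tuple(pd.unique(self.site.astype(str)))

    def site_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.site.astype(str), return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def subset(self, rows: Sequence[int]) -> "FeatureDataset":
        """Row-subset (or reorder) the dataset by integer position."""
        rows = np.asarray(rows, dtype=int)
        return FeatureDataset(
            values=self.values[rows],
            site=self.site[rows],
            covariates=self.covariates.iloc[rows],
            feature_ids=self.feature_ids,
            subject_ids=tuple(np.asarray(self.subject_ids, dtype=object)[rows]),
        )

    def validate_for_fit(self, min_sites: int = 1) -> None:
        counts = self.site_counts()
        if len(counts) < min_sites:
            raise ValueError(f"fitting requires at least {min_sites} site(s)")
        small = [s for s, c in counts.items() if c < 2]
        if small:
            raise ValueError(f"sites with fewer than 2 subjects: {small}")


@dataclasses.dataclass(frozen=True)
class DesignMatrix:
    """Design for the location/scale model: site indicators + covariates.

    Sites are cell-means coded (one indicator column per site, no separate
    intercept), which is full rank by construction.  The identifiability
    convention — site effects constrained to a zero mean weighted by site
    proportions n_i/N, so the overall level alpha is the weighted mean of the
    site intercepts — is applied when the least-squares coefficients are
    reduced to (alpha, beta), and is recorded in ``encoding``.
    """

    matrix: np.ndarray
    column_names: tuple[str, ...]
    site_order: tuple[str, ...]
    n_per_site: tuple[int, ...]
    n_covariates: int
    encoding: str

    @property
    def site_block(self) -> np.ndarray:
        return self.matrix[:, : len(self.site_order)]

    @property
    def covariate_block(self) -> np.ndarray:
        return self.matrix[:, len(self.site_order):]

    def site_index(self) -> np.ndarray:
        """Per-subject integer index into ``site_order``."""
        return np.argmax(self.site_block, axis=1)


def build_design(
    dataset: FeatureDataset,
    schema: CovariateSchema,
    site_order: Sequence[str] | None = None,
) -> DesignMatrix:
    """Build the design matrix: one indicator per site plus covariate columns.

    Parameters
    ----------
    dataset
        The data whose subjects define the rows.
    schema
        Covariates to include (possibly none).
    site_order
        Site registry to code against.  Defaults to the dataset's own sites;
        pass a fitted model's registry when building a design for transfer.
        Every site present in the data must appear in the registry.
    """
    sites = np.asarray(dataset.site, dtype=str)
    if site_order is None:
        site_order = tuple(pd.unique(sites))
    else:
        site_order = tuple(map(str, site_order))
        unseen = set(sites) - set(site_order)
        if unseen:
            raise ValueError(f"unseen site label(s): {sorted(unseen)}")
    indicator = np.zeros((dataset.n_subjects, len(site_order)))
    for k, s in enumerate(site_order):
        indicator[sites == s, k] = 1.0
    counts = indicator.sum(axis=0).astype(int)
    cov = schema.encode(dataset.covariates)
    matrix = np.hstack([indicator, cov])
    names = tuple(f"site[{s}]" for s in site_order) + tuple(schema.names)
    return DesignMatrix(
        matrix=matrix,
        column_names=names,
        site_order=site_order,
        n_per_site=tuple(counts.tolist()),
        n_covariates=cov.shape[1],
        encoding=(
            "cell-means site coding; overall level = n_i/N-weighted mean of "
            "site intercepts (site effects sum to zero with weights n_i/N)"
        ),
    )


def read_table(
    path,
    site_column: str = "site",
    covariate_columns: Sequence[str] = ("age", "sex"),
    subject_column: str = "subject_id",
    sep: str | None = None,
) -> FeatureDataset:
    """Read a wide delimited table: one row per subject.

    Expected columns: subject id, site, covariates, then one column per
    feature.  ``sep=None`` infers comma vs tab from the file.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    meta = [subject_column, site_column, *covariate_columns]
    missing = [c for c in meta if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    feature_cols = [c for c in df.columns if c not in meta]
    return FeatureDataset(
        values=df[feature_cols].to_numpy(float),
        site=df[site_column].to_numpy(str),
        covariates=df[list(covariate_columns)].copy(),
        feature_ids=tuple(feature_cols),
        subject_ids=tuple(df[subject_column].astype(str)),
    )


def write_table(dataset: FeatureDataset, path, sep: str = "\t") -> None:
    """Write the wide tabular layout read by :func:`read_table`."""
    df = pd.DataFrame({"subject_id": dataset.subject_ids, "site": dataset.site})
    for c in dataset.covariates.columns:
        df[c] = dataset.covariates[c].to_numpy()
    feat = pd.DataFrame(dataset.values, columns=list(dataset.feature_ids))
    pd.concat([df, feat], axis=1).to_csv(path, sep=sep, index=False)
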