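"""Serialization and transfer application of fitted harmonization models.

The transferable-ComBat workflow: fit on a training cohort, save the fitted
parameters (never any subject-level data), ship the archive, and harmonize
new subjects from known sites with the saved parameters only — no refit.

The archive is a single ``.npz`` file: a plain-text JSON manifest (format
version, site registry, covariate schema, fit options) stored under the key
``manifest``, plus one named float64 array per model field.  Arrays are
stored losslessly, so ``load_model(save_model(m))`` is value-exact.
"""

from __future__ import annotations

import json
import zipfile

import numpy as np

from .combat import (
    CombatModel,
    EBEstimates,
    FitOptions,
    LSEstimates,
    PriorHyperparameters,
)
from .dataset import CovariateSchema, FeatureDataset, build_design
from . import combat as _combat

__all__ = ["ARCHIVE_VERSION", "save_model", "load_model", "apply_transfer"]

ARCHIVE_VERSION = 1

_ARRAY_FIELDS = {
    "alpha": lambda m: m.ls.alpha,
    "beta": lambda m: m.ls.beta,
    "sigma": lambda m: m.ls.sigma,
    "constant_feature_mask": lambda m: m.ls.constant_feature_mask,
    "gamma_bar": lambda m: m.priors.gamma_bar,
    "tau2": lambda m: m.priors.tau2,
    "lambda_": lambda m: m.priors.lambda_,
    "theta": lambda m: m.priors.theta,
    "degenerate": lambda m: m.priors.degenerate,
    "gamma_star": lambda m: m.eb.gamma_star,
    "delta_star": lambda m: m.eb.delta_star,
    "eb_iterations": lambda m: m.eb.iterations,
    "eb_converged": lambda m: m.eb.converged,
}


def save_model(model: CombatModel, destination) -> None:
    """Write a fitted model to ``destination`` as a single archive file."""
    manifest = {
        "format": "tcombat-model",
        "version": ARCHIVE_VERSION,
        "site_registry": list(model.site_registry),
        "covariate_schema": model.covariate_schema.to_dict(),
        "feature_ids": list(model.feature_ids),
        "fit_options": model.fit_options.to_dict(),
    }
    arrays = {name: np.asarray(get(model)) for name, get in _ARRAY_FIELDS.items()}
    np.savez(destination, manifest=np.array(json.dumps(manifest)), **arrays)


def load_model(source) -> CombatModel:
    """Load an archive written by :func:`save_model`, validating its layout."""
    try:
        with np.load(source, allow_pickle=False) as npz:
            if "manifest" not in npz:
                raise ValueError("not a model archive: manifest missing")
            manifest = json.loads(str(npz["manifest"]))
            arrays = {name: npz[name] for name in _ARRAY_FIELDS}
    except (OSError, KeyError, json.JSONDecodeError, zipfile.BadZipFile) as exc:
        raise ValueError(f"corrupt or unreadable model archive: {exc}") from exc
    if manifest.get("format") != "tcombat-model":
        raise ValueError("not a tcombat model archive")
    if manifest.get("version") != ARCHIVE_VERSION:
        raise ValueError(f"unsupported archive version {manifest.get('version')!r}")
    sites = tuple(manifest["site_registry"])
    features = tuple(manifest["feature_ids"])
    s, v = len(sites), len(features)
    if arrays["gamma_star"].shape != (s, v) or arrays["alpha"].shape != (v,):
        raise ValueError("manifest/payload shape mismatch")
    ls = LSEstimates(
        alpha=arrays["alpha"],
        beta=arrays["beta"],
        sigma=arrays["sigma"],
        constant_feature_mask=arrays["constant_feature_mask"].astype(bool),
    )
    priors = PriorHyperparameters(
        gamma_bar=arrays["gamma_bar"],
        tau2=arrays["tau2"],
        lambda_=arrays["lambda_"],
        theta=arrays["theta"],
        degenerate=arrays["degenerate"].astype(bool),
    )
    eb = EBEstimates(
        gamma_star=arrays["gamma_star"],
        delta_star=arrays["delta_star"],
        iterations=arrays["eb_iterations"].astype(int),
        converged=arrays["eb_converged"].astype(bool),
    )
    return CombatModel(
        ls=ls,
        priors=priors,
        eb=eb,
        site_registry=sites,
        covariate_schema=CovariateSchema.from_dict(manifest["covariate_schema"]),
        feature_ids=features,
        fit_options=FitOptions(**manifest["fit_options"]),
    )


def _reorder_features(model: CombatModel, feature_ids) -> CombatModel:
    """Permute a model's per-feature arrays to a new feature ordering."""
    pos = {f: k for k, f in enumerate(model.feature_ids)}
    idx = np.array([pos[f] for f in feature_ids])
    ls = LSEstimates(
        alpha=model.ls.alpha[idx],
        beta=model.ls.beta[:, idx],
        sigma=model.ls.sigma[idx],
        constant_feature_mask=model.ls.constant_feature_mask[idx],
    )
    eb = EBEstimates(
        gamma_star=model.eb.gamma_star[:, idx],
        delta_star=model.eb.delta_star[:, idx],
        iterations=model.eb.iterations,
        converged=model.eb.converged,
    )
    return CombatModel(
        ls=ls,
        priors=model.priors,
        eb=eb,
        site_registry=model.site_registry,
        covariate_schema=model.covariate_schema,
        feature_ids=tuple(map(str, feature_ids)),
        fit_options=model.fit_options,
    )


def apply_transfer(model: CombatModel, new_data: FeatureDataset) -> FeatureDataset:
    """Harmonize new subjects using only the model's saved parameters.

    Each subject is standardized with the saved (alpha, beta, sigma) and
    transformed with the saved (gamma*, delta*) of its site.  Sites absent
    from the model's registry are a hard error — a transfer model is never
    silently refit.  Covariate values outside any previously seen range are
    allowed (the covariate model extrapolates linearly) but may be less
    reliable; a column reordering or missing covariate is an error.
    """
    if tuple(new_data.feature_ids) != tuple(model.feature_ids):
        if set(new_data.feature_ids) == set(model.feature_ids):
            model = _reorder_features(model, new_data.feature_ids)
        else:
            raise ValueError("feature_ids of new data do not match the model")
    missing = [
        c
        for c in model.covariate_schema.names
        if c not in new_data.covariates.columns
    ]
    if missing:
        raise ValueError(f"new data lacks covariate column(s): {missing}")
    design = build_design(
        new_data, model.covariate_schema, site_order=model.site_registry
    )
    return _combat.harmonize(new_data, design, model)
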