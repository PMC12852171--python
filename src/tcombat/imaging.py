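"""NIfTI bridge: masked voxel extraction and volume writing.

Converts stacks of already-aligned 3-D scalar volumes (e.g. registered FA
or MD maps) to the subjects × features matrix the harmonization operates
on, and writes per-feature results (harmonized values, frequency maps) back
into volumes.  Values pass through bit-exact: this module never resamples
or interpolates.

Voxel ordering: features are the voxels with a nonzero mask/atlas label, in
ascending linear index of the volume's native (C-order) array layout.  The
ordering is deterministic, so a feature index map built once is valid for
every volume on the same grid.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .dataset import FeatureDataset
from .evaluation import AtlasLabels

__all__ = [
    "VolumeStack",
    "VoxelIndexMap",
    "load_volumes",
    "volumes_to_features",
    "features_to_volumes",
]

_AFFINE_TOL = 1e-4


@dataclasses.dataclass(frozen=True)
class VolumeStack:
    """Per-subject 3-D volumes sharing one grid (shape and affine)."""

    data: np.ndarray            # (n_subjects, nx, ny, nz)
    affine: np.ndarray          # (4, 4)
    subject_ids: tuple[str, ...]

    def __post_init__(self):
        if self.data.ndim != 4:
            raise ValueError("data must be subjects × 3-D")
        if len(self.subject_ids) != self.data.shape[0]:
            raise ValueError("subject_ids must match the number of volumes")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


@dataclasses.dataclass(frozen=True)
class VoxelIndexMap:
    """Bijective mapping between feature index and 3-D voxel coordinate."""

    coords: np.ndarray          # (n_features, 3) int
    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self):
        lin = np.ravel_multi_index(self.coords.T, self.shape)
        if np.unique(lin).size != lin.size:
            raise ValueError("voxel coordinates must be unique")

    @property
    def n_features(self) -> int:
        return self.coords.shape[0]


def load_volumes(paths: Sequence, subject_ids: Sequence[str] | None = None) -> VolumeStack:
    """Load NIfTI volumes into a stack, checking grid compatibility."""
    imgs = [nib.load(str(p)) for p in paths]
    ref = imgs[0]
    vols = []
    for p, img in zip(paths, imgs):
        if img.shape != ref.shape:
            raise ValueError(f"shape mismatch for {p}")
        if not np.allclose(img.affine, ref.affine, atol=_AFFINE_TOL):
            raise ValueError(f"affine mismatch for {p}")
        vols.append(np.asarray(img.dataobj, dtype=float))
    if subject_ids is None:
        subject_ids = tuple(str(p) for p in paths)
    return VolumeStack(
        data=np.stack(vols), affine=ref.affine, subject_ids=tuple(subject_ids)
    )


def volumes_to_features(
    stack: VolumeStack,
    mask: np.ndarray | "nib.Nifti1Image",
    site: Sequence[str],
    covariates: pd.DataFrame,
    mask_affine: np.ndarray | None = None,
) -> tuple[FeatureDataset, VoxelIndexMap, AtlasLabels]:
    """Extract masked voxels from every subject volume.

    ``mask`` is an integer-labelled volume (an atlas): any nonzero label is
    in-mask, and the label value is carried per feature as its ROI id.
    """
    if hasattr(mask, "affine"):
        mask_affine = mask.affine
        mask = np.asarray(mask.dataobj)
    mask = np.asarray(mask)
    if mask.shape != stack.shape:
        raise ValueError("mask shape does not match the volume grid")
    if mask_affine is not None and not np.allclose(
        mask_affine, stack.affine, atol=_AFFINE_TOL
    ):
        raise ValueError("mask affine does not match the volume grid")
    labels = np.rint(mask).astype(int)
    lin = np.flatnonzero(labels.ravel(order="C"))
    if lin.size == 0:
        raise ValueError("mask is empty")
    coords = np.column_stack(np.unravel_index(lin, stack.shape))
    flat = stack.data.reshape(stack.data.shape[0], -1)
    values = flat[:, lin]
    index_map = VoxelIndexMap(coords=coords, shape=stack.shape, affine=stack.affine)
    atlas = AtlasLabels(labels=labels.ravel(order="C")[lin])
    dataset = FeatureDataset(
        values=values,
        site=np.asarray(site, dtype=str),
        covariates=covariates,
        feature_ids=tuple(
            f"vox_{x}_{y}_{z}" for x, y, z in coords
        ),
        subject_ids=stack.subject_ids,
    )
    return dataset, index_map, atlas


def features_to_volumes(
    values: np.ndarray,
    index_map: VoxelIndexMap,
) -> np.ndarray | VolumeStack:
    """Place per-feature values back on the voxel grid; background is zero.

    ``values`` may be a single per-feature vector (returns one 3-D array,
    e.g. a frequency map) or a subjects × features matrix (returns a
    :class:`VolumeStack`).
    """
    values = np.asarray(values, float)
    lin = np.ravel_multi_index(index_map.coords.T, index_map.shape)
    if values.ndim == 1:
        if values.size != index_map.n_features:
            raise ValueError("value count does not match the index map")
        vol = np.zeros(int(np.prod(index_map.shape)))
        vol[lin] = values
        return vol.reshape(index_map.shape)
    if values.shape[1] != index_map.n_features:
        raise ValueError("value count does not match the index map")
    out = np.zeros((values.shape[0], int(np.prod(index_map.shape))))
    out[:, lin] = values
    return VolumeStack(
        data=out.reshape((values.shape[0],) + index_map.shape),
        affine=index_map.affine,
        subject_ids=tuple(f"sub{j:05d}" for j in range(values.shape[0])),
    )


def save_volume(volume: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a 3-D array as NIfTI."""
    nib.save(nib.Nifti1Image(np.asarray(volume, float), affine), str(path))
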