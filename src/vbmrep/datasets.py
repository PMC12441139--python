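"""In-memory container for voxelwise gray-matter data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VoxelDataset:
    """Subjects x in-mask-voxels gray-matter matrix with grid geometry.

    ``data`` holds one row per subject (order identical to the subject
    table) and one column per voxel inside ``mask``; ``mask`` is the 3-D
    boolean analysis mask; ``affine`` maps voxel indices (0-based) to world
    coordinates.
    """

    data: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    subject_ids: list[str]
    voxel_size: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (subjects x voxels)")
        if self.data.shape[1] != int(self.mask.sum()):
            raise ValueError(
                f"data has {self.data.shape[1]} columns but mask has "
                f"{int(self.mask.sum())} voxels"
            )
        if len(self.subject_ids) != self.data.shape[0]:
            raise ValueError("subject_ids length must match data rows")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mask.shape

    def to_4d(self) -> np.ndarray:
        """Expand to a (x, y, z, subjects) stack with zeros outside the mask."""
        out = np.zeros(self.mask.shape + (self.n_subjects,), dtype=float)
        out[self.mask, :] = self.data.T
        return out

    def voxel_coords(self) -> np.ndarray:
        """(V, 3) voxel indices of in-mask voxels, order matching columns."""
        return np.argwhere(self.mask)


def common_mask(datasets: list[VoxelDataset]) -> np.ndarray:
    """Intersection of analysis masks across cohorts (common grid required)."""
    shape = datasets[0].mask.shape
    for d in datasets[1:]:
        if d.mask.shape != shape:
            raise ValueError("datasets have different grid shapes")
    mask = datasets[0].mask.copy()
    for d in datasets[1:]:
        mask &= d.mask
    if not mask.any():
        raise ValueError("common mask is empty")
    return mask


def subset_to_mask(dataset: VoxelDataset, mask: np.ndarray) -> VoxelDataset:
    """Restrict a dataset's columns to a (sub-)mask of its own mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dataset.mask.shape:
        raise ValueError("mask shape mismatch")
    if np.any(mask & ~dataset.mask):
        raise ValueError("target mask must be a subset of the dataset mask")
    keep = mask[dataset.mask]
    return VoxelDataset(
        data=dataset.data[:, keep],
        mask=mask,
        affine=dataset.affine,
        subject_ids=list(dataset.subject_ids),
        voxel_size=dataset.voxel_size,
        meta=dict(dataset.meta),
    )


def global_gm_density(dataset: VoxelDataset) -> np.ndarray:
    """Average gray-matter density across in-mask voxels, per subject."""
    return dataset.data.mean(axis=1)
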