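"""Atlas and mask handling: labelled volumes, coverage rules, ROI extraction.

A parcellation is a 3-D integer label volume (0 = background) defining the
regions of interest (ROIs) used as network nodes.  Before connectivity
estimation, ROIs with insufficient coverage inside the functional analysis
mask are excluded, out-of-mask voxels are dropped, and each remaining ROI is
extracted as an n-timepoints x v-voxels block.  Voxel ordering within a
block is the sorted C-order linear index of the label volume -- fixed and
deterministic, so extraction round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Parcellation",
    "analysis_mask",
    "coverage_filter",
    "tissue_nuisance_mask",
    "extract_roi_blocks",
    "roi_summary",
]


@dataclass
class Parcellation:
    """Integer-labelled 3-D volume; 0 is background."""

    labels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValueError("label volume must be integer valued")
            self.labels = np.round(self.labels).astype(np.int32)

    @property
    def roi_ids(self) -> tuple:
        ids = np.unique(self.labels)
        return tuple(int(i) for i in ids[ids > 0])

    def voxel_indices(self, roi_id: int) -> np.ndarray:
        """Sorted C-order linear indices of one ROI's voxels."""
        return np.flatnonzero(self.labels.ravel() == roi_id)

    def centroids(self) -> dict[int, np.ndarray]:
        """ROI centroids in world (affine) coordinates, mm."""
        out = {}
        for rid in self.roi_ids:
            ijk = np.column_stack(np.nonzero(self.labels == rid)).mean(axis=0)
            out[rid] = (self.affine @ np.append(ijk, 1.0))[:3]
        return out

    @classmethod
    def from_nifti(cls, path) -> "Parcellation":
        import nibabel as nib

        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj).astype(np.int32), img.affine)

    def to_nifti(self, path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.labels.astype(np.int32), self.affine), str(path))


def analysis_mask(mean_image, threshold: float = 0.7, mean_over: str = "nonzero") -> np.ndarray:
    """Boolean analysis mask at a fraction of mean signal intensity.

    A voxel is included iff its value is at least ``threshold`` times the
    mean intensity.  The reference mean is taken over nonzero voxels by
    default (``mean_over='all'`` uses every voxel).  Scale invariant.
    """
    img = np.asarray(mean_image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("mean image contains non-finite values")
    if mean_over == "nonzero":
        nz = img[img != 0]
        if nz.size == 0:
            raise ValueError("all-zero mean image")
        ref = nz.mean()
    elif mean_over == "all":
        ref = img.mean()
        if ref == 0:
            raise ValueError("zero-mean image")
    else:
        raise ValueError("mean_over must be 'nonzero' or 'all'")
    return img >= threshold * ref


def coverage_filter(
    parc: Parcellation,
    mask: np.ndarray,
    threshold: float = 0.25,
) -> tuple[pd.DataFrame, Parcellation]:
    """Exclude ROIs with insufficient analysis-mask coverage.

    An ROI is kept iff the fraction of its voxels inside ``mask`` is at
    least ``threshold`` (boundary inclusive); kept ROIs retain only their
    in-mask voxels.  Returns the coverage report and the filtered
    parcellation.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != parc.labels.shape:
        raise ValueError("mask and parcellation shapes differ")
    rows = []
    new_labels = np.zeros_like(parc.labels)
    for rid in parc.roi_ids:
        inroi = parc.labels == rid
        n_vox = int(inroi.sum())
        n_in = int((inroi & mask).sum())
        frac = n_in / n_vox
        kept = frac >= threshold
        rows.append(
            {"roi_id": rid, "n_voxels": n_vox, "n_in_mask": n_in, "fraction": frac, "kept": kept}
        )
        if kept:
            new_labels[inroi & mask] = rid
    report = pd.DataFrame(rows)
    return report, Parcellation(new_labels, parc.affine)


def tissue_nuisance_mask(
    gm,
    tissue,
    gm_max: float = 0.01,
    tissue_min: float = 0.80,
) -> np.ndarray:
    """WM/CSF nuisance mask from tissue probability maps.

    A voxel is included iff its grey-matter probability is strictly below
    ``gm_max`` and its WM (or CSF) probability strictly above
    ``tissue_min`` -- strict inequalities, keeping nuisance signals free of
    grey-matter contamination.
    """
    gm = np.asarray(gm, dtype=float)
    tissue = np.asarray(tissue, dtype=float)
    if gm.shape != tissue.shape:
        raise ValueError("probability map shapes differ")
    for name, arr in (("gm", gm), ("tissue", tissue)):
        if arr.min() < 0 or arr.max() > 1:
            raise ValueError(f"{name} probabilities outside [0, 1]")
    return (gm < gm_max) & (tissue > tissue_min)


def extract_roi_blocks(img4d, parc: Parcellation) -> dict[int, np.ndarray]:
    """Extract an n x v voxel-pattern block for every ROI.

    ``img4d`` is (x, y, z, t); the block for each ROI stacks that ROI's
    voxel time series as columns, in sorted linear-index order.
    """
    data = np.asarray(img4d, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4-D image (x, y, z, t)")
    if data.shape[:3] != parc.labels.shape:
        raise ValueError("spatial shapes of image and parcellation differ")
    flat = data.reshape(-1, data.shape[3])  # voxels x time, C order
    blocks = {}
    for rid in parc.roi_ids:
        idx = parc.voxel_indices(rid)
        if idx.size == 0:
            raise ValueError(f"ROI {rid} has no voxels")
        blocks[rid] = flat[idx].T  # n x v
    return blocks


def roi_summary(X, method: str = "mean") -> np.ndarray:
    """Summarise an ROI block as a single time series.

    ``mean``: arithmetic voxel mean per time point.  ``first_singular_vector``:
    left singular vector of the column-demeaned block scaled by its singular
    value, with sign aligned to positive correlation with the voxel mean
    (SVD leaves the sign arbitrary).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] < 1:
        raise ValueError("ROI block has no voxels")
    mean_ts = X.mean(axis=1)
    if method == "mean":
        return mean_ts
    if method == "first_singular_vector":
        Xc = X - X.mean(axis=0)
        if not np.any(Xc):
            raise ValueError("degenerate all-constant block: no singular structure")
        U, s, _ = np.linalg.svd(Xc, full_matrices=False)
        ts = U[:, 0] * s[0]
        ref = mean_ts - mean_ts.mean()
        if ts @ ref < 0:
            ts = -ts
        return ts
    raise ValueError("method must be 'mean' or 'first_singular_vector'")
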