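"""Connectivity estimators for ROI-based network analysis.

Implements the Pearson correlation, its unsigned variant, and distance
correlation in two flavours: the classic double-centred (biased) estimator
used for univariate ROI-mean series, and the U-centred (unbiased) estimator
used for multivariate voxel patterns.  Distance correlation measures general
(linear or non-linear) dependence between two sets of signals by comparing
the pairwise Euclidean distance structure of their time points; the
U-centred variant is unbiased with respect to the number of voxels in a
region, which makes regions of different sizes comparable.

The distance-correlation value reported here is the ratio
``dCov / sqrt(dVarX * dVarY)`` with non-positive distance covariance
truncated to zero.  On the double-centred path this equals the square of
Szekely's classic dCor; on the U-centred path it is the bias-corrected
R* statistic of Szekely & Rizzo (2014), which can be negative under
independence (hence the truncation rule).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "CenteredMatrix",
    "ConnectivityMatrix",
    "pearson",
    "unsigned_pearson",
    "euclidean_distance_matrix",
    "center",
    "distance_cov_var",
    "distance_correlation",
    "zscore_voxels",
    "connectivity_matrix",
    "MEASURES",
]

MEASURES = ("pcor", "unsigned_pcor", "uvdcor", "mvdcor")

#: value stored on the diagonal of connectivity matrices; self-connections
#: are undefined and must be excluded from vectorised analyses.
DIAGONAL_SENTINEL = np.nan


def _as_series(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("time series must have at least 2 points")
    if not np.all(np.isfinite(x)):
        raise ValueError("time series contains non-finite values")
    return x


def pearson(x, y) -> float:
    """Pearson correlation between two time series.

    Raises on length mismatch or a constant input (zero variance) rather
    than silently returning NaN.
    """
    x, y = _as_series(x), _as_series(y)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        raise ValueError("constant input: Pearson correlation undefined")
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


def unsigned_pearson(x, y) -> float:
    """Absolute Pearson correlation (sign of negative correlations flipped).

    Used when comparing against distance correlation, which cannot
    distinguish positive from negative association and spans [0, 1].
    """
    return abs(pearson(x, y))


def _as_block(X) -> np.ndarray:
    """Coerce input to an n-timepoints x v-voxels matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.size == 0:
        raise ValueError("expected a non-empty n x v matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("voxel matrix contains non-finite values")
    return X


def euclidean_distance_matrix(X) -> np.ndarray:
    """Pairwise Euclidean distances between time points in voxel space.

    ``X`` is n x v (time by voxels); the result is the symmetric n x n
    matrix ``a`` with ``a[i, j] = ||X[i] - X[j]||``.
    """
    X = _as_block(X)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 time points")
    return squareform(pdist(X, metric="euclidean"))


@dataclass(frozen=True)
class CenteredMatrix:
    """A centred distance matrix together with its normalisation factor.

    ``centering='double'`` subtracts row, column and grand means
    (K = n^2); ``centering='U'`` applies U-centering, which zeroes row and
    column sums and the diagonal and yields an unbiased distance-covariance
    estimator (K = n(n-3), requiring n >= 4).
    """

    values: np.ndarray
    centering: str
    K: float

    @property
    def n(self) -> int:
        return self.values.shape[0]


def center(a: np.ndarray, mode: str = "double") -> CenteredMatrix:
    """Centre a pairwise distance matrix for distance-covariance computation."""
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("distance matrix must be square")
    n = a.shape[0]
    if mode == "double":
        row = a.mean(axis=1, keepdims=True)
        col = a.mean(axis=0, keepdims=True)
        A = a - row - col + a.mean()
        return CenteredMatrix(A, "double", float(n) ** 2)
    if mode == "U":
        if n < 4:
            raise ValueError(f"U-centering requires n >= 4 (got n={n}, K=n(n-3) <= 0)")
        rs = a.sum(axis=1, keepdims=True)
        cs = a.sum(axis=0, keepdims=True)
        A = a - rs / (n - 2) - cs / (n - 2) + a.sum() / ((n - 1) * (n - 2))
        np.fill_diagonal(A, 0.0)
        return CenteredMatrix(A, "U", float(n * (n - 3)))
    raise ValueError(f"unknown centering mode {mode!r}")


def distance_cov_var(A: CenteredMatrix, B: CenteredMatrix) -> tuple[float, float, float]:
    """Distance covariance and the two distance variances.

    Returns ``(dCov, dVarA, dVarB)`` where each is the normalised inner
    product of the centred matrices, ``sum(A*B)/K``.  On the U-centred path
    dCov is an unbiased estimator and may be negative under independence.
    """
    if A.centering != B.centering:
        raise ValueError("centering mode mismatch")
    if A.n != B.n:
        raise ValueError("size mismatch between centred matrices")
    K = A.K
    a, b = A.values, B.values
    return (
        float((a * b).sum() / K),
        float((a * a).sum() / K),
        float((b * b).sum() / K),
    )


def _dcor_from_centered(A: CenteredMatrix, B: CenteredMatrix) -> tuple[float, bool]:
    """dCor ratio with the truncation rule; returns (value, truncated)."""
    dcov, dvara, dvarb = distance_cov_var(A, B)
    if dvara <= 0.0 or dvarb <= 0.0:
        warnings.warn("zero distance variance: returning dCor = 0", RuntimeWarning)
        return 0.0, False
    if dcov <= 0.0:
        return 0.0, True
    return float(np.clip(dcov / np.sqrt(dvara * dvarb), 0.0, 1.0)), False


def distance_correlation(X, Y, mode: str = "double") -> float:
    """Distance correlation between two voxel-pattern blocks.

    Both blocks must share the number of time points.  A non-positive
    distance covariance is truncated to zero (negative U-centred estimates
    indicate non-significant dependence); a zero distance variance returns
    zero with a warning.  For multivariate use the caller should z-score
    each voxel first (see :func:`zscore_voxels`).
    """
    X, Y = _as_block(X), _as_block(Y)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("time-point mismatch between X and Y")
    A = center(euclidean_distance_matrix(X), mode)
    B = center(euclidean_distance_matrix(Y), mode)
    value, _ = _dcor_from_centered(A, B)
    return value


def zscore_voxels(X, drop_constant: bool = True, tol: float = 1e-12) -> np.ndarray:
    """Z-score every voxel column (population SD, ddof=0).

    Voxels with SD below ``tol`` carry no signal and are dropped with a
    warning (or raise when ``drop_constant`` is false).
    """
    X = _as_block(X)
    sd = X.std(axis=0, ddof=0)
    const = sd < tol
    if const.any():
        if not drop_constant or const.all():
            raise ValueError("constant voxel time series cannot be z-scored")
        warnings.warn(
            f"dropping {int(const.sum())} constant voxel(s) before z-scoring",
            RuntimeWarning,
        )
        X = X[:, ~const]
        sd = sd[~const]
    return (X - X.mean(axis=0)) / sd


@dataclass
class ConnectivityMatrix:
    """Symmetric R x R connectivity matrix for one measure.

    The diagonal holds a NaN sentinel: self-connections are undefined and
    excluded from all vectorised analyses.  ``n_truncated`` counts entries
    whose (U-centred) distance covariance was non-positive and was set to
    zero by the truncation rule.
    """

    values: np.ndarray
    measure: str
    roi_ids: tuple = field(default_factory=tuple)
    n_truncated: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.roi_ids = tuple(self.roi_ids) if len(self.roi_ids) else tuple(
            range(self.values.shape[0])
        )

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    def lower_triangle(self) -> np.ndarray:
        """Vectorised lower triangle, diagonal excluded, fixed ROI order."""
        i, j = np.tril_indices(self.n_rois, k=-1)
        return self.values[i, j]

    def regional_vector(self, roi_index: int) -> np.ndarray:
        """Connections of one ROI to all others (self excluded)."""
        row = self.values[roi_index]
        return np.delete(row, roi_index)

    # -- serialisation -----------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write as TSV (ROI labels as header row/column) + JSON sidecar."""
        path = Path(path)
        labels = [str(r) for r in self.roi_ids]
        with open(path, "w") as fh:
            fh.write("roi\t" + "\t".join(labels) + "\n")
            for lab, row in zip(labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
        sidecar = {"measure": self.measure, "n_truncated": int(self.n_truncated)}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_tsv(cls, path) -> "ConnectivityMatrix":
        path = Path(path)
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = [line.rstrip("\n").split("\t")[1:] for line in fh]
        values = np.array(rows, dtype=float)
        meta = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls(
            values,
            measure=meta.get("measure", "unknown"),
            roi_ids=tuple(header),
            n_truncated=meta.get("n_truncated", 0),
        )

    def to_npz(self, path) -> None:
        """Compact binary container (NumPy .npz)."""
        np.savez_compressed(
            path,
            values=self.values,
            measure=np.array(self.measure),
            roi_ids=np.array([str(r) for r in self.roi_ids]),
            n_truncated=np.array(self.n_truncated),
        )

    @classmethod
    def from_npz(cls, path) -> "ConnectivityMatrix":
        with np.load(path) as z:
            return cls(
                z["values"],
                measure=str(z["measure"]),
                roi_ids=tuple(z["roi_ids"].tolist()),
                n_truncated=int(z["n_truncated"]),
            )


def connectivity_matrix(
    roi_blocks: Sequence[np.ndarray],
    measure: str,
    roi_ids: Sequence | None = None,
) -> ConnectivityMatrix:
    """Full ROI x ROI connectivity matrix for one measure.

    ``pcor``/``unsigned_pcor``/``uvdcor`` are computed on the voxel-mean
    time series of each ROI (uvdcor with double centering); ``mvdcor`` is
    the U-centred distance correlation on z-scored voxel patterns.  Centred
    matrices are computed once per ROI, so assembling the full matrix costs
    O(R) distance matrices plus O(R^2) inner products.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    blocks = [_as_block(b) for b in roi_blocks]
    if len(blocks) < 2:
        raise ValueError("need at least 2 ROIs")
    n = blocks[0].shape[0]
    for k, b in enumerate(blocks):
        if b.shape[0] != n:
            raise ValueError(f"ROI {k} has {b.shape[0]} time points, expected {n}")
        if b.shape[1] == 0:
            raise ValueError(f"ROI {k} has zero voxels")
    R = len(blocks)
    ids = tuple(roi_ids) if roi_ids is not None else tuple(range(R))
    out = np.full((R, R), DIAGONAL_SENTINEL)
    n_trunc = 0

    if measure in ("pcor", "unsigned_pcor", "uvdcor"):
        means = [b.mean(axis=1) for b in blocks]
        if measure == "uvdcor":
            cents = [center(euclidean_distance_matrix(m[:, None]), "double") for m in means]
            for i in range(R):
                for j in range(i):
                    val, trunc = _dcor_from_centered(cents[i], cents[j])
                    out[i, j] = out[j, i] = val
                    n_trunc += trunc
        else:
            for i in range(R):
                for j in range(i):
                    r = pearson(means[i], means[j])
                    if measure == "unsigned_pcor":
                        r = abs(r)
                    out[i, j] = out[j, i] = r
    else:  # mvdcor
        cents = [center(euclidean_distance_matrix(zscore_voxels(b)), "U") for b in blocks]
        for i in range(R):
            for j in range(i):
                val, trunc = _dcor_from_centered(cents[i], cents[j])
                out[i, j] = out[j, i] = val
                n_trunc += trunc

    return ConnectivityMatrix(out, measure=measure, roi_ids=ids, n_truncated=n_trunc)
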