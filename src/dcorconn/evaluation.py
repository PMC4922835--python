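"""Evaluation battery for comparing connectivity measures.

Covers test-retest reliability (intraclass correlation of vectorised
connectivity matrices, per ROI, and per connection), between-participant
similarity, ROI homogeneity (variance explained by the first principal
component of voxelwise connectivity patterns), robustness to the choice of
parcellation via voxel-level projection, a connection-swap permutation test
for paired reliability differences, motion association, structure-function
correspondence, and structural covariance (the same estimators applied
across participants to grey-matter volumes).

Vectorisation convention throughout: lower triangle, diagonal excluded,
fixed ROI order.  All statistics are invariant to a simultaneous relabeling
of ROI rows and columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .dcor_core import ConnectivityMatrix, connectivity_matrix, pearson
from .parcellation import Parcellation

__all__ = [
    "SubjectSessionStack",
    "icc",
    "reliability_within",
    "per_connection_icc",
    "between_participant_similarity",
    "roi_homogeneity",
    "homogeneity_profile",
    "voxel_connectivity_patterns",
    "cross_parcellation_robustness",
    "swap_permutation_test",
    "motion_association",
    "structure_function_similarity",
    "structural_covariance",
    "zero_weakest",
]


@dataclass
class SubjectSessionStack:
    """Connectivity matrices indexed by (participant, session, measure)."""

    matrices: dict = field(default_factory=dict)
    roi_ids: tuple = ()

    def add(self, participant, session, measure, mat: ConnectivityMatrix) -> None:
        if session not in (1, 2):
            raise ValueError("sessions are labelled 1 and 2")
        if not self.roi_ids:
            self.roi_ids = tuple(mat.roi_ids)
        elif tuple(mat.roi_ids) != self.roi_ids:
            raise ValueError("inconsistent ROI ids across stack entries")
        self.matrices[(participant, session, measure)] = mat

    def get(self, participant, session, measure) -> ConnectivityMatrix:
        key = (participant, session, measure)
        if key not in self.matrices:
            raise KeyError(f"missing connectivity matrix for {key}")
        return self.matrices[key]

    @property
    def participants(self) -> tuple:
        return tuple(sorted({k[0] for k in self.matrices}))

    @property
    def measures(self) -> tuple:
        return tuple(sorted({k[2] for k in self.matrices}))

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------

def icc(u, w, form: str = "icc1") -> float:
    """Intraclass correlation between two paired measurement vectors.

    Treats each element as a target rated twice (k = 2 raters/sessions) and
    computes single-measure ICC from the ANOVA mean squares.  Forms:
    ``icc1`` one-way random ICC(1,1) (default), ``icc2`` two-way random
    absolute agreement ICC(2,1), ``icc3`` two-way mixed consistency
    ICC(3,1).
    """
    u = np.asarray(u, dtype=float).ravel()
    w = np.asarray(w, dtype=float).ravel()
    if u.size != w.size:
        raise ValueError("length mismatch")
    n = u.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    data = np.column_stack([u, w])
    if np.ptp(data) == 0:
        raise ValueError("zero-variance input: ICC undefined")
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_total = ((data - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    bms = ss_rows / (n - 1)  # between-target
    jms = ss_cols / (k - 1)  # between-session
    ems = ss_err / ((n - 1) * (k - 1))  # residual
    wms = (ss_cols + ss_err) / (n * (k - 1))  # within-target (one-way)
    if form == "icc1":
        denom = bms + (k - 1) * wms
        val = (bms - wms) / denom if denom != 0 else 0.0
    elif form == "icc2":
        denom = bms + (k - 1) * ems + k * (jms - ems) / n
        val = (bms - ems) / denom if denom != 0 else 0.0
    elif form == "icc3":
        denom = bms + (k - 1) * ems
        val = (bms - ems) / denom if denom != 0 else 0.0
    else:
        raise ValueError("form must be one of 'icc1', 'icc2', 'icc3'")
    return float(np.clip(val, -1.0, 1.0))


def reliability_within(
    stack: SubjectSessionStack,
    measure: str,
    form: str = "icc1",
    regional: bool = False,
):
    """Session-1 vs session-2 ICC of connectivity per participant.

    Returns a Series of one ICC per participant (vectorised lower-triangle
    matrices), or -- with ``regional=True`` -- a participants x ROI frame of
    ICCs of each ROI's row of connections.
    """
    if not regional:
        vals = {}
        for p in stack.participants:
            m1 = stack.get(p, 1, measure)
            m2 = stack.get(p, 2, measure)
            vals[p] = icc(m1.lower_triangle(), m2.lower_triangle(), form)
        s = pd.Series(vals, name=f"icc_{measure}")
        s.attrs["icc_form"] = form
        return s
    rows = {}
    for p in stack.participants:
        m1 = stack.get(p, 1, measure)
        m2 = stack.get(p, 2, measure)
        rows[p] = [
            icc(m1.regional_vector(i), m2.regional_vector(i), form)
            for i in range(stack.n_rois)
        ]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(stack.roi_ids))
    df.attrs["icc_form"] = form
    return df


def per_connection_icc(stack: SubjectSessionStack, measure: str, form: str = "icc1") -> np.ndarray:
    """Session-1 vs session-2 ICC of each connection across participants.

    Returns a symmetric R x R matrix (diagonal NaN); connections with zero
    between-participant variance are flagged NaN with a warning.
    """
    parts = stack.participants
    R = stack.n_rois
    s1 = np.stack([stack.get(p, 1, measure).values for p in parts])
    s2 = np.stack([stack.get(p, 2, measure).values for p in parts])
    out = np.full((R, R), np.nan)
    n_degenerate = 0
    for i in range(R):
        for j in range(i):
            u, w = s1[:, i, j], s2[:, i, j]
            if np.ptp(np.column_stack([u, w])) == 0:
                n_degenerate += 1
                continue
            out[i, j] = out[j, i] = icc(u, w, form)
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} connection(s) with zero variance: ICC set to NaN",
            RuntimeWarning,
        )
    return out


def between_participant_similarity(
    stack: SubjectSessionStack,
    measure: str,
    session: int = 1,
    leave_one_out: bool = False,
) -> pd.Series:
    """Pearson correlation of each participant's matrix with the group mean.

    The group-average matrix includes the indexed participant by default
    (``leave_one_out=True`` excludes it).
    """
    parts = stack.participants
    if len(parts) < 3:
        raise ValueError("need at least 3 participants")
    vecs = np.stack([stack.get(p, session, measure).lower_triangle() for p in parts])
    mean_all = vecs.mean(axis=0)
    vals = {}
    for idx, p in enumerate(parts):
        ref = (
            (mean_all * len(parts) - vecs[idx]) / (len(parts) - 1)
            if leave_one_out
            else mean_all
        )
        vals[p] = pearson(vecs[idx], ref)
    return pd.Series(vals, name=f"similarity_{measure}")


# ---------------------------------------------------------------------------
# homogeneity
# ---------------------------------------------------------------------------

def roi_homogeneity(voxel_conn) -> float:
    """Percent of variance explained by the first PC of voxel connectivity.

    ``voxel_conn`` is v x (R-1): one whole-brain connectivity pattern per
    voxel.  Each voxel's pattern is demeaned (PCA ignores its mean level, so
    overall connectivity strength does not affect homogeneity) and the
    percent of total variance captured by the first principal component of
    the voxel-by-target matrix is returned.
    """
    C = np.asarray(voxel_conn, dtype=float)
    if C.ndim != 2 or C.shape[0] < 2 or C.shape[1] < 2:
        raise ValueError("need at least 2 voxels and 2 target ROIs")
    C = C - C.mean(axis=1, keepdims=True)  # remove each voxel's mean pattern level
    s = np.linalg.svd(C, compute_uv=False)
    total = float((s**2).sum())
    if total == 0:
        raise ValueError("rank-0 connectivity patterns after demeaning")
    return float(100.0 * s[0] ** 2 / total)


def voxel_connectivity_patterns(blocks: dict[int, np.ndarray]) -> dict[int, np.ndarray]:
    """Pearson connectivity of every voxel to the mean series of other ROIs.

    For each ROI, returns a v x (R-1) matrix: the whole-brain connectivity
    pattern of each of its voxels.
    """
    rids = list(blocks)
    means = {r: blocks[r].mean(axis=1) for r in rids}
    out = {}
    for r in rids:
        X = blocks[r]
        targets = [means[o] for o in rids if o != r]
        pat = np.empty((X.shape[1], len(targets)))
        for c, t in enumerate(targets):
            tc = t - t.mean()
            tn = np.sqrt(tc @ tc)
            Xc = X - X.mean(axis=0)
            xn = np.sqrt((Xc**2).sum(axis=0))
            pat[:, c] = (Xc.T @ tc) / (xn * tn)
        out[r] = pat
    return out


def homogeneity_profile(blocks: dict[int, np.ndarray]) -> pd.Series:
    """Per-ROI homogeneity from raw voxel blocks (values in (0, 100])."""
    pats = voxel_connectivity_patterns(blocks)
    return pd.Series({r: roi_homogeneity(p) for r, p in pats.items()}, name="homogeneity")


# ---------------------------------------------------------------------------
# cross-parcellation robustness
# ---------------------------------------------------------------------------

def cross_parcellation_robustness(
    mA: ConnectivityMatrix,
    pA: Parcellation,
    mB: ConnectivityMatrix,
    pB: Parcellation,
) -> float:
    """Agreement between connectivity estimates from two parcellations.

    ROI-level matrices are projected onto voxel pairs (each voxel pair
    inherits its ROI-pair value), using only voxels labelled in both
    parcellations; pairs falling within a single ROI in either parcellation
    are excluded (self-connections are undefined).  Returns the Pearson
    correlation over the remaining shared voxel pairs.
    """
    if pA.labels.shape != pB.labels.shape:
        raise ValueError("parcellations are on different voxel grids")
    labA, labB = pA.labels.ravel(), pB.labels.ravel()
    idA = {r: k for k, r in enumerate(mA.roi_ids)}
    idB = {r: k for k, r in enumerate(mB.roi_ids)}
    shared = np.flatnonzero(
        np.isin(labA, list(idA)) & np.isin(labB, list(idB))
    )
    if shared.size < 2:
        raise ValueError("no shared voxels between parcellations")
    a_idx = np.array([idA[l] for l in labA[shared]])
    b_idx = np.array([idB[l] for l in labB[shared]])
    ii, jj = np.triu_indices(shared.size, k=1)
    keep = (a_idx[ii] != a_idx[jj]) & (b_idx[ii] != b_idx[jj])
    va = mA.values[a_idx[ii[keep]], a_idx[jj[keep]]]
    vb = mB.values[b_idx[ii[keep]], b_idx[jj[keep]]]
    return pearson(va, vb)


# ---------------------------------------------------------------------------
# permutation test for paired reliability differences
# ---------------------------------------------------------------------------

def _spearman_rows(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Row-wise Spearman correlation of two equally shaped matrices."""
    rx = rankdata(X, axis=1)
    ry = rankdata(Y, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    num = (rx * ry).sum(axis=1)
    den = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    return num / den


def swap_permutation_test(
    pvec, dvec, pvec2, dvec2, n_perm: int = 5000, seed: int | None = None
) -> tuple[float, float]:
    """Connection-swap permutation test of a reliability difference.

    The observed statistic is |rho_S(d1, d2)| - |rho_S(p1, p2)| (Spearman
    session-1 vs session-2 reliability of each measure).  The null swaps the
    two measures' values for random subsets of connections, consistently
    across both sessions, and recomputes the difference; the p-value is the
    fraction of permuted |differences| at least as large as the observed
    |difference|.  Returns ``(p_value, observed)``.
    """
    p1 = np.asarray(pvec, dtype=float).ravel()
    d1 = np.asarray(dvec, dtype=float).ravel()
    p2 = np.asarray(pvec2, dtype=float).ravel()
    d2 = np.asarray(dvec2, dtype=float).ravel()
    L = p1.size
    if not (d1.size == p2.size == d2.size == L):
        raise ValueError("all four vectors must have equal length")
    observed = abs(spearmanr(d1, d2).statistic) - abs(spearmanr(p1, p2).statistic)
    rng = np.random.default_rng(seed)
    swap = rng.random((n_perm, L)) < 0.5
    P1 = np.where(swap, d1, p1)
    D1 = np.where(swap, p1, d1)
    P2 = np.where(swap, d2, p2)
    D2 = np.where(swap, p2, d2)
    null = np.abs(_spearman_rows(D1, D2)) - np.abs(_spearman_rows(P1, P2))
    p_value = float(np.mean(np.abs(null) >= abs(observed)))
    return p_value, float(observed)


# ---------------------------------------------------------------------------
# motion and structure-function
# ---------------------------------------------------------------------------

def motion_association(
    stack: SubjectSessionStack,
    motion_totals: dict | pd.Series,
    roi_centroids: dict,
    measure: str,
    session: int = 1,
) -> tuple[float, float]:
    """Association between connectivity and total head motion.

    Correlates each connection's strength with participants' total motion
    (Pearson, across participants), then summarises: ``mean_corr`` averages
    the per-connection motion correlations, and ``distance_dependence``
    correlates them with the Euclidean distance between ROI centroids
    (motion artefacts inflate short-distance connections, giving a negative
    value).
    """
    parts = stack.participants
    motion = np.array([float(motion_totals[p]) for p in parts])
    if np.ptp(motion) == 0:
        raise ValueError("constant motion vector")
    vecs = np.stack([stack.get(p, session, measure).lower_triangle() for p in parts])
    i, j = np.tril_indices(stack.n_rois, k=-1)
    cent = np.stack([np.asarray(roi_centroids[r], dtype=float) for r in stack.roi_ids])
    dists = np.linalg.norm(cent[i] - cent[j], axis=1)
    mc = motion - motion.mean()
    mn = np.sqrt(mc @ mc)
    V = vecs - vecs.mean(axis=0)
    vn = np.sqrt((V**2).sum(axis=0))
    ok = vn > 0
    corrs = np.full(vecs.shape[1], np.nan)
    corrs[ok] = (V[:, ok].T @ mc) / (vn[ok] * mn)
    mean_corr = float(np.nanmean(corrs))
    valid = np.isfinite(corrs)
    distance_dependence = pearson(dists[valid], corrs[valid])
    return mean_corr, distance_dependence


def structure_function_similarity(
    fc: ConnectivityMatrix, sc: ConnectivityMatrix, mode: str = "all"
) -> float:
    """Spearman correspondence of functional and structural connectivity.

    Computed over lower-triangle entries; ``positive_only`` restricts to
    connections positive in both matrices (connection-strength distributions
    are positively skewed, hence the rank correlation).
    """
    if tuple(fc.roi_ids) != tuple(sc.roi_ids):
        raise ValueError("matrices have different ROI ids")
    f = fc.lower_triangle()
    s = sc.lower_triangle()
    if mode == "positive_only":
        keep = (f > 0) & (s > 0)
        f, s = f[keep], s[keep]
    elif mode != "all":
        raise ValueError("mode must be 'all' or 'positive_only'")
    if f.size < 3:
        raise ValueError("fewer than 3 eligible connection pairs")
    return float(spearmanr(f, s).statistic)


# ---------------------------------------------------------------------------
# structural covariance
# ---------------------------------------------------------------------------

def structural_covariance(
    gm_blocks, measure: str, roi_ids=None
) -> ConnectivityMatrix:
    """Structural covariance network from residualized grey-matter volumes.

    ``gm_blocks`` holds one participants x voxels matrix per ROI (total-GM
    residualization already applied); participants play the role of time
    points and the same estimator code path as functional connectivity is
    used, including the truncation count.
    """
    if isinstance(gm_blocks, dict):
        roi_ids = tuple(gm_blocks)
        gm_blocks = list(gm_blocks.values())
    n_part = np.asarray(gm_blocks[0]).shape[0]
    if n_part < 5:
        raise ValueError("need at least 5 participants")
    return connectivity_matrix(gm_blocks, measure, roi_ids=roi_ids)


def zero_weakest(mat: ConnectivityMatrix, n_zero: int) -> ConnectivityMatrix:
    """Zero the ``n_zero`` weakest-|value| connections (control analysis).

    Matches the number of truncated (negative distance covariance)
    connections in a distance-correlation matrix so that Pearson-based
    matrices have the same number of exact zeros.
    """
    values = mat.values.copy()
    i, j = np.tril_indices(values.shape[0], k=-1)
    order = np.argsort(np.abs(values[i, j]))[:n_zero]
    values[i[order], j[order]] = 0.0
    values[j[order], i[order]] = 0.0
    return ConnectivityMatrix(values, measure=mat.measure, roi_ids=mat.roi_ids,
                              n_truncated=mat.n_truncated)
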