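"""Synthetic multi-participant, two-session cohort generation and pipeline.

The generator emulates the structure that matters for comparing connectivity
measures: a modular ground-truth network shared by a participant's two
sessions (so true test-retest reliability exists), ROIs that are either
homogeneous (every voxel carries the region's signal) or inhomogeneous (two
anticorrelated sub-populations whose mixing fraction is participant-specific
but stable across sessions), independent voxel noise, optional AR(1)
temporal autocorrelation, and optional motion-coupled artefacts.  Two
sessions of different length (261 and 152 volumes at TR = 1.97 s) mirror a
typical test-retest resting-state design.

Two paths are provided: a fast in-memory path (`generate_cohort_blocks`)
that yields ROI voxel blocks directly, and a full on-disk path
(`generate_cohort` / `run_pipeline`) that writes NIfTI volumes, motion
files and tissue maps and then runs extraction, confound regression,
optional prewhitening, and connectivity estimation end to end.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dcor_core import connectivity_matrix
from .evaluation import SubjectSessionStack
from .parcellation import (
    Parcellation,
    analysis_mask,
    coverage_filter,
    extract_roi_blocks,
    tissue_nuisance_mask,
)
from .preprocess import (
    build_design,
    dct_basis,
    expand_signals,
    fit_autocorr,
    glm_residuals,
    prewhiten,
    rms_displacement,
)
from .simulate import _ar1_filter

__all__ = [
    "CohortSpec",
    "CohortBlocks",
    "generate_cohort_blocks",
    "generate_cohort",
    "run_pipeline",
    "stack_from_blocks",
    "config_hash",
]

log = logging.getLogger("dcorconn")

CONFOUND_OPTIONS = ("N", "C", "CW", "CWG")


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters of a synthetic two-session cohort.

    ``inhomogeneity`` is the fraction of ROIs containing two anticorrelated
    voxel sub-populations; the participant-specific share of the first
    sub-population is drawn uniformly from ``subpop_fraction_range`` and
    perturbed per session by a normal jitter of SD
    ``subpop_session_jitter`` (emulating between-session differences in head
    position and coregistration, which change how anatomical sub-populations
    map onto the same atlas voxels).  ``ar1`` applies a
    first-order autoregressive filter to the latent signals (0 emulates
    already-prewhitened residuals).  ``motion_artifact_gain`` couples a
    low-rank artefact, correlated with the generated motion trace, into the
    voxel data with spatially smooth ROI gains.
    """

    n_participants: int = 20
    session_lengths: tuple[int, int] = (261, 152)
    tr: float = 1.97
    grid_shape: tuple[int, int, int] = (20, 20, 10)
    n_rois: int = 8
    voxels_per_roi: int = 20
    n_modules: int = 2
    within_r: float = 0.5
    between_r: float = 0.1
    inhomogeneity: float = 0.5
    subpop_fraction_range: tuple[float, float] = (0.35, 0.65)
    subpop_session_jitter: float = 0.1
    voxel_noise_sd: float = 0.2
    ar1: float = 0.0
    motion_sd: float = 0.05
    motion_artifact_gain: float = 0.0
    gm_noise_sd: float = 0.3
    seed: int | None = None

    def __post_init__(self):
        if min(self.session_lengths) < 8:
            raise ValueError("session lengths must be >= 8")
        if not 0.0 <= self.inhomogeneity <= 1.0:
            raise ValueError("inhomogeneity fraction must lie in [0, 1]")


def _true_covariance(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Modular R x R signal covariance and the module assignment."""
    modules = np.arange(spec.n_rois) % spec.n_modules
    same = modules[:, None] == modules[None, :]
    C = np.where(same, spec.within_r, spec.between_r).astype(float)
    np.fill_diagonal(C, 1.0)
    if np.linalg.eigvalsh(C).min() <= 0:
        raise ValueError("infeasible network covariance")
    return C, modules


@dataclass
class CohortBlocks:
    """In-memory cohort: ROI voxel blocks plus ground truth."""

    spec: CohortSpec
    blocks: dict  # (participant, session) -> list of n x v arrays
    truth: np.ndarray  # R x R generating signal correlation matrix
    modules: np.ndarray
    inhomogeneous: np.ndarray  # boolean per ROI
    subpop_fractions: np.ndarray  # participants x R
    motion_totals: dict  # participant -> scalar summary (session 1)
    centroids: dict  # roi_id -> 3-vector (mm)
    roi_ids: tuple = ()


def _roi_boxes(spec: CohortSpec) -> dict[int, np.ndarray]:
    """Place each ROI as a small contiguous box inside the grid.

    Returns roi_id -> array of C-order linear voxel indices; box shape is
    chosen to hold exactly ``voxels_per_roi`` voxels.
    """
    gx, gy, gz = spec.grid_shape
    v = spec.voxels_per_roi
    # box: v = bx * by * 1 with bx as square as possible
    bx = int(np.floor(np.sqrt(v)))
    while v % bx:
        bx -= 1
    by = v // bx
    per_row = max(1, (gx - 1) // (bx + 1))
    boxes = {}
    for k in range(spec.n_rois):
        row, col = divmod(k, per_row)
        x0 = 1 + col * (bx + 1)
        y0 = 1 + (row % max(1, (gy - 1) // (by + 1))) * (by + 1)
        z0 = 1 + (row // max(1, (gy - 1) // (by + 1))) * 2
        if x0 + bx > gx or y0 + by > gy or z0 >= gz:
            raise ValueError("grid too small for requested ROIs")
        xs, ys, zs = np.meshgrid(
            np.arange(x0, x0 + bx), np.arange(y0, y0 + by), [z0], indexing="ij"
        )
        boxes[k + 1] = np.ravel_multi_index(
            (xs.ravel(), ys.ravel(), zs.ravel()), spec.grid_shape
        )
    return boxes


def build_atlas(spec: CohortSpec) -> Parcellation:
    """Label volume with the cohort's ROI boxes."""
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    flat = labels.ravel()
    for rid, idx in _roi_boxes(spec).items():
        flat[idx] = rid
    affine = np.diag([3.0, 3.0, 4.0, 1.0])  # voxel size in mm
    return Parcellation(labels, affine)


def _motion_trace(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """n x 6 random-walk rigid-body parameters (mm, rad)."""
    steps = rng.normal(0.0, sd, size=(n, 6))
    steps[:, 3:] *= 0.01  # rotations are small (radians)
    steps[0] = 0.0
    return np.cumsum(steps, axis=0)


def _session_signals(
    rng: np.random.Generator, n: int, chol: np.ndarray, ar1: float
) -> np.ndarray:
    """n x R latent ROI signals with the target covariance and AR(1) filter."""
    S = rng.standard_normal((n, chol.shape[0])) @ chol.T
    if ar1 > 0:
        S = np.column_stack([_ar1_filter(S[:, k], ar1) for k in range(S.shape[1])])
    return S


def generate_cohort_blocks(spec: CohortSpec) -> CohortBlocks:
    """Fast in-memory cohort of ROI voxel blocks.

    Deterministic given ``spec.seed``.  Within a participant the two
    sessions share the ground-truth network and sub-population mixing but
    have independent signal realizations.
    """
    rng = np.random.default_rng(spec.seed)
    C, modules = _true_covariance(spec)
    chol = np.linalg.cholesky(C)
    R, v = spec.n_rois, spec.voxels_per_roi
    n_inhom = int(round(spec.inhomogeneity * R))
    inhom = np.zeros(R, dtype=bool)
    inhom[rng.choice(R, size=n_inhom, replace=False)] = True
    lo, hi = spec.subpop_fraction_range
    fractions = rng.uniform(lo, hi, size=(spec.n_participants, R))

    atlas = build_atlas(spec)
    centroids = atlas.centroids()
    # spatially smooth artefact gain: decays from a focus point
    cent_arr = np.stack([centroids[r] for r in atlas.roi_ids])
    focus = cent_arr.mean(axis=0) + np.array([-15.0, -15.0, 0.0])
    gains = np.exp(-np.linalg.norm(cent_arr - focus, axis=1) / 20.0)

    blocks: dict = {}
    motion_totals: dict = {}
    for p in range(spec.n_participants):
        motion_level = float(rng.lognormal(mean=0.0, sigma=0.5))
        for sess_idx, n in enumerate(spec.session_lengths):
            session = sess_idx + 1
            S = _session_signals(rng, n, chol, spec.ar1)
            motion = _motion_trace(rng, n, spec.motion_sd * motion_level)
            trace = rms_displacement(motion)
            if session == 1:
                motion_totals[p] = trace.total
            artifact = _ar1_filter(rng.standard_normal(n), 0.5)
            roi_blocks = []
            for k in range(R):
                if inhom[k]:
                    f = float(np.clip(
                        fractions[p, k] + rng.normal(0.0, spec.subpop_session_jitter),
                        0.05, 0.95,
                    ))
                    n_a = int(round(f * v))
                    sig = np.column_stack(
                        [np.tile(S[:, k : k + 1], (1, n_a)), np.tile(-S[:, k : k + 1], (1, v - n_a))]
                    )
                else:
                    sig = np.tile(S[:, k : k + 1], (1, v))
                block = sig + rng.normal(0.0, spec.voxel_noise_sd, size=(n, v))
                if spec.motion_artifact_gain > 0:
                    block = block + (
                        spec.motion_artifact_gain * motion_level * gains[k] * artifact
                    )[:, None]
                roi_blocks.append(block)
            blocks[(p, session)] = roi_blocks

    return CohortBlocks(
        spec=spec,
        blocks=blocks,
        truth=C,
        modules=modules,
        inhomogeneous=inhom,
        subpop_fractions=fractions,
        motion_totals=motion_totals,
        centroids=centroids,
        roi_ids=atlas.roi_ids,
    )


def stack_from_blocks(cohort: CohortBlocks, measures=("pcor", "mvdcor")) -> SubjectSessionStack:
    """Estimate connectivity for every participant/session/measure."""
    stack = SubjectSessionStack()
    for (p, session), roi_blocks in cohort.blocks.items():
        for measure in measures:
            mat = connectivity_matrix(roi_blocks, measure, roi_ids=cohort.roi_ids)
            stack.add(p, session, measure, mat)
    return stack


# ---------------------------------------------------------------------------
# on-disk dataset
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec, outdir) -> Path:
    """Write a full synthetic dataset: 4-D images, atlas, motion, tissue, GM.

    Layout (BIDS-inspired, not validated)::

        outdir/
          atlas.nii.gz
          tissue_gm.nii.gz  tissue_wm.nii.gz  tissue_csf.nii.gz
          sub-XX/ses-Y/func.nii.gz
          sub-XX/ses-Y/motion.txt
          sub-XX/anat_gm.nii.gz
          manifest.json

    The manifest records the spec and ground truth so every evaluation
    metric can be scored without re-reading generator code.
    """
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort_blocks(spec)
    rng = np.random.default_rng(None if spec.seed is None else spec.seed + 1)
    atlas = build_atlas(spec)
    atlas.to_nifti(outdir / "atlas.nii.gz")
    boxes = _roi_boxes(spec)

    # tissue probability maps: GM inside ROIs, WM shell elsewhere, CSF corner
    gm_p = np.zeros(spec.grid_shape)
    gm_p.ravel()[np.concatenate(list(boxes.values()))] = 0.95
    wm_p = np.where(gm_p > 0, 0.02, 0.0)
    wm_p[..., -3:] = 0.9
    gm_p[..., -3:] = 0.0
    csf_p = np.zeros(spec.grid_shape)
    csf_p[:2, :2, :] = 0.95
    wm_p[:2, :2, :] = 0.0
    for name, vol in (("gm", gm_p), ("wm", wm_p), ("csf", csf_p)):
        nib.save(nib.Nifti1Image(vol.astype(np.float32), atlas.affine),
                 str(outdir / f"tissue_{name}.nii.gz"))

    # grey-matter volumes across participants: ROI-level covariance reuses
    # the functional ground truth, plus a total-GM (global scale) component
    R = spec.n_rois
    chol = np.linalg.cholesky(cohort.truth)
    traits = rng.standard_normal((spec.n_participants, R)) @ chol.T
    global_scale = rng.normal(1.0, 0.1, size=spec.n_participants)

    motion_rng = np.random.default_rng(None if spec.seed is None else spec.seed + 2)
    for p in range(spec.n_participants):
        subdir = outdir / f"sub-{p:02d}"
        for sess_idx, n in enumerate(spec.session_lengths):
            session = sess_idx + 1
            sdir = subdir / f"ses-{session}"
            sdir.mkdir(parents=True, exist_ok=True)
            vol = np.zeros(spec.grid_shape + (n,), dtype=np.float32)
            flat = vol.reshape(-1, n)
            for rid, roi_block in zip(atlas.roi_ids, cohort.blocks[(p, session)]):
                flat[boxes[rid]] = (100.0 + 10.0 * roi_block).T
            # WM/CSF compartments carry their own fluctuating nuisance signals
            wm_sig = _ar1_filter(motion_rng.standard_normal(n), 0.3)
            csf_sig = _ar1_filter(motion_rng.standard_normal(n), 0.3)
            wm_idx = np.flatnonzero(tissue_nuisance_mask(gm_p, wm_p).ravel())
            csf_idx = np.flatnonzero(tissue_nuisance_mask(gm_p, csf_p).ravel())
            flat[wm_idx] = 100.0 + 2.0 * wm_sig + motion_rng.normal(0, 0.5, (wm_idx.size, n))
            flat[csf_idx] = 100.0 + 2.0 * csf_sig + motion_rng.normal(0, 0.5, (csf_idx.size, n))
            nib.save(nib.Nifti1Image(vol, atlas.affine), str(sdir / "func.nii.gz"))
            motion = _motion_trace(motion_rng, n, spec.motion_sd)
            np.savetxt(sdir / "motion.txt", motion, fmt="%.8f")
        gm_vol = np.zeros(spec.grid_shape, dtype=np.float32)
        gflat = gm_vol.ravel()
        for k, rid in enumerate(atlas.roi_ids):
            gflat[boxes[rid]] = global_scale[p] * (
                5.0 + traits[p, k] + rng.normal(0, spec.gm_noise_sd, boxes[rid].size)
            )
        nib.save(nib.Nifti1Image(gm_vol, atlas.affine), str(subdir / "anat_gm.nii.gz"))

    manifest = {
        "spec": asdict(spec),
        "roi_ids": list(atlas.roi_ids),
        "truth": cohort.truth.tolist(),
        "modules": cohort.modules.tolist(),
        "inhomogeneous_rois": cohort.inhomogeneous.tolist(),
        "subpop_fractions": cohort.subpop_fractions.tolist(),
        "motion_totals": {str(k): v for k, v in cohort.motion_totals.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("wrote synthetic cohort to %s", outdir)
    return outdir


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "dataset": None,
    "atlas": None,
    "tr_seconds": 1.97,
    "highpass_hz": 0.008,
    "band_hz": None,
    "whiten": True,
    "confounds": "CW",
    "measures": ["pcor", "mvdcor"],
    "mask_threshold": 0.7,
    "coverage_threshold": 0.25,
}


def config_hash(config: dict) -> str:
    """Stable hash of a pipeline configuration."""
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    merged = dict(DEFAULT_CONFIG)
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged.update(config)
    if merged["dataset"] is None:
        raise ValueError("config must name a dataset directory")
    if merged["confounds"] not in CONFOUND_OPTIONS:
        raise ValueError(f"confounds must be one of {CONFOUND_OPTIONS}")
    return merged


def _confound_design(motion, wm, csf, gs, option: str) -> pd.DataFrame:
    """Nuisance regressors for one of the N / C / CW / CWG options.

    N: motion expansions only; C adds the CSF signal expansion; CW adds WM;
    CWG additionally expands the global (whole-analysis-mask mean) signal.
    """
    names = ["tx", "ty", "tz", "rx", "ry", "rz"]
    cols = [np.asarray(motion, dtype=float)]
    if option in ("C", "CW", "CWG"):
        cols.append(np.asarray(csf, dtype=float)[:, None])
        names.append("csf")
    if option in ("CW", "CWG"):
        cols.append(np.asarray(wm, dtype=float)[:, None])
        names.append("wm")
    if option == "CWG":
        cols.append(np.asarray(gs, dtype=float)[:, None])
        names.append("global")
    return expand_signals(np.column_stack(cols), names)


def run_pipeline(config) -> tuple[SubjectSessionStack, dict]:
    """Run extraction -> confound GLM -> (optional) prewhitening -> connectivity.

    ``config`` is a mapping or a YAML path with the keys of
    ``DEFAULT_CONFIG``.  Returns the subject/session stack of connectivity
    matrices and a report with the coverage table, config hash and per-stage
    notes.  Deterministic: rerunning with the same config on the same
    dataset is bit-identical.
    """
    import nibabel as nib

    cfg = _load_config(config)
    dataset = Path(cfg["dataset"])
    atlas_path = Path(cfg["atlas"]) if cfg["atlas"] else dataset / "atlas.nii.gz"
    atlas = Parcellation.from_nifti(atlas_path)
    manifest = json.loads((dataset / "manifest.json").read_text())

    gm_p = np.asanyarray(nib.load(str(dataset / "tissue_gm.nii.gz")).dataobj)
    wm_p = np.asanyarray(nib.load(str(dataset / "tissue_wm.nii.gz")).dataobj)
    csf_p = np.asanyarray(nib.load(str(dataset / "tissue_csf.nii.gz")).dataobj)
    wm_mask = tissue_nuisance_mask(gm_p, wm_p)
    csf_mask = tissue_nuisance_mask(gm_p, csf_p)

    stack = SubjectSessionStack()
    coverage_reports = []
    participants = sorted(d.name for d in dataset.glob("sub-*"))
    log.info("pipeline start: %d participants, confounds=%s, whiten=%s",
             len(participants), cfg["confounds"], cfg["whiten"])
    for sub in participants:
        p = int(sub.split("-")[1])
        for sdir in sorted((dataset / sub).glob("ses-*")):
            session = int(sdir.name.split("-")[1])
            img = nib.load(str(sdir / "func.nii.gz"))
            data = np.asanyarray(img.dataobj).astype(float)
            n = data.shape[3]
            mask = analysis_mask(data.mean(axis=3), threshold=cfg["mask_threshold"])
            report, parc = coverage_filter(atlas, mask, threshold=cfg["coverage_threshold"])
            report["participant"], report["session"] = p, session
            coverage_reports.append(report)
            blocks = extract_roi_blocks(data, parc)

            motion = np.loadtxt(sdir / "motion.txt")
            flat = data.reshape(-1, n)
            wm_sig = flat[wm_mask.ravel()].mean(axis=0)
            csf_sig = flat[csf_mask.ravel()].mean(axis=0)
            gs_sig = flat[mask.ravel()].mean(axis=0)
            confounds = _confound_design(motion, wm_sig, csf_sig, gs_sig, cfg["confounds"])
            if cfg["band_hz"]:
                dct = dct_basis(n, cfg["tr_seconds"], band_hz=tuple(cfg["band_hz"]))
            else:
                dct = dct_basis(n, cfg["tr_seconds"], highpass_hz=cfg["highpass_hz"])
            design = build_design(confounds, dct, intercept=True)

            clean = {}
            for rid, block in blocks.items():
                resid = glm_residuals(block, design)
                if cfg["whiten"]:
                    model = fit_autocorr(resid, tr=cfg["tr_seconds"])
                    resid = prewhiten(resid, model)
                clean[rid] = resid
            for measure in cfg["measures"]:
                mat = connectivity_matrix(
                    list(clean.values()), measure, roi_ids=tuple(clean)
                )
                stack.add(p, session, measure, mat)
            log.info("processed %s %s (%d ROIs kept)", sub, sdir.name, len(blocks))

    report = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "coverage": pd.concat(coverage_reports, ignore_index=True),
        "manifest": manifest,
        "participants": participants,
    }
    return stack, report
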