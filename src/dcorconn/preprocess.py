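"""Time-series conditioning applied before connectivity estimation.

The pipeline implemented here mirrors standard resting-state fMRI practice:

1. expand the six rigid-body motion parameters plus the average white-matter
   and CSF signals into 32 nuisance regressors (base, temporal derivative,
   and their squares);
2. add a discrete-cosine (DCT) basis to the GLM to implement high-pass or
   band-pass filtering;
3. regress the nuisance design out of every voxel time series;
4. model the residual temporal autocorrelation per ROI with a white-noise +
   8-exponential covariance family fitted by (Re)ML, and prewhiten the
   residuals with the inverse symmetric square root of that covariance.

Correlational connectivity measures assume exchangeable time points, so
residual autocorrelation biases them; prewhitening restores exchangeability
to the extent the covariance family captures the autocorrelation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import toeplitz

__all__ = [
    "expand_signals",
    "expand_confounds",
    "dct_basis",
    "build_design",
    "glm_residuals",
    "AutocorrModel",
    "fit_autocorr",
    "prewhiten",
    "lag1_autocorr",
    "MotionTrace",
    "rms_displacement",
    "residualize_total_gm",
    "DEFAULT_HALF_LIVES",
]

#: half-lives (in units of TR) of the exponential autocovariance basis
DEFAULT_HALF_LIVES = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0)

CONFOUND_BASES = ("tx", "ty", "tz", "rx", "ry", "rz", "wm", "csf")


def _backward_diff(x: np.ndarray) -> np.ndarray:
    """Backward difference with the first sample set to 0."""
    d = np.zeros_like(x)
    d[1:] = np.diff(x, axis=0)
    return d


def expand_signals(base: np.ndarray, names: Sequence[str]) -> pd.DataFrame:
    """Expand base signals into base / derivative / squares / squared derivative.

    The derivative is the backward difference with first element 0; squares
    are computed after differencing.  Yields 4 columns per base signal.
    """
    base = np.asarray(base, dtype=float)
    if base.ndim == 1:
        base = base[:, None]
    deriv = _backward_diff(base)
    blocks = [base, deriv, base**2, deriv**2]
    labels = (
        list(names)
        + [f"{b}_d" for b in names]
        + [f"{b}_sq" for b in names]
        + [f"{b}_d_sq" for b in names]
    )
    return pd.DataFrame(np.column_stack(blocks), columns=labels)


def expand_confounds(motion, wm, csf) -> pd.DataFrame:
    """Expand 6 motion parameters + WM + CSF signals into 32 regressors.

    For each of the 8 base signals the expansion is: base, first-order
    temporal derivative (backward difference, first element 0), squared
    base, squared derivative -- 32 columns in total.
    """
    motion = np.asarray(motion, dtype=float)
    wm = np.asarray(wm, dtype=float).ravel()
    csf = np.asarray(csf, dtype=float).ravel()
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be an n x 6 matrix")
    n = motion.shape[0]
    if wm.size != n or csf.size != n:
        raise ValueError("WM/CSF signal length does not match motion parameters")
    if n < 3:
        raise ValueError("need at least 3 time points")
    return expand_signals(np.column_stack([motion, wm, csf]), CONFOUND_BASES)


def _dct_columns(n: int, ks) -> np.ndarray:
    t = np.arange(n)
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2 * n)) for k in ks]
    if not cols:
        return np.empty((n, 0))
    C = np.column_stack(cols)
    return C / np.linalg.norm(C, axis=0)


def dct_basis(
    n: int,
    tr: float,
    highpass_hz: float | None = None,
    band_hz: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """DCT regressor set implementing a high-pass or band-pass filter.

    The k-th DCT component has frequency ``k / (2 n TR)``.  High-pass:
    return the ``floor(2 n TR f_hp)`` lowest-frequency components (their
    removal in the GLM suppresses frequencies below ``f_hp``).  Band-pass:
    return the components below ``f_lo`` plus those above ``f_hi``, so that
    regressing them out retains the pass band.  Columns are mutually
    orthogonal and unit norm.
    """
    if n < 8:
        raise ValueError("need at least 8 time points for a DCT filter basis")
    nyquist = 1.0 / (2.0 * tr)
    if (highpass_hz is None) == (band_hz is None):
        raise ValueError("specify exactly one of highpass_hz or band_hz")
    if highpass_hz is not None:
        if not 0 <= highpass_hz < nyquist:
            raise ValueError("high-pass cutoff out of range")
        k_max = int(np.floor(2 * n * tr * highpass_hz))
        ks = list(range(1, k_max + 1))
    else:
        f_lo, f_hi = band_hz
        if not (0 < f_lo < f_hi <= nyquist):
            raise ValueError("band limits out of range or inverted")
        k_lo = int(np.floor(2 * n * tr * f_lo))
        k_hi = int(np.ceil(2 * n * tr * f_hi))
        ks = list(range(1, k_lo + 1)) + list(range(k_hi, n))
    return pd.DataFrame(_dct_columns(n, ks), columns=[f"dct_{k:03d}" for k in ks])


def build_design(*parts: pd.DataFrame | np.ndarray, intercept: bool = True) -> pd.DataFrame:
    """Assemble a design matrix from labelled parts, optionally + intercept."""
    frames = []
    if intercept:
        n = np.asarray(parts[0]).shape[0]
        frames.append(pd.DataFrame({"intercept": np.ones(n)}))
    for p in parts:
        frames.append(p if isinstance(p, pd.DataFrame) else pd.DataFrame(np.asarray(p)))
    X = pd.concat([f.reset_index(drop=True) for f in frames], axis=1)
    zero = (X == 0).all(axis=0)
    if zero.any():
        X = X.loc[:, ~zero]
    return X


def glm_residuals(Y, X) -> np.ndarray:
    """Residuals of a voxelwise GLM: Y minus its projection onto span(X).

    Collinear columns are handled by the least-squares pseudoinverse (a
    warning is emitted when the design is rank deficient); residuals are
    orthogonal to every design column and re-residualizing is a no-op.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    Xv = np.asarray(X, dtype=float)
    if Xv.ndim == 1:
        Xv = Xv[:, None]
    if Xv.shape[0] != Y.shape[0]:
        raise ValueError("design and data have different numbers of rows")
    rank = np.linalg.matrix_rank(Xv)
    if rank >= Xv.shape[0]:
        raise ValueError("design matrix is full row rank: residuals would be zero")
    if rank < Xv.shape[1]:
        warnings.warn(
            f"rank-deficient design ({rank}/{Xv.shape[1]}): collinear columns ignored",
            RuntimeWarning,
        )
    beta, *_ = np.linalg.lstsq(Xv, Y, rcond=None)
    return Y - Xv @ beta


@dataclass
class AutocorrModel:
    """Temporal covariance model: white noise + exponential components.

    ``weights[0]`` is the white-noise variance; ``weights[m]`` scales the
    exponential autocovariance ``exp(-|dt| * ln2 / half_lives[m-1])`` with
    ``dt`` in TR units.  The implied n x n covariance is symmetric positive
    definite whenever the white-noise weight is positive.
    """

    weights: np.ndarray
    half_lives: tuple = DEFAULT_HALF_LIVES
    tr: float = 1.0
    n: int = 0

    def basis(self, n: int | None = None) -> list[np.ndarray]:
        n = n or self.n
        lags = np.arange(n, dtype=float)
        out = [np.eye(n)]
        for h in self.half_lives:
            out.append(toeplitz(np.exp(-lags * np.log(2.0) / h)))
        return out

    def covariance(self, n: int | None = None) -> np.ndarray:
        n = n or self.n
        Q = self.basis(n)
        return sum(w * q for w, q in zip(self.weights, Q))

    def implied_lag1(self) -> float:
        """Lag-1 autocorrelation of the fitted covariance."""
        acf0 = float(self.weights[0]) + float(self.weights[1:].sum())
        acf1 = float(
            sum(
                w * np.exp(-np.log(2.0) / h)
                for w, h in zip(self.weights[1:], self.half_lives)
            )
        )
        return acf1 / acf0


def fit_autocorr(
    resid,
    tr: float = 1.0,
    half_lives: tuple = DEFAULT_HALF_LIVES,
    max_iter: int = 64,
    tol: float = 1e-6,
) -> AutocorrModel:
    """Fit the white-noise + exponential covariance family by ML/Fisher scoring.

    The sample covariance is pooled over voxels (the design has already been
    regressed out, so maximising this pooled likelihood is the restricted
    likelihood of the original model).  Hyperparameters are kept
    non-negative by projection.  On failure to produce a usable fit the
    model falls back to white noise with a warning.
    """
    R = np.asarray(resid, dtype=float)
    if R.ndim == 1:
        R = R[:, None]
    n, v = R.shape
    if v < 1:
        raise ValueError("need at least one voxel")
    # pooled sample covariance across voxels, additionally averaged along
    # diagonals: the model family is stationary, so only the Toeplitz part
    # of the sample covariance is informative, and pooling lags tames the
    # variance of the rank-v voxel covariance
    Sv = (R @ R.T) / v
    acov = np.array([np.mean(np.diagonal(Sv, k)) for k in range(n)])
    S = toeplitz(acov)
    s2 = float(np.trace(S) / n)
    if s2 <= 0:
        raise ValueError("residuals have zero variance")

    model = AutocorrModel(np.zeros(len(half_lives) + 1), half_lives, tr, n)
    Q = model.basis(n)
    m = len(Q)
    lam = np.zeros(m)
    lam[0] = s2  # start at white noise
    eps = 1e-8 * s2

    def negll_grad(l):
        """Negative log-likelihood (up to constants) and its gradient."""
        Sig = sum(li * q for li, q in zip(l, Q))
        sign, logdet = np.linalg.slogdet(Sig)
        if sign <= 0:
            return np.inf, np.zeros(m)
        P = np.linalg.inv(Sig)
        PSP = P @ S @ P
        f = 0.5 * (logdet + np.sum(P * S))
        g = np.array([0.5 * (np.sum(P * q) - np.sum(PSP * q)) for q in Q])
        return f, g

    # bounded quasi-Newton on the pooled likelihood: the exponential
    # components are nearly collinear, so box-constrained L-BFGS-B is far
    # more stable here than an unguarded Newton/Fisher step
    from scipy.optimize import minimize

    res = minimize(
        negll_grad,
        lam,
        jac=True,
        method="L-BFGS-B",
        bounds=[(eps, None)] + [(0.0, None)] * (m - 1),
        options={"maxiter": max_iter, "ftol": tol * 1e-3},
    )
    failed = not np.all(np.isfinite(res.x))
    if not failed:
        lam = res.x

    if failed or not np.all(np.isfinite(lam)):
        warnings.warn(
            "autocorrelation model fit did not converge; falling back to white noise",
            RuntimeWarning,
        )
        lam = np.zeros(m)
        lam[0] = s2

    model.weights = lam
    return model


def prewhiten(resid, model: AutocorrModel) -> np.ndarray:
    """Whiten residuals with the inverse symmetric square root of the model.

    For data generated from the fitted covariance the output time points are
    (approximately) exchangeable: unit variance, near-zero lag-1
    autocorrelation.
    """
    R = np.asarray(resid, dtype=float)
    if R.ndim == 1:
        R = R[:, None]
    n = R.shape[0]
    if model.n and model.n != n:
        raise ValueError("model was fitted for a different number of time points")
    Sigma = model.covariance(n)
    evals, evecs = np.linalg.eigh(Sigma)
    if evals.min() <= 0:
        raise ValueError("model covariance is not positive definite")
    W = (evecs / np.sqrt(evals)) @ evecs.T
    return W @ R


def lag1_autocorr(ts) -> float:
    """Normalised lag-1 autocorrelation r1 = pearson(ts[1:], ts[:-1])."""
    x = np.asarray(ts, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("need at least 3 time points")
    from .dcor_core import pearson

    return pearson(x[1:], x[:-1])


@dataclass
class MotionTrace:
    """Per-volume head displacement (mm) and its scalar summary."""

    per_volume: np.ndarray
    total: float


def rms_displacement(motion, radius_mm: float = 80.0) -> MotionTrace:
    """RMS volume-to-volume displacement from 6 rigid-body parameters.

    Columns are 3 translations (mm) then 3 rotations (radians).  The
    per-volume value is the Jenkinson-style RMS displacement averaged over a
    sphere of ``radius_mm`` centred at the origin, using the small-angle
    approximation for the rotation contribution:

        d_t = sqrt(|dt_trans|^2 + (2/5) R^2 |dt_rot|^2)

    The first volume has displacement 0; ``total`` is the mean over the
    n - 1 volume-to-volume values.
    """
    M = np.asarray(motion, dtype=float)
    if M.ndim != 2 or M.shape[1] != 6:
        raise ValueError("motion must be an n x 6 matrix (3 translations, 3 rotations)")
    d = np.diff(M, axis=0)
    trans = d[:, :3]
    rot = d[:, 3:]
    disp = np.sqrt((trans**2).sum(axis=1) + (2.0 / 5.0) * radius_mm**2 * (rot**2).sum(axis=1))
    per_volume = np.concatenate([[0.0], disp])
    total = float(disp.mean()) if disp.size else 0.0
    return MotionTrace(per_volume, total)


def residualize_total_gm(gm, total=None) -> np.ndarray:
    """Remove total-grey-matter differences from voxelwise GM volumes.

    Each voxel column (across participants) is residualized against the
    total-GM covariate with an intercept, leaving only regional variability.
    ``total`` defaults to the row sums of ``gm``.
    """
    G = np.asarray(gm, dtype=float)
    if G.ndim != 2 or G.shape[0] < 3:
        raise ValueError("need a participants x voxels matrix with >= 3 participants")
    t = G.sum(axis=1) if total is None else np.asarray(total, dtype=float).ravel()
    if t.size != G.shape[0]:
        raise ValueError("total-GM vector length mismatch")
    if np.ptp(t) == 0:
        raise ValueError("total-GM covariate is constant")
    X = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X, G, rcond=None)
    return G - X @ beta
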