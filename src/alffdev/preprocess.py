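"""Temporal preprocessing of resting-state 4D volumes.

The pipeline applied by :func:`preprocess_subject` is, in order:

1. discard the first ``n`` volumes (dummy scans),
2. spatial Gaussian smoothing,
3. voxelwise linear detrending,
4. nuisance regression (Friston-24 motion expansion + mean white-matter and
   cerebrospinal-fluid signals),
5. ideal band-pass filtering (default 0.01-0.08 Hz).

Registration steps (slice timing, realignment estimation, normalisation) are
out of scope: the data this package consumes are assumed to live on a common
grid already, with realignment parameters supplied as motion traces.

Every temporal operation here is linear in the data, which makes the stage
order auditable and lets the ALFF module cross-check the ideal band-pass
against its own spectral band selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.fft
from scipy import ndimage

from .datatypes import MotionTrace, Volume4D

__all__ = [
    "NuisanceSet",
    "PreprocessParams",
    "discard_initial_volumes",
    "motion_exclusion",
    "framewise_displacement",
    "smooth_gaussian",
    "detrend_linear",
    "friston24_expand",
    "extract_tissue_means",
    "regress_nuisance",
    "bandpass_filter",
    "preprocess_subject",
]

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class NuisanceSet:
    """A t x k matrix of nuisance regressors with column labels.

    By default k = 26: the Friston-24 motion expansion plus the mean WM and
    CSF signals.  No constant column is included; the regression adds its own
    intercept.
    """

    regressors: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.regressors = np.asarray(self.regressors, dtype=float)
        if self.regressors.ndim != 2:
            raise ValueError("regressors must be 2D (t x k)")
        if self.regressors.shape[1] != len(self.labels):
            raise ValueError("label count must match regressor columns")


@dataclass
class PreprocessParams:
    """Tunable constants of the preprocessing stage."""

    discard: int = 10
    fwhm_mm: float = 8.0
    band_hz: tuple[float, float] = (0.01, 0.08)
    exclude_trans_mm: float = 3.0
    exclude_rot_deg: float = 3.0
    fd_sphere_radius_mm: float = 50.0


def discard_initial_volumes(
    vol: Volume4D, motion: MotionTrace, n: int = 10
) -> tuple[Volume4D, MotionTrace]:
    """Drop the first ``n`` timepoints from the volume and motion trace jointly."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if vol.n_volumes <= n:
        raise ValueError(f"cannot discard {n} of {vol.n_volumes} volumes")
    if motion.n_volumes != vol.n_volumes:
        raise ValueError("motion trace and volume have different lengths")
    return vol.with_data(vol.data[..., n:]), MotionTrace(motion.params[n:], motion.tr_s)


def motion_exclusion(
    motion: MotionTrace, trans_mm: float = 3.0, rot_deg: float = 3.0
) -> bool:
    """Return True (exclude the subject) if head motion breaches the limits.

    The rule is the conventional one for cohort QC: exclude when the maximum
    absolute translation over the run exceeds ``trans_mm`` on any axis, or the
    maximum absolute rotation exceeds ``rot_deg`` (trace rotations are radians
    and converted before comparison).
    """
    max_trans = np.max(np.abs(motion.translations_mm))
    max_rot_deg = np.degrees(np.max(np.abs(motion.rotations_rad)))
    return bool(max_trans > trans_mm or max_rot_deg > rot_deg)


def framewise_displacement(
    motion: MotionTrace, sphere_radius_mm: float = 50.0
) -> tuple[np.ndarray, float]:
    """Power-style framewise displacement.

    FD_t = sum |delta translation_i| + r * sum |delta rotation_i| for t >= 2,
    with rotations mapped to arc length on a sphere of radius ``r`` (50 mm by
    default).  FD_1 is defined as 0 and the mean is taken over all frames.
    """
    if motion.n_volumes < 2:
        raise ValueError("need at least two frames for framewise displacement")
    d = np.diff(motion.params, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + sphere_radius_mm * np.abs(d[:, 3:]).sum(axis=1)
    fd = np.concatenate([[0.0], fd])
    return fd, float(fd.mean())


def smooth_gaussian(
    vol: Volume4D, fwhm_mm: float = 8.0, mask: np.ndarray | None = None
) -> Volume4D:
    """Convolve each frame with an isotropic Gaussian of the given FWHM (mm).

    sigma per axis is fwhm / (2 sqrt(2 ln 2)) converted to voxels.  Boundary
    handling is zero padding outside the grid; optional masked renormalisation
    (dividing by the smoothed mask) is off by default and only compensates
    edge attenuation inside ``mask``.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return vol.with_data(vol.data.copy())
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / v for v in vol.voxel_size_mm]
    out = ndimage.gaussian_filter(vol.data, sigma=sigma_vox + [0.0], mode="constant")
    if mask is not None:
        norm = ndimage.gaussian_filter(mask.astype(out.dtype), sigma=sigma_vox, mode="constant")
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(mask[..., None], out / np.maximum(norm, 1e-12)[..., None], out)
    return vol.with_data(out)


def _ramp_design(t: int) -> np.ndarray:
    ramp = np.arange(t, dtype=float)
    ramp -= ramp.mean()
    return np.column_stack([np.ones(t), ramp])


def detrend_linear(ts: np.ndarray) -> np.ndarray:
    """Residual of a least-squares fit of intercept + linear ramp.

    ``ts`` may be 1D (t,) or 2D (t, k); the fit is per column.
    """
    ts = np.asarray(ts)
    t = ts.shape[0]
    if t < 3:
        raise ValueError("need at least 3 timepoints to detrend")
    X = _ramp_design(t)
    beta, *_ = np.linalg.lstsq(X, ts.reshape(t, -1), rcond=None)
    resid = ts.reshape(t, -1) - X @ beta
    return resid.reshape(ts.shape).astype(ts.dtype, copy=False)


def friston24_expand(motion: MotionTrace) -> NuisanceSet:
    """Friston 24-parameter motion expansion.

    Columns are R(t), R(t)^2, R(t-1), R(t-1)^2 for each of the six rigid-body
    parameters; lagged rows at t=1 are zero-filled (toolbox convention).
    """
    if motion.n_volumes < 2:
        raise ValueError("need at least two frames")
    R = motion.params
    lag = np.vstack([np.zeros(6), R[:-1]])
    cols = np.hstack([R, R**2, lag, lag**2])
    names = [f"{p}{i}" for p in ("mot", "mot_sq", "lag", "lag_sq") for i in range(1, 7)]
    return NuisanceSet(cols, names)


def extract_tissue_means(
    vol: Volume4D, wm_mask: np.ndarray, csf_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame spatial mean of the signal within the WM and CSF masks."""
    out = []
    for name, mask in (("wm", wm_mask), ("csf", csf_mask)):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != vol.grid_dims:
            raise ValueError(f"{name} mask shape does not match volume grid")
        if not mask.any():
            raise ValueError(f"{name} mask is empty")
        out.append(vol.data[mask].mean(axis=0).astype(float))
    return out[0], out[1]


def regress_nuisance(
    vol: Volume4D, nuisance: NuisanceSet, mask: np.ndarray
) -> Volume4D:
    """Voxelwise least-squares removal of [intercept | nuisance regressors].

    Residuals are orthogonal to every retained regressor.  Rank-deficient
    designs (e.g. an all-zero motion trace) drop the dependent columns with a
    logged warning rather than failing.
    """
    t = vol.n_volumes
    Z = nuisance.regressors
    if Z.shape[0] != t:
        raise ValueError("nuisance rows must match volume timepoints")
    if t <= Z.shape[1] + 1:
        raise ValueError("need more timepoints than regressors")
    X = np.column_stack([np.ones(t), Z])
    # column-pivoted elimination of dependent columns via QR diagnostics
    keep = _independent_columns(X)
    if len(keep) < X.shape[1]:
        dropped = [
            (["intercept"] + list(nuisance.labels))[j]
            for j in range(X.shape[1])
            if j not in keep
        ]
        msg = f"nuisance design rank-deficient; dropping columns {dropped}"
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
        logger.warning(msg)
        X = X[:, keep]
    mask = np.asarray(mask, dtype=bool)
    Y = vol.data[mask].T.astype(float)  # t x V
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = np.zeros(vol.data.shape, dtype=resid.dtype)
    out[mask] = resid.T
    return vol.with_data(out)


def _independent_columns(X: np.ndarray, tol: float = 1e-10) -> list[int]:
    """Greedy left-to-right selection of linearly independent columns."""
    keep: list[int] = []
    basis = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        col = X[:, j]
        scale = np.linalg.norm(col)
        if scale <= tol:
            continue
        if basis.shape[1]:
            proj = basis @ (basis.T @ col)
            resid = col - proj
        else:
            resid = col
        if np.linalg.norm(resid) > tol * max(scale, 1.0):
            keep.append(j)
            basis = np.column_stack([basis, resid / np.linalg.norm(resid)])
    return keep


def bandpass_filter(
    vol: Volume4D,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    mask: np.ndarray | None = None,
) -> Volume4D:
    """Ideal frequency-domain band-pass filter.

    Each in-mask voxel series is DFT'd, all bins with frequency outside
    [low, high] (inclusive; DC and the mirrored negative frequencies handled
    by the real FFT) are zeroed, and the series inverted back to a real
    signal.  With this ideal filter, ALFF computed over the same band before
    and after filtering is identical to numerical tolerance.
    """
    t = vol.n_volumes
    nyquist = 1.0 / (2.0 * vol.tr_s)
    if not (0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] must satisfy 0 < low < high < Nyquist={nyquist}"
        )
    freqs = np.fft.rfftfreq(t, vol.tr_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    if mask is None:
        series = vol.data.reshape(-1, t)
    else:
        mask = np.asarray(mask, dtype=bool)
        series = vol.data[mask]
    spec = scipy.fft.rfft(series.astype(float), axis=-1)
    spec[:, ~keep] = 0.0
    filtered = scipy.fft.irfft(spec, n=t, axis=-1)
    if mask is None:
        out = filtered.reshape(vol.data.shape)
    else:
        out = np.zeros(vol.data.shape, dtype=filtered.dtype)
        out[mask] = filtered
    return vol.with_data(out)


def preprocess_subject(
    vol: Volume4D,
    motion: MotionTrace,
    brain_mask: np.ndarray,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray,
    params: PreprocessParams | None = None,
) -> tuple[Volume4D, float]:
    """Run the fixed preprocessing chain on one subject.

    Returns the preprocessed volume and the subject's mean framewise
    displacement (computed on the retained frames, used downstream as a
    group-model covariate).  The stage order is fixed and logged:
    discard -> smooth -> detrend -> nuisance regression -> band-pass.
    """
    params = params or PreprocessParams()
    vol, motion = discard_initial_volumes(vol, motion, params.discard)
    _, mean_fd = framewise_displacement(motion, params.fd_sphere_radius_mm)
    logger.info(
        "preprocess: discard=%d fwhm=%.1fmm band=%s", params.discard, params.fwhm_mm, params.band_hz
    )
    vol = smooth_gaussian(vol, params.fwhm_mm, mask=None)
    brain = np.asarray(brain_mask, dtype=bool)
    detr = np.zeros(vol.data.shape, dtype=float)
    detr[brain] = detrend_linear(vol.data[brain].T.astype(float)).T
    vol = vol.with_data(detr)
    wm_ts, csf_ts = extract_tissue_means(vol, wm_mask, csf_mask)
    fr24 = friston24_expand(motion)
    nuis = NuisanceSet(
        np.column_stack([fr24.regressors, wm_ts, csf_ts]), fr24.labels + ["wm", "csf"]
    )
    vol = regress_nuisance(vol, nuis, brain)
    vol = bandpass_filter(vol, params.band_hz[0], params.band_hz[1], brain)
    return vol, mean_fd
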