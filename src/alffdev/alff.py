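"""Amplitude of low-frequency fluctuations (ALFF).

ALFF indexes the strength of a voxel's spontaneous low-frequency activity:
the time series is Fourier transformed, the square root of the power
spectrum is taken, and the result is averaged over the low-frequency band
(0.01-0.08 Hz by default).  Per-subject maps are standardized by dividing by
the global (within-brain-mask) mean ALFF, which removes global scale
differences between subjects.

Spectral conventions (fixed and documented because unstandardized ALFF
values depend on them; standardization divides any fixed convention out):

* power per bin is ``|X_k|^2 / N`` with one-sided doubling of all bins other
  than DC and (for even N) Nyquist, so that the one-sided power sums to
  ``sum(ts^2)`` (Parseval);
* band-edge bins are included (``low <= f <= high``);
* no windowing or tapering is applied before the DFT;
* the global mean is taken over the brain mask only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft

from .datatypes import Volume4D

__all__ = ["ALFFMap", "compute_alff_voxel", "compute_alff_map", "standardize_global_mean"]


@dataclass
class ALFFMap:
    """Voxelwise ALFF values on a 3D grid.

    ``values`` is zero outside ``mask`` (sentinel).  When ``standardized`` is
    true the in-mask mean is 1 to numerical tolerance.
    """

    values: np.ndarray
    band_hz: tuple[float, float]
    mask: np.ndarray
    standardized: bool = False
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")

    def in_mask(self) -> np.ndarray:
        return self.values[self.mask]


def _band_bins(n: int, tr_s: float, band_hz: tuple[float, float]) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, tr_s)
    keep = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not keep.any():
        df = 1.0 / (n * tr_s)
        n_min = int(np.ceil(1.0 / (band_hz[1] * tr_s)))
        raise ValueError(
            f"no DFT bins inside band {band_hz} for n={n} (resolution {df:.5f} Hz); "
            f"need a series of at least ~{n_min} points"
        )
    return keep


def _one_sided_power(series: np.ndarray, n: int) -> np.ndarray:
    """One-sided power spectrum |X_k|^2/N with doubling of interior bins."""
    spec = scipy.fft.rfft(np.asarray(series, dtype=float), axis=-1)
    power = np.abs(spec) ** 2 / n
    mult = np.full(power.shape[-1], 2.0)
    mult[0] = 1.0
    if n % 2 == 0:
        mult[-1] = 1.0
    return power * mult


def compute_alff_voxel(
    ts: np.ndarray, tr_s: float, band_hz: tuple[float, float] = (0.01, 0.08)
) -> float:
    """ALFF of a single time series: mean sqrt(power) over in-band bins."""
    ts = np.asarray(ts, dtype=float)
    n = ts.shape[-1]
    if n < 8:
        raise ValueError("series too short for a meaningful spectrum (need >= 8 points)")
    nyquist = 1.0 / (2.0 * tr_s)
    if not (0 < band_hz[0] < band_hz[1] <= nyquist):
        raise ValueError(f"band {band_hz} outside (0, Nyquist={nyquist}]")
    keep = _band_bins(n, tr_s, band_hz)
    power = _one_sided_power(ts, n)
    return float(np.sqrt(power[..., keep]).mean(axis=-1))


def compute_alff_map(
    vol: Volume4D, mask: np.ndarray, band_hz: tuple[float, float] = (0.01, 0.08)
) -> ALFFMap:
    """Apply :func:`compute_alff_voxel` to every in-mask voxel of a volume."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.grid_dims:
        raise ValueError("mask shape does not match volume grid")
    if not mask.any():
        raise ValueError("empty mask")
    n = vol.n_volumes
    keep = _band_bins(n, vol.tr_s, band_hz)
    series = vol.data[mask].astype(float)
    power = _one_sided_power(series, n)
    alff = np.sqrt(power[:, keep]).mean(axis=1)
    values = np.zeros(vol.grid_dims)
    values[mask] = alff
    return ALFFMap(values, tuple(band_hz), mask, standardized=False, voxel_size_mm=vol.voxel_size_mm)


def standardize_global_mean(amap: ALFFMap, mask: np.ndarray | None = None) -> ALFFMap:
    """Divide each in-mask value by the in-mask mean (global-mean ALFF).

    The output's in-mask mean is 1.  Standardization is scale invariant:
    maps ``m`` and ``c*m`` standardize identically.
    """
    mask = amap.mask if mask is None else np.asarray(mask, dtype=bool)
    gmean = amap.values[mask].mean()
    if not np.isfinite(gmean) or gmean <= 0:
        raise ValueError(f"global mean ALFF must be positive, got {gmean}")
    values = np.zeros_like(amap.values)
    values[mask] = amap.values[mask] / gmean
    return ALFFMap(values, amap.band_hz, mask, standardized=True, voxel_size_mm=amap.voxel_size_mm)
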