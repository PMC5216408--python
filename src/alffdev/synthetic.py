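"""Synthetic resting-state cohort generator.

Emulates the statistical structure a developmental ALFF study assumes,
without any real imaging data: a 2 (diagnosis: ASD/TC) x 3 (age cohort:
child / adolescent / adult) cross-sectional cohort with matched covariates,
per-subject 4D volumes carrying band-limited (0.01-0.08 Hz) oscillations
whose amplitude is modulated by planted diagnosis, age and diagnosis-by-age
effects in specified regions, random-walk motion traces, and ADOS-like
symptom scores linearly coupled to the realized regional amplitudes.

The default cell sizes (18/20, 28/26, 18/18; 128 subjects, 64 ASD / 64 TC),
acquisition timing (TR = 2 s, 180 volumes) and band match the study design
this package targets.  The grid is deliberately small (24 x 28 x 24 at
3 mm) so a full cohort runs at desk scale; voxelwise model cost is linear
in voxels, so nothing about the inference changes with grid size.

Signal model per subject (in-brain voxels)::

    y(v, t) = baseline
              + g(v) * [ bg(v, t) + sum_r 1_r(v) * a0 * m_r * s_r(t) ]
              + tissue confounds + linear drift + white noise

where ``bg`` is spatially smooth, temporally band-limited background
activity, ``g`` is a smooth subject-specific amplitude-modulation field
(biological variability that survives spatial smoothing), ``s_r`` is a
unit-RMS sum of in-band sinusoids coherent across region ``r``, and the
multiplier ``m_r = amplitude_model(diagnosis, age) * (1 + jitter)`` carries
the planted effects.  Sinusoids (rather than filtered noise) give the
planted amplitude a closed-form relation to ALFF for oracle checks.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.fft
from scipy import ndimage

from .datatypes import MotionTrace, Volume4D

__all__ = [
    "COHORTS",
    "CohortSpec",
    "RegionEffectSpec",
    "SymptomCoupling",
    "SimulationConfig",
    "TissueMasks",
    "make_masks",
    "cohort_from_age",
    "generate_phenotypes",
    "realized_region_amplitudes",
    "generate_motion_trace",
    "generate_subject_volume",
    "generate_symptoms",
    "generate_dataset",
    "SyntheticDataset",
    "Recruitment",
    "simulate_recruitment",
    "apply_exclusions",
    "write_dataset",
]

COHORTS = ("child", "adolescent", "adult")
DIAGNOSES = ("ASD", "TC")

# stream tags keeping per-subject random draws independent and replayable
_S_PHENO, _S_VOLUME, _S_JITTER, _S_MOTION, _S_SYMPTOM, _S_RECRUIT = range(6)


def cohort_from_age(age: float) -> str:
    """Age-cohort cut points: child < 11, adolescent 11-18, adult >= 18."""
    if age < 11:
        return "child"
    if age < 18:
        return "adolescent"
    return "adult"


@dataclass
class CohortSpec:
    """Design of the cohort: cell sizes, age windows and covariate models.

    The default totals 128 subjects (64 ASD / 64 TC) in a 2 x 3 design.
    ``age_mean_sd`` are the nominal per-cohort age distributions; sampled
    ages are restricted to within 3 SD of the nominal cohort mean
    (resampled otherwise), mirroring a matching step that trims outliers.
    """

    cell_sizes: dict = field(default_factory=lambda: {
        ("ASD", "child"): 18, ("TC", "child"): 20,
        ("ASD", "adolescent"): 28, ("TC", "adolescent"): 26,
        ("ASD", "adult"): 18, ("TC", "adult"): 18,
    })
    age_ranges: dict = field(default_factory=lambda: {
        "child": (6.0, 11.0), "adolescent": (11.0, 18.0), "adult": (18.0, 40.0),
    })
    age_mean_sd: dict = field(default_factory=lambda: {
        "child": (9.4, 1.3), "adolescent": (14.0, 1.9), "adult": (25.4, 5.0),
    })
    male_proportion: float = 0.9
    fiq_mean: float = 108.0
    fiq_sd: float = 14.0
    seed: int = 0

    def validate(self) -> None:
        for cell, n in self.cell_sizes.items():
            if not (isinstance(n, (int, np.integer)) and n > 0):
                raise ValueError(f"cell {cell} must have a positive integer count, got {n}")
        lo_prev = -np.inf
        for cohort in COHORTS:
            lo, hi = self.age_ranges[cohort]
            if not lo < hi:
                raise ValueError(f"age range for {cohort} is empty")
            if lo < lo_prev:
                raise ValueError("age intervals must be ordered and disjoint")
            lo_prev = hi

    @property
    def total(self) -> int:
        return int(sum(self.cell_sizes.values()))


@dataclass
class RegionEffectSpec:
    """A planted region and its amplitude model over (diagnosis, age).

    ``amplitude`` maps each diagnosis to quadratic coefficients
    (b0, b1 per year, b2 per year^2): multiplier = b0 + b1*age + b2*age^2.
    ``noise_sd`` is the relative amplitude jitter across subjects.
    """

    region_id: str
    center_vox: tuple[int, int, int]
    radius_vox: float = 3.5
    amplitude: dict = field(default_factory=lambda: {"ASD": (1.0, 0.0, 0.0), "TC": (1.0, 0.0, 0.0)})
    noise_sd: float = 0.1

    def multiplier(self, diagnosis: str, age: float) -> float:
        b0, b1, b2 = self.amplitude[diagnosis]
        return b0 + b1 * age + b2 * age**2

    def validate(self, age_span: tuple[float, float] = (4.0, 70.0)) -> None:
        ages = np.linspace(*age_span, 200)
        for diag in self.amplitude:
            m = np.array([self.multiplier(diag, a) for a in ages])
            if (m < 0).any():
                raise ValueError(
                    f"region {self.region_id}: amplitude multiplier negative for {diag}"
                )

    def voxel_indices(self, grid_dims, brain=None, exclude=None) -> np.ndarray:
        """(k, 3) voxel coordinates of the sphere, clipped to the brain mask."""
        grids = np.indices(grid_dims)
        d2 = sum((grids[i] - self.center_vox[i]) ** 2 for i in range(3))
        sel = d2 <= self.radius_vox**2
        if brain is not None:
            sel &= brain
        if exclude is not None:
            sel &= ~exclude
        coords = np.argwhere(sel)
        if coords.size == 0:
            raise ValueError(f"region {self.region_id} lies outside the grid/brain")
        if (np.asarray(self.center_vox) >= np.asarray(grid_dims)).any() or min(self.center_vox) < 0:
            raise ValueError(f"region {self.region_id} center outside the grid")
        return coords


def _default_regions() -> list[RegionEffectSpec]:
    # TC trajectory in the mPFC: quadratic in age with vertex near 22 y
    # (high in childhood, minimum in the twenties); ASD flat -> interaction.
    # Precuneus/MOG: constant 15% ASD reduction (one subject-jitter SD)
    # -> diagnosis main effect with interior F ~ 20 at n = 128.
    tc_quad = (1.0 + 0.0035 * 22.0**2, -2 * 0.0035 * 22.0, 0.0035)
    return [
        RegionEffectSpec("mPFC", (12, 23, 16), noise_sd=0.15,
                         amplitude={"TC": tc_quad, "ASD": (1.3, 0.0, 0.0)}),
        RegionEffectSpec("precuneus", (16, 7, 16), noise_sd=0.15,
                         amplitude={"TC": (1.0, 0.0, 0.0), "ASD": (0.85, 0.0, 0.0)}),
        RegionEffectSpec("MOG", (8, 7, 9), noise_sd=0.15,
                         amplitude={"TC": (1.0, 0.0, 0.0), "ASD": (0.85, 0.0, 0.0)}),
    ]


@dataclass
class SymptomCoupling:
    """Linear map from realized region amplitude multipliers to ADOS_SOCIAL.

    social = round(clip(intercept + sum_r weight_r * m_r + noise)).
    Communication and stereotyped subscores are drawn independently (no
    planted coupling) with magnitudes typical of ADOS subscales.
    """

    weights: dict = field(default_factory=lambda: {"mPFC": 7.5, "precuneus": 7.5, "MOG": 7.5})
    intercept: float = -14.5
    noise_sd: float = 0.8
    score_range: tuple[int, int] = (0, 14)
    comm_mean_sd: tuple[float, float] = (3.5, 1.6)
    stereo_mean_sd: tuple[float, float] = (2.2, 1.4)
    other_range: tuple[int, int] = (0, 8)


@dataclass
class SimulationConfig:
    """All knobs of the volume simulator.  Defaults are the study conditions."""

    grid_dims: tuple[int, int, int] = (24, 28, 24)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tr_s: float = 2.0
    n_volumes: int = 180
    band_hz: tuple[float, float] = (0.01, 0.08)
    background_noise: float = 1.0
    baseline: float = 100.0
    bg_oscillation_rms: float = 0.5
    bg_oscillation_fwhm_mm: float = 6.0
    modulation_sd: float = 0.03
    modulation_fwhm_mm: float = 9.0
    n_sinusoids: int = 5
    sinusoid_band_hz: tuple[float, float] = (0.015, 0.075)
    region_base_amplitude: float = 0.8
    regions: list = field(default_factory=_default_regions)
    symptom_coupling: SymptomCoupling = field(default_factory=SymptomCoupling)
    motion_trans_step_mm: float = 0.03
    motion_rot_step_rad: float = 3e-4
    drift_sd: float = 0.5
    tissue_confound_rms: float = 1.5
    tissue_leak: float = 0.3
    brain_axes_vox: tuple[float, float, float] = (11.0, 13.0, 11.0)
    wm_axes_vox: tuple[float, float, float] = (4.5, 5.5, 4.5)
    csf_axes_vox: tuple[float, float, float] = (2.0, 2.5, 2.0)

    def validate(self) -> None:
        nyq = 1.0 / (2.0 * self.tr_s)
        if not (0 < self.band_hz[0] < self.band_hz[1] < nyq):
            raise ValueError(f"band {self.band_hz} must lie strictly inside (0, {nyq})")
        if self.n_volumes <= 10:
            raise ValueError("n_volumes must exceed the discard count")
        for r in self.regions:
            r.validate()


def scale_to_grid(config: SimulationConfig, grid_dims: tuple[int, int, int]) -> SimulationConfig:
    """Rescale a configuration's geometry (masks, regions) to a new grid.

    Region centers, radii and tissue ellipsoid axes are scaled by the
    per-axis ratio of the new to the old grid, so a configuration designed
    on the default grid stays geometrically valid on smaller or larger ones.
    """
    f = [g / o for g, o in zip(grid_dims, config.grid_dims)]
    fr = float(np.cbrt(f[0] * f[1] * f[2]))
    regions = [
        replace(
            r,
            center_vox=tuple(int(round(c * fi)) for c, fi in zip(r.center_vox, f)),
            radius_vox=max(r.radius_vox * fr, 1.0),
        )
        for r in config.regions
    ]
    scale3 = lambda axes: tuple(a * fi for a, fi in zip(axes, f))  # noqa: E731
    return replace(
        config,
        grid_dims=tuple(int(g) for g in grid_dims),
        regions=regions,
        brain_axes_vox=scale3(config.brain_axes_vox),
        wm_axes_vox=scale3(config.wm_axes_vox),
        csf_axes_vox=scale3(config.csf_axes_vox),
    )


@dataclass
class TissueMasks:
    brain: np.ndarray
    wm: np.ndarray
    csf: np.ndarray

    @property
    def gray(self) -> np.ndarray:
        return self.brain & ~self.wm & ~self.csf


def _ellipsoid(grid_dims, axes) -> np.ndarray:
    center = [(d - 1) / 2.0 for d in grid_dims]
    grids = np.indices(grid_dims)
    d2 = sum(((grids[i] - center[i]) / axes[i]) ** 2 for i in range(3))
    return d2 <= 1.0


def make_masks(config: SimulationConfig) -> TissueMasks:
    """Nested-ellipsoid brain / white-matter / CSF masks on the grid."""
    brain = _ellipsoid(config.grid_dims, config.brain_axes_vox)
    csf = _ellipsoid(config.grid_dims, config.csf_axes_vox)
    wm = _ellipsoid(config.grid_dims, config.wm_axes_vox) & ~csf
    return TissueMasks(brain=brain, wm=wm & brain, csf=csf & brain)


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *stream]))


# ---------------------------------------------------------------------------
# phenotypes


def _sample_age(rng, lo, hi, mean, sd) -> float:
    for _ in range(10_000):
        age = rng.normal(mean, sd)
        if lo <= age < hi and abs(age - mean) <= 3 * sd:
            return float(age)
    raise RuntimeError("age sampling failed; check cohort spec")


def generate_phenotypes(spec: CohortSpec) -> pd.DataFrame:
    """One record per subject; ADOS columns are filled by generate_symptoms."""
    spec.validate()
    rng = _rng(spec.seed, _S_PHENO)
    rows = []
    idx = 0
    for cohort in COHORTS:
        lo, hi = spec.age_ranges[cohort]
        mean, sd = spec.age_mean_sd[cohort]
        for diag in DIAGNOSES:
            n = spec.cell_sizes.get((diag, cohort))
            if n is None:
                raise ValueError(f"missing cell ({diag}, {cohort})")
            for _ in range(int(n)):
                idx += 1
                rows.append({
                    "subject_id": f"sub-{idx:04d}",
                    "diagnosis": diag,
                    "age_years": round(_sample_age(rng, lo, hi, mean, sd), 2),
                    "cohort": cohort,
                    "gender": int(rng.random() < spec.male_proportion),
                    "fiq": round(float(rng.normal(spec.fiq_mean, spec.fiq_sd)), 1),
                    "ados_comm": np.nan,
                    "ados_social": np.nan,
                    "ados_stereo": np.nan,
                })
    return pd.DataFrame(rows)


def realized_region_amplitudes(
    phenotypes: pd.DataFrame, config: SimulationConfig, seed: int
) -> pd.DataFrame:
    """Per-subject realized amplitude multipliers m_r = model(diag, age)*(1+jitter).

    Both the volume generator and the symptom generator consume this table,
    so the planted brain-behaviour coupling is exact by construction.
    """
    out = {}
    for i, rec in enumerate(phenotypes.itertuples()):
        rng = _rng(seed, _S_JITTER, i)
        out[rec.subject_id] = [
            r.multiplier(rec.diagnosis, rec.age_years) * (1.0 + rng.normal(0.0, r.noise_sd))
            for r in config.regions
        ]
    return pd.DataFrame.from_dict(
        out, orient="index", columns=[r.region_id for r in config.regions]
    )


# ---------------------------------------------------------------------------
# motion


def generate_motion_trace(
    config: SimulationConfig,
    seed: int,
    subject_index: int = 0,
    step_scale: float = 1.0,
    spike_mm: float = 0.0,
) -> MotionTrace:
    """Random-walk rigid-body trace; first row is zeros.

    ``spike_mm`` injects a brief translation excursion (used to construct
    subjects that breach the 3 mm exclusion limit deterministically).
    """
    if config.n_volumes < 2:
        raise ValueError("need at least two volumes")
    rng = _rng(seed, _S_MOTION, subject_index)
    steps = rng.normal(
        0.0,
        [config.motion_trans_step_mm] * 3 + [config.motion_rot_step_rad] * 3,
        size=(config.n_volumes - 1, 6),
    ) * step_scale
    params = np.vstack([np.zeros(6), np.cumsum(steps, axis=0)])
    if spike_mm:
        t0 = config.n_volumes // 2
        params[t0:t0 + 5, 0] += spike_mm
    return MotionTrace(params, config.tr_s)


# ---------------------------------------------------------------------------
# volumes


def _smooth_complex(arr: np.ndarray, sigma_vox) -> np.ndarray:
    out = np.empty_like(arr)
    out.real = ndimage.gaussian_filter(arr.real, sigma=list(sigma_vox) + [0.0], mode="constant")
    out.imag = ndimage.gaussian_filter(arr.imag, sigma=list(sigma_vox) + [0.0], mode="constant")
    return out


_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _background_oscillation(rng, config: SimulationConfig, brain: np.ndarray) -> np.ndarray:
    """Spatially smooth, temporally band-limited background activity (float32)."""
    if config.bg_oscillation_rms <= 0:
        return np.zeros(config.grid_dims + (config.n_volumes,), dtype=np.float32)
    T = config.n_volumes
    freqs = np.fft.rfftfreq(T, config.tr_s)
    band = (freqs >= config.band_hz[0]) & (freqs <= config.band_hz[1])
    nf = freqs.size
    sigma = [config.bg_oscillation_fwhm_mm * _FWHM_TO_SIGMA / v for v in config.voxel_size_mm]
    coeff = np.zeros(config.grid_dims + (nf,), dtype=np.complex64)
    nb = int(band.sum())
    raw = (
        rng.standard_normal(config.grid_dims + (nb,), dtype=np.float32)
        + 1j * rng.standard_normal(config.grid_dims + (nb,), dtype=np.float32)
    )
    coeff[..., band] = _smooth_complex(raw, sigma)
    bg = scipy.fft.irfft(coeff, n=T, axis=-1).astype(np.float32)
    rms = float(np.sqrt(np.mean(bg[brain] ** 2)))
    if rms > 0:
        bg *= config.bg_oscillation_rms / rms
    return bg


def _modulation_field(rng, config: SimulationConfig, brain: np.ndarray) -> np.ndarray:
    if config.modulation_sd <= 0:
        return np.ones(config.grid_dims, dtype=np.float32)
    sigma = [config.modulation_fwhm_mm * _FWHM_TO_SIGMA / v for v in config.voxel_size_mm]
    f = ndimage.gaussian_filter(
        rng.standard_normal(config.grid_dims, dtype=np.float32), sigma=sigma, mode="constant"
    )
    sd = float(f[brain].std())
    if sd > 0:
        f = f / sd * config.modulation_sd
    return (1.0 + f).astype(np.float32)


def _region_course(rng, config: SimulationConfig) -> np.ndarray:
    """Unit-RMS sum of K random in-band sinusoids, coherent across the region."""
    t = np.arange(config.n_volumes) * config.tr_s
    f = rng.uniform(*config.sinusoid_band_hz, size=config.n_sinusoids)
    phi = rng.uniform(0, 2 * np.pi, size=config.n_sinusoids)
    s = np.sin(2 * np.pi * f[:, None] * t[None, :] + phi[:, None]).sum(axis=0)
    rms = np.sqrt(np.mean(s**2))
    return (s / rms if rms > 0 else s).astype(np.float32)


def _tissue_series(rng, config: SimulationConfig) -> np.ndarray:
    raw = rng.standard_normal(config.n_volumes, dtype=np.float32)
    sig = ndimage.gaussian_filter1d(raw, sigma=3.0, mode="constant")
    rms = np.sqrt(np.mean(sig**2))
    return (sig / rms * config.tissue_confound_rms if rms > 0 else sig).astype(np.float32)


def generate_subject_volume(
    record,
    config: SimulationConfig,
    seed: int,
    subject_index: int = 0,
    masks: TissueMasks | None = None,
    amplitudes: dict | None = None,
) -> Volume4D:
    """Simulate one subject's 4D volume.

    ``record`` is a phenotype row (needs ``diagnosis`` and ``age_years``).
    ``amplitudes`` maps region_id to the realized multiplier; if omitted it
    is recomputed from the subject's jitter stream (identical either way).
    """
    masks = masks or make_masks(config)
    brain = masks.brain
    rng = _rng(seed, _S_VOLUME, subject_index)
    if amplitudes is None:
        jrng = _rng(seed, _S_JITTER, subject_index)
        amplitudes = {
            r.region_id: r.multiplier(record.diagnosis, record.age_years)
            * (1.0 + jrng.normal(0.0, r.noise_sd))
            for r in config.regions
        }
    T = config.n_volumes
    data = np.zeros(config.grid_dims + (T,), dtype=np.float32)
    nb = int(brain.sum())
    if config.background_noise > 0:
        data[brain] = rng.standard_normal((nb, T), dtype=np.float32) * config.background_noise
    signal = _background_oscillation(rng, config, brain)
    for r in config.regions:
        coords = r.voxel_indices(config.grid_dims, brain=brain, exclude=masks.wm | masks.csf)
        course = _region_course(rng, config)
        amp = config.region_base_amplitude * amplitudes[r.region_id]
        signal[coords[:, 0], coords[:, 1], coords[:, 2], :] += np.float32(amp) * course
    g = _modulation_field(rng, config, brain)
    data[brain] += g[brain, None] * signal[brain]
    wm_sig = _tissue_series(rng, config)
    csf_sig = _tissue_series(rng, config)
    data[masks.wm] += wm_sig
    data[masks.csf] += csf_sig
    data[masks.gray] += np.float32(config.tissue_leak) * (wm_sig + csf_sig)
    drift = np.float32(rng.normal(0.0, config.drift_sd)) * np.linspace(
        -1, 1, T, dtype=np.float32
    )
    data[brain] += drift + np.float32(config.baseline)
    return Volume4D(data, config.voxel_size_mm, config.tr_s)


# ---------------------------------------------------------------------------
# symptoms


def generate_symptoms(
    phenotypes: pd.DataFrame,
    region_amplitudes: pd.DataFrame,
    coupling: SymptomCoupling,
    seed: int = 0,
) -> pd.DataFrame:
    """Fill ADOS subscores for ASD subjects.

    The social subscore is an affine function of the realized region
    amplitudes plus Gaussian noise, rounded and clipped into the documented
    integer range; communication and stereotyped subscores are independent
    draws (no planted coupling).
    """
    phen = phenotypes.copy()
    rng = _rng(seed, _S_SYMPTOM)
    lo, hi = coupling.score_range
    olo, ohi = coupling.other_range
    active = {r: w for r, w in coupling.weights.items() if r in region_amplitudes.columns}
    base = (hi + lo) / 2.0 if not active else coupling.intercept
    for i in phen.index:
        if phen.at[i, "diagnosis"] != "ASD":
            continue
        sid = phen.at[i, "subject_id"]
        social = base + sum(
            w * region_amplitudes.at[sid, rid] for rid, w in active.items()
        ) + rng.normal(0.0, coupling.noise_sd)
        phen.at[i, "ados_social"] = int(np.clip(np.round(social), lo, hi))
        phen.at[i, "ados_comm"] = int(np.clip(np.round(rng.normal(*coupling.comm_mean_sd)), olo, ohi))
        phen.at[i, "ados_stereo"] = int(np.clip(np.round(rng.normal(*coupling.stereo_mean_sd)), olo, ohi))
    return phen


# ---------------------------------------------------------------------------
# whole datasets


@dataclass
class SyntheticDataset:
    """A fully materialized cohort (use only with small configurations)."""

    phenotypes: pd.DataFrame
    masks: TissueMasks
    volumes: list
    motion: list
    amplitudes: pd.DataFrame
    config: SimulationConfig
    spec: CohortSpec
    seed: int


def generate_dataset(
    spec: CohortSpec | None = None,
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate phenotypes, symptoms, volumes and motion for a whole cohort."""
    spec = spec or CohortSpec()
    config = config or SimulationConfig()
    config.validate()
    phen = generate_phenotypes(replace(spec, seed=seed))
    masks = make_masks(config)
    amps = realized_region_amplitudes(phen, config, seed)
    phen = generate_symptoms(phen, amps, config.symptom_coupling, seed)
    volumes, motion = [], []
    for i, rec in enumerate(phen.itertuples()):
        volumes.append(
            generate_subject_volume(
                rec, config, seed, i, masks, amplitudes=amps.loc[rec.subject_id].to_dict()
            )
        )
        motion.append(generate_motion_trace(config, seed, i))
    return SyntheticDataset(phen, masks, volumes, motion, amps, config, spec, seed)


def iter_subjects(
    phen: pd.DataFrame, config: SimulationConfig, seed: int, masks: TissueMasks, amps: pd.DataFrame
):
    """Stream (record, volume, motion) per subject without holding the cohort."""
    for i, rec in enumerate(phen.itertuples()):
        vol = generate_subject_volume(
            rec, config, seed, i, masks, amplitudes=amps.loc[rec.subject_id].to_dict()
        )
        yield rec, vol, generate_motion_trace(config, seed, i)


# ---------------------------------------------------------------------------
# recruitment with planted exclusions


@dataclass
class Recruitment:
    """A raw recruited sample prior to motion / matching exclusions."""

    phenotypes: pd.DataFrame  # includes a high_motion flag column
    motion: dict  # subject_id -> MotionTrace
    spec: CohortSpec
    config: SimulationConfig
    seed: int


def simulate_recruitment(
    spec: CohortSpec | None = None,
    config: SimulationConfig | None = None,
    seed: int = 0,
    n_unmatched: int = 49,
    n_high_motion: int = 7,
) -> Recruitment:
    """Recruit a raw sample: the matched core plus planted exclusions.

    The raw sample is the matched core cohort plus ``n_unmatched`` subjects
    whose ages fall outside the 3-SD matching window (young children /
    older adults) and ``n_high_motion`` subjects whose motion traces breach
    the 3 mm / 3 degree limits.  Defaults reproduce a 184-subject intake
    reduced to 128 after both filters.
    """
    spec = spec or CohortSpec()
    config = config or SimulationConfig()
    core = generate_phenotypes(replace(spec, seed=seed))
    core["high_motion"] = False
    rng = _rng(seed, _S_RECRUIT)
    rows = []
    nxt = spec.total
    # age-outlier recruits alternate child-low / adult-high and ASD / TC
    for j in range(n_unmatched):
        nxt += 1
        if j % 2 == 0:
            cohort = "child"
            mean, sd = spec.age_mean_sd["child"]
            age = rng.uniform(max(3.5, mean - 4.5 * sd), mean - 3.2 * sd)
        else:
            cohort = "adult"
            mean, sd = spec.age_mean_sd["adult"]
            age = rng.uniform(mean + 3.2 * sd, mean + 6.0 * sd)
        rows.append(_extra_row(nxt, DIAGNOSES[j % 4 // 2], age, cohort, rng, spec, False))
    for j in range(n_high_motion):
        nxt += 1
        cohort = COHORTS[j % 3]
        lo, hi = spec.age_ranges[cohort]
        mean, sd = spec.age_mean_sd[cohort]
        age = _sample_age(rng, lo, hi, mean, sd)
        rows.append(_extra_row(nxt, DIAGNOSES[j % 2], age, cohort, rng, spec, True))
    phen = pd.concat([core, pd.DataFrame(rows)], ignore_index=True)
    motion = {}
    for i, rec in enumerate(phen.itertuples()):
        spike = 4.0 + rng.uniform(0, 2) if rec.high_motion else 0.0
        motion[rec.subject_id] = generate_motion_trace(config, seed, i, spike_mm=spike)
    return Recruitment(phen, motion, spec, config, seed)


def _extra_row(idx, diag, age, cohort, rng, spec: CohortSpec, high_motion: bool) -> dict:
    return {
        "subject_id": f"sub-{idx:04d}",
        "diagnosis": diag,
        "age_years": round(float(age), 2),
        "cohort": cohort,
        "gender": int(rng.random() < spec.male_proportion),
        "fiq": round(float(rng.normal(spec.fiq_mean, spec.fiq_sd)), 1),
        "ados_comm": np.nan,
        "ados_social": np.nan,
        "ados_stereo": np.nan,
        "high_motion": high_motion,
    }


def apply_exclusions(
    rec: Recruitment, trans_mm: float = 3.0, rot_deg: float = 3.0
) -> tuple[pd.DataFrame, dict]:
    """Apply the cohort filters: motion QC first, then 3-SD age matching.

    Returns the retained phenotype table and a summary of counts.
    """
    from .preprocess import motion_exclusion

    phen = rec.phenotypes
    moved = phen["subject_id"].map(
        lambda s: motion_exclusion(rec.motion[s], trans_mm, rot_deg)
    )
    after_motion = phen[~moved]
    mismatched = after_motion.apply(
        lambda row: abs(row["age_years"] - rec.spec.age_mean_sd[row["cohort"]][0])
        > 3 * rec.spec.age_mean_sd[row["cohort"]][1],
        axis=1,
    )
    final = after_motion[~mismatched].drop(columns=["high_motion"]).reset_index(drop=True)
    summary = {
        "recruited": int(len(phen)),
        "motion_excluded": int(moved.sum()),
        "matching_excluded": int(mismatched.sum()),
        "final": int(len(final)),
        "final_asd": int((final["diagnosis"] == "ASD").sum()),
        "final_tc": int((final["diagnosis"] == "TC").sum()),
    }
    return final, summary


# ---------------------------------------------------------------------------
# on-disk datasets


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_dataset(directory, spec=None, config=None, seed: int = 0) -> dict:
    """Generate a cohort and write it to ``directory``.

    Layout: one 4D NIfTI per subject, one 6-column motion text file per
    subject, brain/WM/CSF mask NIfTIs, a phenotype TSV and a JSON manifest
    recording the configuration, seed, file list and data checksums.
    Subjects are generated and written one at a time, so large cohorts never
    reside in memory.
    """
    from pathlib import Path

    from .io import write_motion, write_phenotypes, write_volume

    spec = spec or CohortSpec()
    config = config or SimulationConfig()
    config.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    phen = generate_phenotypes(replace(spec, seed=seed))
    masks = make_masks(config)
    amps = realized_region_amplitudes(phen, config, seed)
    phen = generate_symptoms(phen, amps, config.symptom_coupling, seed)
    files, checksums = [], {}
    for name, m in (("brain", masks.brain), ("wm", masks.wm), ("csf", masks.csf)):
        path = directory / f"mask_{name}.nii"
        write_volume(path, Volume4D(m.astype(np.uint8), config.voxel_size_mm, config.tr_s))
        files.append(path.name)
    for rec, vol, mot in iter_subjects(phen, config, seed, masks, amps):
        vpath = directory / f"{rec.subject_id}_bold.nii"
        mpath = directory / f"{rec.subject_id}_motion.txt"
        write_volume(vpath, vol)
        write_motion(mpath, mot)
        files += [vpath.name, mpath.name]
        checksums[rec.subject_id] = hashlib.md5(
            np.ascontiguousarray(vol.data).tobytes()
        ).hexdigest()
    ppath = directory / "phenotypes.tsv"
    write_phenotypes(ppath, phen)
    files.append(ppath.name)
    manifest = {
        "seed": int(seed),
        "cohort_spec": _jsonable(asdict(spec)),
        "simulation_config": _jsonable(asdict(config)),
        "files": files,
        "checksums": checksums,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
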