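"""Monte-Carlo calibration utilities for the random-field cluster machinery.

These helpers generate stationary smooth Gaussian null fields (white noise
convolved with a Gaussian kernel and renormalized to unit variance) and
measure the family-wise cluster false-positive rate of the GRF extent
threshold, or the null distribution of the voxelwise F statistic through
the full simulate -> preprocess -> ALFF -> ANCOVA chain.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import ndimage, stats

from . import synthetic
from .glm import (
    SmoothnessEstimate,
    VoxelwiseANCOVA,
    build_design,
    estimate_smoothness,
    extract_clusters,
    grf_extent_threshold,
)

__all__ = [
    "smooth_null_field",
    "grf_cluster_fwer",
    "null_simulation_config",
    "null_voxelwise_f",
    "effect_recovery_run",
]

_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _kernel_norm(sigma_vox, pad: int) -> float:
    """Standard deviation of unit white noise after Gaussian filtering."""
    size = [2 * pad + 1] * 3
    delta = np.zeros(size)
    delta[pad, pad, pad] = 1.0
    k = ndimage.gaussian_filter(delta, sigma=sigma_vox, mode="constant")
    return float(np.sqrt((k**2).sum()))


def smooth_null_field(
    grid_dims, fwhm_vox: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance stationary Gaussian field with known smoothness.

    White noise is generated on a padded grid, filtered, cropped and divided
    by the exact kernel norm, so the interior of the field is stationary
    with per-voxel variance 1.
    """
    sigma = fwhm_vox * _SIGMA
    pad = max(int(np.ceil(4 * sigma)), 2)
    shape = tuple(d + 2 * pad for d in grid_dims)
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="constant")
    sl = tuple(slice(pad, pad + d) for d in grid_dims)
    return field[sl] / _kernel_norm([sigma] * 3, pad)


def grf_cluster_fwer(
    n_sim: int = 500,
    grid_dims=(24, 28, 24),
    fwhm_vox: float = 4.0,
    z_thresh: float | None = None,
    cluster_alpha: float = 0.05,
    seed: int = 0,
    mask: np.ndarray | None = None,
    n_estimate: int = 50,
    connectivity: int = 6,
) -> dict:
    """Family-wise cluster false-positive rate of the GRF extent threshold.

    Smoothness is estimated from ``n_estimate`` of the simulated fields
    (treated as residual maps), the extent threshold computed once, and the
    proportion of null fields containing any surviving cluster returned.

    The default smoothness (4 voxels FWHM, i.e. ~12 mm at 3 mm voxels, the
    composite smoothness typical after 8 mm applied smoothing) lies inside
    the validity regime of the random-field cluster-size approximation;
    below ~3 voxels FWHM the lattice approximation is known to degrade and
    the threshold becomes conservative (see the methods note).
    """
    if z_thresh is None:
        z_thresh = float(stats.norm.isf(0.01))
    if mask is None:
        mask = np.ones(grid_dims, dtype=bool)
    rng = np.random.default_rng(seed)
    est_fields = np.stack(
        [smooth_null_field(grid_dims, fwhm_vox, rng) for _ in range(n_estimate)]
    )
    sm = estimate_smoothness(est_fields, mask, (1.0, 1.0, 1.0))
    k, info = grf_extent_threshold(z_thresh, sm, mask, cluster_alpha)
    hits = 0
    for _ in range(n_sim):
        z = smooth_null_field(grid_dims, fwhm_vox, rng)
        cres = extract_clusters(z, z_thresh, k, connectivity, mask)
        hits += bool(len(cres))
    return {
        "fwer": hits / n_sim,
        "extent_threshold": k,
        "n_sim": n_sim,
        "z_thresh": z_thresh,
        "estimated_fwhm_vox": sm.fwhm_vox,
        "true_fwhm_vox": fwhm_vox,
        "grf_info": info,
    }


def null_simulation_config(**overrides) -> synthetic.SimulationConfig:
    """Simulation config with every planted and shared signal switched off.

    With no regions, no smooth background field, no modulation field and no
    tissue leak into gray matter, the per-voxel ALFF values are independent
    across voxels and exchangeable across subjects — the regime in which the
    voxelwise F statistic follows its nominal F distribution exactly.
    """
    cfg = synthetic.SimulationConfig(
        regions=[], bg_oscillation_rms=0.0, modulation_sd=0.0, tissue_leak=0.0
    )
    return replace(cfg, **overrides) if overrides else cfg


def null_voxelwise_f(
    seed: int = 0,
    spec: synthetic.CohortSpec | None = None,
    sim_config: synthetic.SimulationConfig | None = None,
    fwhm_mm: float = 0.0,
    effect: str = "diagnosis",
):
    """Voxelwise F values from a fully null cohort run through the pipeline.

    Returns ``(f_values, df1, df2)`` for the requested effect.  Smoothing
    defaults to 0 mm so in-mask voxels stay independent and the empirical
    distribution can be compared to F(df1, df2) with an i.i.d. test.
    """
    from .pipeline import compute_cohort_alff
    from .preprocess import PreprocessParams

    spec = spec or synthetic.CohortSpec()
    sim_config = sim_config or null_simulation_config()
    phen = synthetic.generate_phenotypes(replace(spec, seed=seed))
    amps = synthetic.realized_region_amplitudes(phen, sim_config, seed)
    phen = synthetic.generate_symptoms(phen, amps, sim_config.symptom_coupling, seed)
    params = PreprocessParams(fwhm_mm=fwhm_mm, band_hz=sim_config.band_hz)
    alff_stack, phen, masks = compute_cohort_alff(phen, sim_config, seed, params)
    design = build_design(phen)
    results = VoxelwiseANCOVA(alff_stack, design, mask=masks.brain).fit()
    sm = results.stat_maps[effect]
    return sm.F[sm.mask], sm.df1, sm.df2


def effect_recovery_run(seed: int, n_perm: int = 200) -> dict:
    """One full pipeline run under the default planted effects.

    Simulates the default 128-subject cohort, runs preprocessing, ALFF,
    group inference, trajectory modelling and symptom prediction, and
    scores how well the planted structure is recovered: Dice overlap of the
    detected interaction cluster with the planted mPFC region, coverage of
    the planted precuneus/MOG regions by the diagnosis clusters, the
    per-group quadratic-trajectory p values, and the permutation p values
    of the three ADOS subscales.
    """
    from .io import RunConfig
    from .pipeline import (
        analyze_cohort,
        compute_cohort_alff,
        dice_coefficient,
        planted_region_masks,
    )

    sim = synthetic.SimulationConfig()
    phen = synthetic.generate_phenotypes(replace(synthetic.CohortSpec(), seed=seed))
    amps = synthetic.realized_region_amplitudes(phen, sim, seed)
    phen = synthetic.generate_symptoms(phen, amps, sim.symptom_coupling, seed)
    alff_stack, phen, masks = compute_cohort_alff(phen, sim, seed)
    cfg = RunConfig(seed=seed, n_perm=n_perm)
    res = analyze_cohort(alff_stack, phen, masks, cfg)
    planted = planted_region_masks(sim, masks)
    inter = res["clusters"]["interaction"].union_mask(masks.brain.shape)
    diagm = res["clusters"]["diagnosis"].union_mask(masks.brain.shape)
    out = {
        "seed": seed,
        "interaction_dice_mpfc": dice_coefficient(inter, planted["mPFC"]),
        "diagnosis_coverage": {
            r: float((diagm & planted[r]).sum() / planted[r].sum())
            for r in ("precuneus", "MOG")
        },
        "extent_threshold": res["clusters"]["interaction"].extent_threshold,
        "trajectory_p": (
            {g: f.p_value for g, f in res["trajectory"]["fits"].items()}
            if res["trajectory"]
            else {}
        ),
        "prediction": {
            t: {"r": p.r, "p_perm": p.p_perm} for t, p in res["predictions"].items()
        },
    }
    return out
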