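"""End-to-end orchestration: simulate -> preprocess -> ALFF -> group stats ->
trajectory -> prediction.

Subjects are generated, preprocessed and reduced to ALFF maps one at a time,
so a full cohort never has to fit in memory; only the per-subject
standardized ALFF vectors (subjects x in-mask voxels) are retained for the
group stages.  Every randomized stage consumes an explicit seed recorded in
the summary, and all outputs are deterministic functions of
(configuration, seeds).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import synthetic
from .alff import compute_alff_map, standardize_global_mean
from .glm import VoxelwiseANCOVA, build_design, posthoc_ttests
from .io import RunConfig, write_phenotypes
from .prediction import FeatureMatrix, SymptomSVR, bonferroni_gate, build_feature_matrix
from .preprocess import PreprocessParams, preprocess_subject
from .trajectory import compare_group_trajectories, fit_quadratic

__all__ = [
    "compute_cohort_alff",
    "analyze_cohort",
    "run_all",
    "dice_coefficient",
    "planted_region_masks",
]

logger = logging.getLogger(__name__)

ADOS_TARGETS = ("ados_comm", "ados_social", "ados_stereo")


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|) of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    return float(2.0 * (a & b).sum() / denom) if denom else 0.0


def planted_region_masks(config: synthetic.SimulationConfig, masks=None) -> dict:
    """Boolean masks of the planted effect regions on the simulation grid."""
    masks = masks or synthetic.make_masks(config)
    out = {}
    for r in config.regions:
        m = np.zeros(config.grid_dims, dtype=bool)
        coords = r.voxel_indices(config.grid_dims, brain=masks.brain, exclude=masks.wm | masks.csf)
        m[tuple(coords.T)] = True
        out[r.region_id] = m
    return out


def compute_cohort_alff(
    phen: pd.DataFrame,
    sim_config: synthetic.SimulationConfig,
    seed: int,
    params: PreprocessParams | None = None,
):
    """Simulate and preprocess every subject, returning standardized ALFF.

    Returns ``(alff_stack, phen, masks)`` where ``alff_stack`` is
    (n_subjects, n_in-mask voxels) and ``phen`` gains a ``mean_fd`` column.
    """
    params = params or PreprocessParams(band_hz=sim_config.band_hz)
    masks = synthetic.make_masks(sim_config)
    amps = synthetic.realized_region_amplitudes(phen, sim_config, seed)
    stack, fds = [], []
    for rec, vol, motion in synthetic.iter_subjects(phen, sim_config, seed, masks, amps):
        clean, mean_fd = preprocess_subject(
            vol, motion, masks.brain, masks.wm, masks.csf, params
        )
        amap = compute_alff_map(clean, masks.brain, params.band_hz)
        stack.append(standardize_global_mean(amap).in_mask())
        fds.append(mean_fd)
    phen = phen.copy()
    phen["mean_fd"] = fds
    return np.stack(stack), phen, masks


def analyze_cohort(
    alff_stack: np.ndarray,
    phen: pd.DataFrame,
    masks,
    cfg: RunConfig,
) -> dict:
    """Group inference, trajectory modelling and symptom prediction."""
    design = build_design(phen)
    model = VoxelwiseANCOVA(
        alff_stack, design, mask=masks.brain, voxel_size_mm=(3.0, 3.0, 3.0)
    )
    results = model.fit()
    smooth = results.smoothness()
    z_thresh = float(stats.norm.isf(cfg.voxel_p))
    clusters = {
        effect: results.cluster_correct(
            effect,
            z_thresh=z_thresh,
            cluster_alpha=cfg.cluster_alpha,
            connectivity=cfg.connectivity,
            smoothness=smooth,
        )
        for effect in ("diagnosis", "age", "interaction")
    }

    # trajectory: ROI = union of interaction clusters, mean ALFF per subject
    trajectory = None
    if len(clusters["interaction"]):
        roi = clusters["interaction"].union_mask(masks.brain.shape)
        roi_vals = _roi_means(alff_stack, masks.brain, roi)
        fits = {}
        for group in ("TC", "ASD"):
            sel = (phen["diagnosis"] == group).to_numpy()
            fits[group] = fit_quadratic(
                phen.loc[sel, "age_years"].to_numpy(), roi_vals[sel], group
            )
        trajectory = {"fits": fits, "report": compare_group_trajectories(fits["TC"], fits["ASD"])}

    # post-hoc ASD vs TC comparisons in each diagnosis-effect cluster
    posthoc = {}
    for i, cl in enumerate(clusters["diagnosis"].clusters):
        roi = np.zeros(masks.brain.shape, dtype=bool)
        roi[tuple(cl.voxels.T)] = True
        posthoc[f"diagnosis_cluster_{i + 1}"] = posthoc_ttests(
            _roi_means(alff_stack, masks.brain, roi), phen,
            family_size=cfg.posthoc_family, family_alpha=0.05,
        )

    # prediction: pool voxels from diagnosis + interaction clusters
    cluster_sets = {}
    for effect in ("diagnosis", "interaction"):
        for i, cl in enumerate(clusters[effect].clusters):
            cluster_sets[f"{effect}_{i + 1}"] = cl.voxels
    predictions = {}
    if cluster_sets:
        for j, target in enumerate(ADOS_TARGETS):
            fm, y = build_feature_matrix(alff_stack, masks.brain, cluster_sets, phen, target)
            if len(y) < 3 or np.ptp(y) == 0:
                continue
            res = SymptomSVR(
                fm.X, y, C=cfg.svr_c, epsilon=cfg.svr_epsilon, target=target
            ).fit()
            predictions[target] = res.permutation_test(cfg.n_perm, seed=cfg.seed + 1000 + j)
    return {
        "design": design,
        "results": results,
        "smoothness": smooth,
        "z_threshold": z_thresh,
        "clusters": clusters,
        "trajectory": trajectory,
        "posthoc": posthoc,
        "predictions": predictions,
    }


def _roi_means(alff_stack, brain_mask, roi_mask) -> np.ndarray:
    sel = roi_mask[brain_mask]
    return alff_stack[:, sel].mean(axis=1)


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc


def run_all(
    cfg: RunConfig,
    spec: synthetic.CohortSpec | None = None,
    sim_config: synthetic.SimulationConfig | None = None,
) -> dict:
    """Execute the full pipeline and write artifacts to ``cfg.output_dir``.

    Returns the machine-readable summary (also written as summary.json).
    """
    cfg.validate()
    spec = spec or synthetic.CohortSpec()
    sim_config = sim_config or synthetic.SimulationConfig()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    phen = _stage("simulate", _simulate_phenotypes, spec, sim_config, cfg.seed)
    params = PreprocessParams(
        discard=cfg.discard, fwhm_mm=cfg.fwhm_mm, band_hz=cfg.band_hz,
        exclude_trans_mm=cfg.exclude_trans_mm, exclude_rot_deg=cfg.exclude_rot_deg,
    )
    alff_stack, phen, masks = _stage(
        "preprocess+alff", compute_cohort_alff, phen, sim_config, cfg.seed, params
    )
    analysis = _stage("group-stats", analyze_cohort, alff_stack, phen, masks, cfg)

    write_phenotypes(out / "phenotypes.tsv", phen)
    for effect, cres in analysis["clusters"].items():
        cres.table().to_csv(out / f"clusters_{effect}.tsv", sep="\t", index=False)
    if analysis["trajectory"]:
        analysis["trajectory"]["report"]["table"].to_csv(
            out / "trajectory_fits.tsv", sep="\t", index=False
        )
    summary = summarize(cfg, spec, sim_config, phen, analysis)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    cfg.to_yaml(out / "run_config.yaml")
    return summary


def _simulate_phenotypes(spec, sim_config, seed):
    from dataclasses import replace

    phen = synthetic.generate_phenotypes(replace(spec, seed=seed))
    amps = synthetic.realized_region_amplitudes(phen, sim_config, seed)
    return synthetic.generate_symptoms(phen, amps, sim_config.symptom_coupling, seed)


def summarize(cfg, spec, sim_config, phen, analysis) -> dict:
    """Aggregate the run into a JSON-serializable summary."""
    res = analysis["results"]
    sm = analysis["smoothness"]
    effects = {}
    for name, stat in res.stat_maps.items():
        cres = analysis["clusters"][name]
        effects[name] = {
            "df": [stat.df1, stat.df2],
            "peak_F": float(stat.F[stat.mask].max()),
            "extent_threshold_voxels": cres.extent_threshold,
            "clusters": json.loads(cres.table().to_json(orient="records")),
        }
    trajectory = None
    if analysis["trajectory"]:
        trajectory = json.loads(
            analysis["trajectory"]["report"]["table"].to_json(orient="records")
        )
    predictions = {}
    pvals = []
    for target, pres in analysis["predictions"].items():
        predictions[target] = {
            "r": pres.r,
            "p_perm": pres.p_perm,
            "n_perm": pres.n_perm,
            "n_subjects": int(len(pres.observed)),
        }
        pvals.append(pres.p_perm)
    if len(pvals) == 3:
        flags = bonferroni_gate(pvals)
        for flag, target in zip(flags, predictions):
            predictions[target]["bonferroni_significant"] = flag
    return {
        "seed": cfg.seed,
        "n_subjects": int(len(phen)),
        "n_asd": int((phen["diagnosis"] == "ASD").sum()),
        "n_tc": int((phen["diagnosis"] == "TC").sum()),
        "z_threshold": analysis["z_threshold"],
        "smoothness_fwhm_mm": list(sm.fwhm_mm),
        "resels": sm.resels,
        "effects": effects,
        "trajectory": trajectory,
        "predictions": predictions,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
    }
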