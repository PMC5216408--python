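"""Voxelwise factorial ANCOVA and random-field cluster inference.

The group model is a 2 (diagnosis) x 3 (age cohort) between-subject design
with gender, FIQ and mean framewise displacement as covariates, fitted
voxelwise to standardized ALFF maps.  Factors use sum-to-zero (effects)
coding and each effect is tested with a partial (Type-III style) F test:
F = ((SSE_reduced - SSE_full)/df1) / (SSE_full/df2), where the reduced
model omits that effect's columns.  Effect size is partial eta squared,
SS_effect / (SS_effect + SSE_full).

F maps are converted to one-tailed Z equivalents (F is one-sided) and
cluster-corrected under Gaussian random field (GRF) theory: field
smoothness is estimated from standardized model residuals, the search
volume is expressed in resels, and the minimum cluster extent k is chosen
so the family-wise probability of any suprathreshold cluster of >= k voxels
is at most the cluster alpha.  The cluster-size tail uses the stationary
Gaussian field approximation P(n >= k) = exp(-beta k^(2/3)) with beta set
by the expected cluster count and expected suprathreshold volume.

Classes follow a Model -> fit() -> Results layout: build a
:class:`VoxelwiseANCOVA` from maps and a design, call :meth:`fit`, then ask
the results object for Z maps, smoothness, and corrected clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, special, stats

from .alff import ALFFMap

__all__ = [
    "DesignMatrix",
    "build_design",
    "VoxelwiseANCOVA",
    "VoxelwiseANCOVAResults",
    "StatMap",
    "f_to_z",
    "SmoothnessEstimate",
    "estimate_smoothness",
    "ec_densities",
    "resel_counts",
    "grf_extent_threshold",
    "Cluster",
    "ClusterResult",
    "extract_clusters",
    "posthoc_ttests",
]

COHORT_ORDER = ("child", "adolescent", "adult")


# ---------------------------------------------------------------------------
# design


@dataclass
class DesignMatrix:
    """n x 9 default design: intercept, diagnosis, 2 age, 2 interaction, 3 covariates."""

    matrix: np.ndarray
    columns: list[str]
    effects: dict  # effect name -> column indices
    subject_ids: list[str]
    coding: str = "sum-to-zero"

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))

    @property
    def df_error(self) -> int:
        return self.n - self.matrix.shape[1]


def build_design(
    phenotypes: pd.DataFrame, covariates: tuple[str, ...] = ("gender", "fiq", "mean_fd")
) -> DesignMatrix:
    """Sum-to-zero factorial design with mean-centered covariates.

    Diagnosis is coded ASD = +1, TC = -1; the age factor uses two deviation
    columns (child and adolescent vs the adult reference); interaction
    columns are their products.  Covariates must be present and complete.
    """
    for col in ("diagnosis", "cohort") + covariates:
        if col not in phenotypes.columns:
            raise ValueError(f"phenotypes missing column {col}")
        if phenotypes[col].isna().any():
            raise ValueError(f"missing values in column {col}")
    diag = phenotypes["diagnosis"].to_numpy()
    cohort = phenotypes["cohort"].to_numpy()
    for level in ("ASD", "TC"):
        if not (diag == level).any():
            raise ValueError(f"diagnosis level {level} absent")
    for level in COHORT_ORDER:
        if not (cohort == level).any():
            raise ValueError(f"cohort level {level} absent")
    n = len(phenotypes)
    d = np.where(diag == "ASD", 1.0, -1.0)
    a1 = np.select([cohort == "child", cohort == "adult"], [1.0, -1.0], default=0.0)
    a2 = np.select([cohort == "adolescent", cohort == "adult"], [1.0, -1.0], default=0.0)
    cols = [np.ones(n), d, a1, a2, d * a1, d * a2]
    names = ["intercept", "diagnosis", "age1", "age2", "diag_x_age1", "diag_x_age2"]
    for cov in covariates:
        x = phenotypes[cov].to_numpy(dtype=float)
        cols.append(x - x.mean())
        names.append(cov)
    X = np.column_stack(cols)
    effects = {
        "diagnosis": [1],
        "age": [2, 3],
        "interaction": [4, 5],
        "covariates": list(range(6, 6 + len(covariates))),
    }
    dm = DesignMatrix(X, names, effects, list(phenotypes["subject_id"]))
    if dm.rank < X.shape[1]:
        raise ValueError(f"design matrix rank deficient (rank {dm.rank} < {X.shape[1]})")
    return dm


# ---------------------------------------------------------------------------
# stat maps and F -> Z


@dataclass
class StatMap:
    """Voxelwise F image with its df, partial eta^2 and Z-equivalent."""

    effect: str
    F: np.ndarray
    df1: int
    df2: int
    partial_eta2: np.ndarray
    Z: np.ndarray
    mask: np.ndarray


def f_to_z(F, df1: int, df2: int):
    """Map F statistics to one-tailed standard-normal Z equivalents.

    Z solves Phi(-Z) = P(F' > F); the tail is computed in log space so very
    large F values do not underflow to Z = inf.
    """
    F = np.asarray(F, dtype=float)
    logp = stats.f.logsf(np.maximum(F, 0.0), df1, df2)
    z = -special.ndtri_exp(logp)
    return z if z.shape else float(z)


# ---------------------------------------------------------------------------
# the model


def _stack_maps(maps) -> tuple[np.ndarray, np.ndarray, tuple]:
    if isinstance(maps, np.ndarray):
        raise TypeError("pass a list of ALFFMap or (data, mask) explicitly")
    mask = np.asarray(maps[0].mask, dtype=bool)
    vox = tuple(maps[0].voxel_size_mm)
    Y = np.stack([m.values[mask] for m in maps])
    return Y, mask, vox


class VoxelwiseANCOVA:
    """Voxelwise linear model for the 2 x 3 + covariates group analysis.

    Parameters
    ----------
    maps
        One :class:`~alffdev.alff.ALFFMap` per design row (standardized
        ALFF), or a pre-stacked (n_subjects, n_voxels) array together with
        ``mask`` and ``voxel_size_mm``.
    design
        A :class:`DesignMatrix` from :func:`build_design`.
    """

    def __init__(self, maps, design: DesignMatrix, mask=None, voxel_size_mm=(3.0, 3.0, 3.0)):
        if isinstance(maps, np.ndarray):
            if mask is None:
                raise ValueError("mask is required with a pre-stacked data array")
            self.mask = np.asarray(mask, dtype=bool)
            self.Y = np.asarray(maps, dtype=float)
            self.voxel_size_mm = tuple(voxel_size_mm)
        else:
            self.Y, self.mask, self.voxel_size_mm = _stack_maps(maps)
        if self.Y.shape[0] != design.n:
            raise ValueError("need one map per design row")
        self.design = design

    def fit(self) -> "VoxelwiseANCOVAResults":
        X = self.design.matrix
        n, p = X.shape
        if np.linalg.matrix_rank(X) < p:
            raise ValueError("design rank deficient")
        Y = self.Y
        Q, _ = np.linalg.qr(X)
        fitted = Q @ (Q.T @ Y)
        resid = Y - fitted
        sse_full = np.einsum("ij,ij->j", resid, resid)
        df2 = n - p
        stat_maps = {}
        for effect in ("diagnosis", "age", "interaction"):
            idx = self.design.effects[effect]
            keep = [j for j in range(p) if j not in idx]
            Qr, _ = np.linalg.qr(X[:, keep])
            resid_r = Y - Qr @ (Qr.T @ Y)
            sse_r = np.einsum("ij,ij->j", resid_r, resid_r)
            ss_eff = np.maximum(sse_r - sse_full, 0.0)
            df1 = len(idx)
            with np.errstate(divide="ignore", invalid="ignore"):
                F = (ss_eff / df1) / (sse_full / df2)
                eta2 = ss_eff / (ss_eff + sse_full)
            # identical maps across subjects: 0/0 guarded to 0
            degenerate = (sse_full < 1e-30) | ~np.isfinite(F)
            F = np.where(degenerate, 0.0, F)
            eta2 = np.where((ss_eff + sse_full) < 1e-30, 0.0, eta2)
            stat_maps[effect] = self._to_statmap(effect, F, df1, df2, eta2)
        return VoxelwiseANCOVAResults(self, stat_maps, resid, sse_full, df2)

    def _to_statmap(self, effect, F, df1, df2, eta2) -> StatMap:
        grid = self.mask.shape
        Fm, Em, Zm = np.zeros(grid), np.zeros(grid), np.zeros(grid)
        Fm[self.mask] = F
        Em[self.mask] = eta2
        Zm[self.mask] = f_to_z(F, df1, df2)
        return StatMap(effect, Fm, df1, df2, Em, Zm, self.mask)


@dataclass
class VoxelwiseANCOVAResults:
    """Fitted voxelwise ANCOVA: stat maps, residuals and cluster inference."""

    model: VoxelwiseANCOVA
    stat_maps: dict
    residuals: np.ndarray  # n_subjects x n_in-mask voxels
    sse: np.ndarray
    df_error: int

    def __getitem__(self, effect: str) -> StatMap:
        return self.stat_maps[effect]

    def smoothness(self) -> "SmoothnessEstimate":
        return estimate_smoothness(
            self.residuals, self.model.mask, self.model.voxel_size_mm
        )

    def cluster_correct(
        self,
        effect: str,
        z_thresh: float | None = None,
        voxel_p: float = 0.01,
        cluster_alpha: float = 0.05,
        connectivity: int = 6,
        smoothness: "SmoothnessEstimate | None" = None,
    ) -> "ClusterResult":
        """GRF cluster-extent correction of one effect's Z map."""
        if z_thresh is None:
            z_thresh = float(stats.norm.isf(voxel_p))
        sm = smoothness or self.smoothness()
        k, info = grf_extent_threshold(z_thresh, sm, self.model.mask, cluster_alpha)
        return extract_clusters(
            self.stat_maps[effect].Z, z_thresh, k, connectivity, self.model.mask, grf_info=info
        )

    def summary(self) -> pd.DataFrame:
        """Peak statistics per effect, in a table."""
        rows = []
        for name, sm in self.stat_maps.items():
            inm = sm.F[sm.mask]
            peak = int(np.argmax(inm))
            rows.append({
                "effect": name,
                "df1": sm.df1,
                "df2": sm.df2,
                "peak_F": float(inm[peak]),
                "peak_Z": float(sm.Z[sm.mask][peak]),
                "peak_partial_eta2": float(sm.partial_eta2[sm.mask][peak]),
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# smoothness and GRF


@dataclass
class SmoothnessEstimate:
    """Estimated field smoothness: per-axis FWHM and the resel volume."""

    fwhm_vox: tuple[float, float, float]
    fwhm_mm: tuple[float, float, float]
    resels: float
    n_voxels: int

    def __post_init__(self) -> None:
        if min(self.fwhm_vox) < 1e-6 or self.resels <= 0:
            raise ValueError("degenerate smoothness estimate (flat residuals?)")


def estimate_smoothness(
    residuals: np.ndarray,
    mask: np.ndarray,
    voxel_size_mm=(3.0, 3.0, 3.0),
    gaussian_acf_correction: bool = True,
) -> SmoothnessEstimate:
    """Residual-based random-field smoothness.

    Residual vectors are normalized to unit length per voxel; the pooled
    variance ``var`` of their spatial first differences along each axis
    measures local roughness.  The raw derivative formula
    fwhm = sqrt(4 ln 2 / var) treats the first difference as an exact
    derivative and therefore overestimates the FWHM of discretely sampled
    smooth fields.  With ``gaussian_acf_correction`` (default) the lag-one
    autocorrelation implied by a Gaussian autocorrelation function is
    inverted instead — var = 2 (1 - exp(-1/(4 sigma^2))) — which recovers
    the kernel FWHM without discretization bias (the estimator used by the
    classic smoothness tools).  Fields rougher than white noise
    (var >= 2) fall back to the raw formula.  The resel count is the
    in-mask voxel volume divided by the product of the FWHMs.
    """
    mask = np.asarray(mask, dtype=bool)
    if residuals.ndim == 2:
        n = residuals.shape[0]
        full = np.zeros((n,) + mask.shape)
        full[:, mask] = residuals
    else:
        full = residuals
        n = full.shape[0]
    if n < 2:
        raise ValueError("need at least 2 residual maps")
    norm = np.sqrt((full**2).sum(axis=0))
    ok = mask & (norm > 0)
    u = np.zeros_like(full)
    u[:, ok] = full[:, ok] / norm[ok]
    fwhm_vox = []
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(1, None)
        sl_b[axis] = slice(None, -1)
        pair = ok[tuple(sl_a)] & ok[tuple(sl_b)]
        if not pair.any():
            raise ValueError("mask too thin to estimate smoothness")
        d = u[(slice(None),) + tuple(sl_a)] - u[(slice(None),) + tuple(sl_b)]
        var = float((d[:, pair] ** 2).sum(axis=0).mean())
        if var <= 0:
            raise ValueError("flat residuals: infinite smoothness")
        if gaussian_acf_correction and var < 2.0:
            sigma2 = -1.0 / (4.0 * np.log(1.0 - var / 2.0))
            fwhm_vox.append(float(np.sqrt(8.0 * np.log(2.0) * sigma2)))
        else:
            fwhm_vox.append(float(np.sqrt(4.0 * np.log(2.0) / var)))
    vox = tuple(float(v) for v in voxel_size_mm)
    fwhm_mm = tuple(f * v for f, v in zip(fwhm_vox, vox))
    n_voxels = int(mask.sum())
    resels = n_voxels / float(np.prod(fwhm_vox))
    return SmoothnessEstimate(tuple(fwhm_vox), fwhm_mm, resels, n_voxels)


def ec_densities(u: float) -> tuple[float, float, float, float]:
    """Euler-characteristic densities rho_0..rho_3 of a unit Gaussian field."""
    l2 = 4.0 * np.log(2.0)
    e = np.exp(-u * u / 2.0)
    rho0 = float(stats.norm.sf(u))
    rho1 = np.sqrt(l2) / (2.0 * np.pi) * e
    rho2 = l2 / (2.0 * np.pi) ** 1.5 * u * e
    rho3 = l2**1.5 / (2.0 * np.pi) ** 2 * (u * u - 1.0) * e
    return rho0, float(rho1), float(rho2), float(rho3)


def resel_counts(mask: np.ndarray, fwhm_vox) -> tuple[float, float, float, float]:
    """Lattice resel counts R_0..R_3 of a mask (Worsley's counting method).

    Counts points, edges, faces and cubes of the in-mask lattice and scales
    them by the per-axis resel sizes 1/FWHM.  Including the lower-order
    counts keeps the expected Euler characteristic accurate for masks whose
    boundary is a non-trivial fraction of the volume.
    """
    m = np.asarray(mask, dtype=bool)
    rx, ry, rz = (1.0 / f for f in fwhm_vox)
    P = float(m.sum())
    Ex = float((m[1:, :, :] & m[:-1, :, :]).sum())
    Ey = float((m[:, 1:, :] & m[:, :-1, :]).sum())
    Ez = float((m[:, :, 1:] & m[:, :, :-1]).sum())
    Fxy = float((m[1:, 1:, :] & m[:-1, 1:, :] & m[1:, :-1, :] & m[:-1, :-1, :]).sum())
    Fxz = float((m[1:, :, 1:] & m[:-1, :, 1:] & m[1:, :, :-1] & m[:-1, :, :-1]).sum())
    Fyz = float((m[:, 1:, 1:] & m[:, :-1, 1:] & m[:, 1:, :-1] & m[:, :-1, :-1]).sum())
    c = m[1:, 1:, 1:] & m[:-1, 1:, 1:] & m[1:, :-1, 1:] & m[1:, 1:, :-1]
    c &= m[:-1, :-1, 1:] & m[:-1, 1:, :-1] & m[1:, :-1, :-1] & m[:-1, :-1, :-1]
    C = float(c.sum())
    R0 = P - Ex - Ey - Ez + Fxy + Fxz + Fyz - C
    R1 = (Ex - Fxy - Fxz + C) * rx + (Ey - Fxy - Fyz + C) * ry + (Ez - Fxz - Fyz + C) * rz
    R2 = (Fxy - C) * rx * ry + (Fxz - C) * rx * rz + (Fyz - C) * ry * rz
    R3 = C * rx * ry * rz
    return R0, R1, R2, R3


def _cluster_model(z_thresh: float, smoothness: SmoothnessEstimate, mask: np.ndarray) -> dict:
    rho = ec_densities(z_thresh)
    R = resel_counts(mask, smoothness.fwhm_vox)
    e_clusters = max(float(np.dot(R, rho)), 1e-12)
    e_voxels = smoothness.n_voxels * rho[0]
    e_size = e_voxels / e_clusters
    beta = (special.gamma(2.5) * e_clusters / max(e_voxels, 1e-12)) ** (2.0 / 3.0)
    return {
        "z_thresh": z_thresh,
        "E_clusters": e_clusters,
        "E_suprathreshold_voxels": e_voxels,
        "E_cluster_size": e_size,
        "beta": beta,
    }


def _tail(beta: float, k: float) -> float:
    return float(np.exp(-beta * k ** (2.0 / 3.0)))


def grf_extent_threshold(
    z_thresh: float,
    smoothness: SmoothnessEstimate,
    mask: np.ndarray,
    cluster_alpha: float = 0.05,
) -> tuple[int, dict]:
    """Smallest cluster extent k with family-wise cluster error <= alpha.

    FWER(k) = 1 - exp(-E[m] * P(n >= k)) under the Poisson clumping
    heuristic, with E[m] from the Euler-characteristic densities over the
    resel counts and P(n >= k) from the stationary cluster-size
    approximation.
    """
    if z_thresh <= 0:
        raise ValueError("z threshold must be positive")
    info = _cluster_model(z_thresh, smoothness, mask)
    em, beta = info["E_clusters"], info["beta"]
    k = 1
    while 1.0 - np.exp(-em * _tail(beta, k)) > cluster_alpha:
        k += 1
        if k > smoothness.n_voxels:
            break
    info["extent_threshold"] = k
    info["cluster_alpha"] = cluster_alpha
    return k, info


# ---------------------------------------------------------------------------
# cluster extraction


@dataclass
class Cluster:
    voxels: np.ndarray  # (k, 3) grid coordinates
    extent: int
    peak_z: float
    peak_coord: tuple[int, int, int]
    p_corrected: float


@dataclass
class ClusterResult:
    clusters: list
    z_threshold: float
    extent_threshold: int
    connectivity: int
    grf_info: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.clusters)

    def union_mask(self, grid_dims) -> np.ndarray:
        out = np.zeros(grid_dims, dtype=bool)
        for c in self.clusters:
            out[tuple(c.voxels.T)] = True
        return out

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "cluster": i + 1,
                "extent_voxels": c.extent,
                "peak_z": c.peak_z,
                "peak_x": c.peak_coord[0],
                "peak_y": c.peak_coord[1],
                "peak_z_coord": c.peak_coord[2],
                "cluster_p_corrected": c.p_corrected,
            }
            for i, c in enumerate(self.clusters)
        ]
        return pd.DataFrame(rows)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def extract_clusters(
    z_map: np.ndarray,
    z_thresh: float,
    extent_threshold: int,
    connectivity: int = 6,
    mask: np.ndarray | None = None,
    grf_info: dict | None = None,
) -> ClusterResult:
    """Connected suprathreshold components with extent >= the threshold.

    Face connectivity (6 neighbours) is the default; 18 and 26 are
    available.  Cluster-level corrected p values come from the same GRF
    cluster-size model used to pick the extent threshold.
    """
    supra = np.asarray(z_map) > z_thresh
    if mask is not None:
        supra &= np.asarray(mask, dtype=bool)
    labels, n_lab = ndimage.label(supra, structure=_STRUCTURES[connectivity])
    clusters = []
    for lab in range(1, n_lab + 1):
        voxels = np.argwhere(labels == lab)
        extent = len(voxels)
        if extent < extent_threshold:
            continue
        zvals = z_map[tuple(voxels.T)]
        peak = int(np.argmax(zvals))
        if grf_info:
            p = 1.0 - np.exp(-grf_info["E_clusters"] * _tail(grf_info["beta"], extent))
            p = float(min(max(p, np.finfo(float).tiny), 1.0))
        else:
            p = np.nan
        clusters.append(
            Cluster(voxels, extent, float(zvals[peak]), tuple(int(v) for v in voxels[peak]), p)
        )
    clusters.sort(key=lambda c: -c.extent)
    return ClusterResult(clusters, float(z_thresh), int(extent_threshold), connectivity, grf_info or {})


# ---------------------------------------------------------------------------
# post-hoc ROI comparisons


def posthoc_ttests(
    roi_values: np.ndarray,
    phenotypes: pd.DataFrame,
    family_size: int = 3,
    family_alpha: float = 0.05,
) -> pd.DataFrame:
    """ASD vs TC two-sample t-tests per age cohort and pooled.

    Per-cohort comparisons are Bonferroni-gated at alpha / family_size
    (0.05/3 ~= 0.017 for the three cohorts); the pooled comparison is
    reported at the family alpha.
    """
    roi_values = np.asarray(roi_values, dtype=float)
    diag = phenotypes["diagnosis"].to_numpy()
    cohort = phenotypes["cohort"].to_numpy()
    alpha_pc = family_alpha / family_size
    rows = []
    for name in list(COHORT_ORDER) + ["pooled"]:
        sel = np.ones(len(diag), dtype=bool) if name == "pooled" else cohort == name
        a = roi_values[sel & (diag == "ASD")]
        b = roi_values[sel & (diag == "TC")]
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"cohort {name}: need at least 2 subjects per group")
        if np.ptp(np.concatenate([a, b])) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=True)
        alpha = family_alpha if name == "pooled" else alpha_pc
        rows.append({
            "comparison": name,
            "n_asd": len(a),
            "n_tc": len(b),
            "t": float(t),
            "p": float(p),
            "alpha": round(alpha, 3),
            "significant": bool(p < alpha),
        })
    return pd.DataFrame(rows)
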