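"""Tests of the group model: design, ANCOVA, smoothness, GRF, clusters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from alffdev.calibration import smooth_null_field
from alffdev.glm import (
    SmoothnessEstimate,
    VoxelwiseANCOVA,
    build_design,
    ec_densities,
    estimate_smoothness,
    extract_clusters,
    f_to_z,
    grf_extent_threshold,
    posthoc_ttests,
    resel_counts,
)
from alffdev.synthetic import CohortSpec, generate_phenotypes


@pytest.fixture(scope="module")
def default_phen():
    phen = generate_phenotypes(CohortSpec(seed=0))
    rng = np.random.default_rng(0)
    phen["mean_fd"] = rng.uniform(0.05, 0.2, len(phen))
    return phen


def glm_oracle(X, y, effect_cols):
    """Direct normal-equations GLM oracle: explicit (X'X)^-1 computations."""
    n, p = X.shape
    bhat = np.linalg.inv(X.T @ X) @ X.T @ y
    sse_full = float(((y - X @ bhat) ** 2).sum())
    keep = [j for j in range(p) if j not in effect_cols]
    Xr = X[:, keep]
    br = np.linalg.inv(Xr.T @ Xr) @ Xr.T @ y
    sse_r = float(((y - Xr @ br) ** 2).sum())
    df1, df2 = len(effect_cols), n - p
    ss = sse_r - sse_full
    return (ss / df1) / (sse_full / df2), ss / (ss + sse_full)


class TestDesign:
    def test_default_cohort_gives_128x9_rank9_df119(self, default_phen):
        dm = build_design(default_phen)
        assert dm.matrix.shape == (128, 9)
        assert dm.rank == 9
        assert dm.df_error == 119

    def test_balanced_factors_orthogonal_without_covariates(self):
        cells = {(d, c): 4 for d in ("ASD", "TC") for c in ("child", "adolescent", "adult")}
        phen = generate_phenotypes(CohortSpec(cell_sizes=cells, seed=1))
        dm = build_design(phen, covariates=())
        X = dm.matrix
        G = X.T @ X
        # diagnosis column orthogonal to age and interaction columns
        assert np.allclose(G[1, 2:6], 0.0)
        assert np.allclose(G[2:4, 4:6], 0.0)

    def test_dropping_covariates_raises_df_error_by_3(self, default_phen):
        full = build_design(default_phen)
        reduced = build_design(default_phen, covariates=())
        assert reduced.df_error == full.df_error + 3

    def test_absent_factor_level_rejected(self, default_phen):
        phen = default_phen[default_phen["cohort"] != "adult"]
        with pytest.raises(ValueError, match="adult"):
            build_design(phen)


class TestANCOVA:
    def test_identical_maps_give_zero_f(self, default_phen):
        dm = build_design(default_phen)
        Y = np.ones((128, 10))
        mask = np.ones((10, 1, 1), bool)
        res = VoxelwiseANCOVA(Y, dm, mask=mask).fit()
        for eff in ("diagnosis", "age", "interaction"):
            assert np.all(res[eff].F == 0)

    def test_matches_direct_normal_equations_oracle(self):
        # 12-subject toy: 2 x 3 cells of 2, one covariate
        cells = {(d, c): 2 for d in ("ASD", "TC") for c in ("child", "adolescent", "adult")}
        phen = generate_phenotypes(CohortSpec(cell_sizes=cells, seed=2))
        rng = np.random.default_rng(3)
        phen["mean_fd"] = rng.uniform(0.05, 0.2, 12)
        dm = build_design(phen, covariates=("mean_fd",))
        Y = rng.normal(size=(12, 5))
        mask = np.ones((5, 1, 1), bool)
        res = VoxelwiseANCOVA(Y, dm, mask=mask).fit()
        for eff in ("diagnosis", "age", "interaction"):
            for v in range(5):
                F_o, eta_o = glm_oracle(dm.matrix, Y[:, v], dm.effects[eff])
                assert res[eff].F[v, 0, 0] == pytest.approx(F_o, abs=1e-8)
                assert res[eff].partial_eta2[v, 0, 0] == pytest.approx(eta_o, abs=1e-8)

    def test_partial_eta2_identity(self, default_phen, rng):
        dm = build_design(default_phen)
        Y = rng.normal(size=(128, 50))
        res = VoxelwiseANCOVA(Y, dm, mask=np.ones((50, 1, 1), bool)).fit()
        for eff in ("diagnosis", "age", "interaction"):
            sm = res[eff]
            F, eta = sm.F[sm.mask], sm.partial_eta2[sm.mask]
            want = (F * sm.df1) / (F * sm.df1 + sm.df2)
            assert np.allclose(eta, want, atol=1e-10)

    def test_partial_equals_sequential_in_balanced_design(self):
        cells = {(d, c): 4 for d in ("ASD", "TC") for c in ("child", "adolescent", "adult")}
        phen = generate_phenotypes(CohortSpec(cell_sizes=cells, seed=4))
        dm = build_design(phen, covariates=())
        rng = np.random.default_rng(5)
        y = rng.normal(size=24)
        X = dm.matrix
        # sequential SS for the interaction (last term) equals the partial SS
        F_partial, _ = glm_oracle(X, y, dm.effects["interaction"])
        # and for diagnosis (first factor): fit after intercept only
        for eff in ("diagnosis", "age"):
            idx = dm.effects[eff]
            prior = [0] + [j for j in range(1, 6) if j < min(idx)]
            Xp = X[:, prior]
            Xf = X[:, prior + idx]
            sse_p = float(((y - Xp @ np.linalg.lstsq(Xp, y, rcond=None)[0]) ** 2).sum())
            sse_f = float(((y - Xf @ np.linalg.lstsq(Xf, y, rcond=None)[0]) ** 2).sum())
            ss_seq = sse_p - sse_f
            bfull = np.linalg.lstsq(X, y, rcond=None)[0]
            sse_full = float(((y - X @ bfull) ** 2).sum())
            keep = [j for j in range(6) if j not in idx]
            Xr = X[:, keep]
            sse_r = float(((y - Xr @ np.linalg.lstsq(Xr, y, rcond=None)[0]) ** 2).sum())
            assert ss_seq == pytest.approx(sse_r - sse_full, rel=1e-8)

    def test_df_bookkeeping_at_full_cohort(self, default_phen, rng):
        dm = build_design(default_phen)
        Y = rng.normal(size=(128, 4))
        res = VoxelwiseANCOVA(Y, dm, mask=np.ones((4, 1, 1), bool)).fit()
        assert (res["diagnosis"].df1, res["diagnosis"].df2) == (1, 119)
        assert (res["age"].df1, res["age"].df2) == (2, 119)
        assert (res["interaction"].df1, res["interaction"].df2) == (2, 119)

    def test_null_f_follows_f_distribution(self, default_phen, rng):
        dm = build_design(default_phen)
        Y = rng.normal(size=(128, 2000))
        res = VoxelwiseANCOVA(Y, dm, mask=np.ones((2000, 1, 1), bool)).fit()
        for eff in ("diagnosis", "interaction"):
            sm = res[eff]
            ks = stats.kstest(sm.F[sm.mask], lambda x, s=sm: stats.f.cdf(x, s.df1, s.df2))
            assert ks.pvalue > 0.01


class TestFToZ:
    def test_p_001_maps_to_z_233(self):
        F = stats.f.isf(0.01, 2, 119)
        assert f_to_z(F, 2, 119) == pytest.approx(stats.norm.isf(0.01), abs=1e-8)
        assert round(float(f_to_z(F, 2, 119)), 2) == 2.33

    def test_median_f_maps_to_zero(self):
        F = stats.f.ppf(0.5, 1, 119)
        assert abs(f_to_z(F, 1, 119)) < 1e-8

    def test_monotone_and_finite_for_huge_f(self):
        F = np.array([0.5, 1.0, 5.0, 50.0, 500.0, 5000.0])
        z = f_to_z(F, 1, 119)
        assert np.all(np.diff(z) > 0)
        assert np.isfinite(z).all()


class TestSmoothness:
    def test_white_noise_fwhm_without_correction(self, rng):
        # var of first differences of normalized white noise is 2:
        # raw formula gives sqrt(4 ln 2 / 2) = sqrt(2 ln 2) ~ 1.177 voxels
        maps = rng.normal(size=(60, 12, 12, 12))
        mask = np.ones((12, 12, 12), bool)
        est = estimate_smoothness(maps, mask, (1, 1, 1), gaussian_acf_correction=False)
        for f in est.fwhm_vox:
            assert f == pytest.approx(np.sqrt(2 * np.log(2)), rel=0.1)

    def test_known_kernel_recovered(self, rng):
        true_fwhm = 8.0 / 3.0  # 8 mm at 3 mm voxels
        maps = np.stack([smooth_null_field((16, 16, 16), true_fwhm, rng) for _ in range(50)])
        est = estimate_smoothness(maps, np.ones((16, 16, 16), bool), (3, 3, 3))
        for f in est.fwhm_mm:
            assert f == pytest.approx(8.0, rel=0.15)

    def test_voxel_size_scales_fwhm_mm(self, rng):
        maps = rng.normal(size=(30, 10, 10, 10))
        mask = np.ones((10, 10, 10), bool)
        a = estimate_smoothness(maps, mask, (3, 3, 3))
        b = estimate_smoothness(maps, mask, (6, 6, 6))
        assert np.allclose(np.array(b.fwhm_mm), 2 * np.array(a.fwhm_mm))
        assert a.fwhm_vox == b.fwhm_vox


class TestGRFThreshold:
    def _smoothness(self, fwhm, mask):
        return SmoothnessEstimate(
            (fwhm,) * 3, (3 * fwhm,) * 3, mask.sum() / fwhm**3, int(mask.sum())
        )

    def test_k_decreases_with_higher_z_threshold(self):
        mask = np.ones((20, 20, 20), bool)
        sm = self._smoothness(3.0, mask)
        k_low, _ = grf_extent_threshold(2.33, sm, mask)
        k_high, _ = grf_extent_threshold(3.1, sm, mask)
        assert k_high < k_low

    def test_k_increases_with_search_volume(self):
        small = np.ones((14, 14, 14), bool)
        big = np.ones((28, 28, 28), bool)
        k_small, _ = grf_extent_threshold(2.33, self._smoothness(3.0, small), small)
        k_big, _ = grf_extent_threshold(2.33, self._smoothness(3.0, big), big)
        assert k_big > k_small

    def test_resel_counts_of_a_box(self):
        mask = np.ones((11, 11, 11), bool)
        R0, R1, R2, R3 = resel_counts(mask, (2.0, 2.0, 2.0))
        assert R0 == pytest.approx(1.0)
        assert R1 == pytest.approx(3 * 10 / 2.0)
        assert R2 == pytest.approx(3 * 100 / 4.0)
        assert R3 == pytest.approx(1000 / 8.0)

    def test_ec_densities_signs_and_magnitudes(self):
        rho = ec_densities(2.33)
        assert rho[0] == pytest.approx(stats.norm.sf(2.33), rel=1e-12)
        assert all(r > 0 for r in rho[1:])


class TestClusters:
    def test_empty_suprathreshold_set(self):
        z = np.zeros((5, 5, 5))
        res = extract_clusters(z, 2.33, 1)
        assert len(res) == 0

    def test_two_disjoint_blobs(self):
        z = np.zeros((10, 10, 10))
        z[1:3, 1:3, 1:3] = 5.0
        z[7:9, 7:9, 7:9] = 4.0
        res = extract_clusters(z, 2.33, 1)
        assert len(res) == 2
        assert sorted(c.extent for c in res.clusters) == [8, 8]
        assert res.clusters[0].peak_z == 5.0

    def test_connectivity_6_vs_26_on_diagonal_pair(self):
        z = np.zeros((6, 6, 6))
        z[2, 2, 2] = 3.0
        z[3, 3, 3] = 3.0  # touches only diagonally
        assert len(extract_clusters(z, 2.33, 1, connectivity=6)) == 2
        assert len(extract_clusters(z, 2.33, 1, connectivity=26)) == 1

    def test_extent_threshold_filters(self):
        z = np.zeros((8, 8, 8))
        z[0:2, 0, 0] = 3.0   # size 2
        z[5:8, 5, 5] = 3.0   # size 3
        res = extract_clusters(z, 2.33, 3)
        assert len(res) == 1 and res.clusters[0].extent == 3


class TestPosthoc:
    def _phen(self, n=10):
        rows = []
        for c in ("child", "adolescent", "adult"):
            for d in ("ASD", "TC"):
                for i in range(n):
                    rows.append({"subject_id": f"{d}-{c}-{i}", "diagnosis": d, "cohort": c})
        return pd.DataFrame(rows)

    def test_identical_groups_give_t0_p1(self, rng):
        phen = self._phen()
        base = rng.normal(size=30)
        vals = np.concatenate([v for v in
                               [base[:10], base[:10], base[10:20], base[10:20],
                                base[20:], base[20:]]])
        out = posthoc_ttests(vals, phen)
        assert np.allclose(out["t"], 0.0, atol=1e-12)
        assert np.allclose(out["p"], 1.0)

    def test_bonferroni_alpha_reported_as_0017(self, rng):
        out = posthoc_ttests(rng.normal(size=60), self._phen())
        assert (out.loc[out.comparison != "pooled", "alpha"] == 0.017).all()

    def test_t_squared_equals_oneway_f(self, rng):
        phen = self._phen()
        vals = rng.normal(size=60)
        out = posthoc_ttests(vals, phen)
        row = out[out.comparison == "child"].iloc[0]
        a = vals[:10]
        b = vals[10:20]
        F = stats.f_oneway(a, b).statistic
        assert row.t**2 == pytest.approx(F, rel=1e-10)

    def test_small_cohort_rejected(self):
        phen = self._phen(n=1)
        with pytest.raises(ValueError, match="at least 2"):
            posthoc_ttests(np.zeros(6), phen)
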