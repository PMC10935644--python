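"""Voxelwise GLM, smoothness estimation, RFT thresholds and ROI overlap."""

import numpy as np
import pytest
from scipy import stats
from scipy.ndimage import gaussian_filter

import braakadl as ba
from braakadl.voxelwise import (
    TMap,
    VoxelImageSet,
    estimate_smoothness,
    expected_euler_characteristic,
    fit_voxelwise_glm,
    rft_threshold,
    roi_overlap,
)

SIGMA = 1.0 / np.sqrt(8 * np.log(2))  # per-FWHM-voxel kernel SD


def _smooth_noise_set(rng, n, shape, fwhm_vox, voxel=(2.0, 2.0, 2.0)):
    vols = np.stack(
        [
            gaussian_filter(rng.standard_normal(shape), SIGMA * fwhm_vox, mode="wrap")
            for _ in range(n)
        ]
    )
    return VoxelImageSet(vols, voxel_size=voxel)


class TestGlm:
    def test_degenerate_voxel_masked_to_zero(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((20, 4, 4, 4))
        data[:, 0, 0, 0] = 7.0  # constant across subjects
        tm = fit_voxelwise_glm(VoxelImageSet(data), rng.standard_normal(20))
        assert tm.t[0, 0, 0] == 0.0
        assert tm.degenerate[0, 0, 0]
        assert not tm.degenerate[1:].any()

    def test_null_t_follows_t_distribution(self):
        rng = np.random.default_rng(1)
        imgs = VoxelImageSet(rng.standard_normal((30, 20, 10, 10)))
        tm = fit_voxelwise_glm(imgs, rng.standard_normal(30),
                               rng.standard_normal((30, 2)))
        vals = tm.t[np.isfinite(tm.t)]
        assert len(vals) == 2000
        assert stats.kstest(vals, stats.t(tm.df).cdf).pvalue > 0.01

    def test_incomplete_covariates_rejected(self):
        rng = np.random.default_rng(2)
        imgs = VoxelImageSet(rng.standard_normal((20, 4, 4, 4)))
        cov = rng.standard_normal((20, 1))
        cov[3] = np.nan
        with pytest.raises(ValueError, match="complete"):
            fit_voxelwise_glm(imgs, rng.standard_normal(20), cov)


class TestSmoothness:
    def test_known_fwhm_recovered_within_15_percent(self):
        rng = np.random.default_rng(3)
        ratios = []
        for _ in range(20):
            imgs = _smooth_noise_set(rng, 12, (40, 40, 40), fwhm_vox=4.0)
            fwhm_mm, _ = estimate_smoothness(imgs.data, imgs.mask, imgs.voxel_size)
            ratios.append(fwhm_mm / 8.0)  # 4 voxels * 2 mm
        assert np.all(np.abs(np.mean(ratios, axis=0) - 1) < 0.15)

    def test_unsmoothed_noise_fwhm_near_voxel_scale(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((15, 20, 20, 20))
        fwhm_mm, resels = estimate_smoothness(data, np.ones((20, 20, 20), bool),
                                              (1.0, 1.0, 1.0))
        assert np.all((fwhm_mm > 0.7) & (fwhm_mm < 1.8))
        assert resels > 8000 / 6  # same order as the voxel count

    def test_doubling_fwhm_divides_resels_by_eight(self):
        rng = np.random.default_rng(5)
        imgs1 = _smooth_noise_set(rng, 15, (36, 36, 36), fwhm_vox=2.0)
        imgs2 = _smooth_noise_set(rng, 15, (36, 36, 36), fwhm_vox=4.0)
        _, r1 = estimate_smoothness(imgs1.data, imgs1.mask, imgs1.voxel_size)
        _, r2 = estimate_smoothness(imgs2.data, imgs2.mask, imgs2.voxel_size)
        assert 6.0 < r1 / r2 < 10.0

    def test_tiny_mask_rejected(self):
        rng = np.random.default_rng(6)
        mask = np.zeros((8, 8, 8), bool)
        mask[:2, :2, :2] = True
        with pytest.raises(ValueError, match="mask"):
            estimate_smoothness(rng.standard_normal((12, 8, 8, 8)), mask, (2, 2, 2))


def _dummy_tmap(df=40, resels=500.0, shape=(6, 6, 6)):
    mask = np.ones(shape, bool)
    return TMap(
        t=np.zeros(shape), df=df, mask=mask, voxel_size=(2, 2, 2),
        degenerate=np.zeros(shape, bool), resels=resels, fwhm_mm=np.array([6.0] * 3),
    )


class TestRft:
    def test_threshold_decreases_with_alpha(self):
        thrs = [rft_threshold(_dummy_tmap(), a)[0] for a in (0.001, 0.01, 0.05, 0.5)]
        assert all(a > b for a, b in zip(thrs, thrs[1:]))

    def test_threshold_nonincreasing_in_smoothness(self):
        # fewer resels (smoother field) => lower threshold, over a wide grid
        thrs = [
            rft_threshold(_dummy_tmap(resels=r), 0.05)[0]
            for r in (2000, 500, 100, 20, 5)
        ]
        assert all(a >= b for a, b in zip(thrs, thrs[1:]))

    def test_expected_ec_decreasing_in_t(self):
        ec = [expected_euler_characteristic(t, 40, 500.0) for t in np.linspace(2, 8, 20)]
        assert all(a > b for a, b in zip(ec, ec[1:]))

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            rft_threshold(_dummy_tmap(), 1.5)

    def test_suprathreshold_mask_definition(self):
        tm = _dummy_tmap()
        rng = np.random.default_rng(7)
        tm.t = rng.normal(0, 3, tm.t.shape)
        thr, supra = rft_threshold(tm, 0.05)
        np.testing.assert_array_equal(supra, tm.t > thr)
        assert thr > 0


class TestOverlap:
    def test_full_and_disjoint_overlap(self):
        roi = np.zeros((10, 10, 10), bool)
        roi[:5] = True
        rep = roi_overlap(roi, {"I-II": roi, "V-VI": ~roi})
        assert rep.proportion("I-II") == 1.0
        assert rep.proportion("V-VI") == 0.0

    def test_printed_percentage_arithmetic(self):
        # 932 of 1000 ROI voxels suprathreshold -> 93.2%
        roi = np.zeros((10, 10, 10), bool)
        roi.ravel()[:1000] = True
        supra = np.zeros_like(roi)
        supra.ravel()[:932] = True
        rep = roi_overlap(supra, {"V-VI": roi})
        assert 100 * rep.proportion("V-VI") == pytest.approx(93.2)
        row = rep.table.iloc[0]
        assert row["n_intersect"] == 932 and row["n_roi"] == 1000

    def test_grid_mismatch_errors(self):
        with pytest.raises(ValueError, match="grid"):
            roi_overlap(np.ones((4, 4, 4), bool), {"x": np.ones((5, 4, 4), bool)})

    def test_both_denominators_reported(self):
        supra = np.zeros((6, 6, 6), bool)
        supra[:3] = True
        roi = np.zeros_like(supra)
        roi[2:4] = True
        rep = roi_overlap(supra, {"m": roi})
        row = rep.table.iloc[0]
        assert row["frac_of_roi"] == pytest.approx(0.5)
        assert row["frac_of_tmap"] == pytest.approx(36 / 108)


class TestSignalRecovery:
    def test_injected_signal_concentrates_in_masks(self):
        """High-amplitude signal inside Braak-like masks yields suprathreshold
        voxels covering >90% of the masks and mostly inside them."""
        rng = np.random.default_rng(8)
        score = rng.normal(10, 3, size=40)
        imgs, masks = ba.generate_images(
            score, shape=(18, 18, 18), amplitude=1.5, noise_sd=1.0,
            noise_fwhm_vox=2.0, seed=42,
        )
        tm = fit_voxelwise_glm(imgs, score)
        thr, supra = rft_threshold(tm, alpha=0.001)
        union = np.zeros_like(supra)
        for m in masks.values():
            union |= m
        rep = roi_overlap(supra, masks)
        assert all(rep.proportion(r) > 0.9 for r in masks)
        assert supra[union].mean() > 0.9
        assert supra[~union].mean() < 0.02

    def test_images_deterministic_under_seed(self):
        score = np.arange(12.0)
        a, _ = ba.generate_images(score, shape=(8, 8, 8), seed=5)
        b, _ = ba.generate_images(score, shape=(8, 8, 8), seed=5)
        np.testing.assert_array_equal(a.data, b.data)


class TestNiftiIO:
    def test_roundtrip_and_sidecar(self, tmp_path):
        import json

        import nibabel as nib

        rng = np.random.default_rng(9)
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        paths = []
        for i in range(12):
            p = tmp_path / f"s{i}.nii.gz"
            nib.save(nib.Nifti1Image(rng.standard_normal((6, 6, 6)), affine), p)
            paths.append(p)
        imgs = ba.voxelwise.load_images(paths)
        assert imgs.n_subjects == 12 and imgs.voxel_size == (2.0, 2.0, 2.0)
        tm = fit_voxelwise_glm(imgs, rng.standard_normal(12))
        ba.voxelwise.save_tmap(tm, tmp_path / "t.nii.gz", tmp_path / "t.json")
        back = nib.load(tmp_path / "t.nii.gz")
        np.testing.assert_allclose(back.get_fdata(), np.nan_to_num(tm.t), atol=1e-6)
        meta = json.loads((tmp_path / "t.json").read_text())
        assert meta["df"] == tm.df
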