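"""SUV normalization, SUVmax/SUVpeak extraction and recovery coefficients."""

import numpy as np
import pytest

import petharmony as ph
from petharmony.suv import measure_study, sphere_mean_map, suv_max, suv_peak
from conftest import sphere_phantom


def _grid(values, spacing=(1.0, 1.0, 1.0)):
    return ph.VoxelGrid(np.asarray(values, float), spacing)


class TestSuvScale:
    def test_unit_arithmetic_without_decay(self):
        meta = ph.StudyMeta(300.0, 75.0, 0.0, 0.0)
        vol = _grid(np.full((4, 4, 4), 5.0))
        vol.value_kind = "concentration"
        out = ph.suv_scale(vol, meta)
        np.testing.assert_allclose(out.values, 1.25)
        assert out.value_kind == "suv"

    def test_decay_correction_over_60_minutes(self):
        meta = ph.StudyMeta(300.0, 75.0, 0.0, 60.0)
        vol = _grid(np.full((2, 2, 2), 5.0))
        vol.value_kind = "concentration"
        out = ph.suv_scale(vol, meta)
        # decay factor 2^(-60/109.77) = 0.6847 -> SUV = 1.25 / 0.6847
        np.testing.assert_allclose(out.values, 1.25 / 2 ** (-60 / 109.77), rtol=1e-6)
        np.testing.assert_allclose(out.values, 1.826, atol=5e-4)

    def test_zero_concentration_gives_zero_suv(self):
        meta = ph.StudyMeta(300.0, 75.0)
        vol = _grid(np.zeros((3, 3, 3)))
        vol.value_kind = "concentration"
        assert ph.suv_scale(vol, meta).values.max() == 0.0

    def test_scaling_is_linear(self, rng):
        meta = ph.StudyMeta(250.0, 60.0, 0.0, 45.0)
        base = rng.random((5, 5, 5))
        a = _grid(base); a.value_kind = "concentration"
        b = _grid(2 * base); b.value_kind = "concentration"
        np.testing.assert_allclose(
            ph.suv_scale(b, meta).values, 2 * ph.suv_scale(a, meta).values
        )

    def test_invalid_meta_rejected(self):
        with pytest.raises(ValueError):
            ph.StudyMeta(-1.0, 75.0)
        with pytest.raises(ValueError):
            ph.StudyMeta(300.0, 0.0)
        with pytest.raises(ValueError):
            ph.StudyMeta(300.0, 75.0, 60.0, 30.0)

    def test_suv_volume_rejected(self):
        with pytest.raises(ValueError, match="concentration"):
            ph.suv_scale(_grid(np.ones((2, 2, 2))), ph.StudyMeta(300.0, 75.0))


class TestSuvMax:
    def test_uniform_volume(self):
        vol = _grid(np.full((6, 6, 6), 2.5))
        mask = ph.RegionMask("liver", np.ones((6, 6, 6), bool), 1.0)
        assert suv_max(vol, mask) == 2.5

    def test_single_hot_voxel(self):
        vals = np.ones((9, 9, 9))
        vals[4, 4, 4] = 7.3
        mask = ph.RegionMask("lesion", np.zeros((9, 9, 9), bool), 1.0, index=1)
        mask.values[3:6, 3:6, 3:6] = True
        assert suv_max(_grid(vals), mask) == 7.3

    def test_matches_exhaustive_scan_on_random_volumes(self, rng):
        for _ in range(5):
            vals = rng.random((10, 11, 12))
            msk = rng.random((10, 11, 12)) > 0.7
            if not msk.any():
                continue
            mask = ph.RegionMask("liver", msk, 1.0)
            brute = max(
                vals[i, j, k]
                for i in range(10) for j in range(11) for k in range(12)
                if msk[i, j, k]
            )
            assert suv_max(_grid(vals), mask) == brute

    def test_empty_mask_rejected(self):
        mask = ph.RegionMask("liver", np.zeros((4, 4, 4), bool), 1.0)
        with pytest.raises(ValueError, match="empty"):
            suv_max(_grid(np.ones((4, 4, 4))), mask)


def _brute_sphere_count(spacing, radius_mm):
    """Voxel centers within radius of a given center voxel, by enumeration."""
    count = 0
    for i in range(-10, 11):
        for j in range(-10, 11):
            for k in range(-10, 11):
                d2 = (i * spacing[0]) ** 2 + (j * spacing[1]) ** 2 + (k * spacing[2]) ** 2
                if d2 <= radius_mm**2:
                    count += 1
    return count


class TestSuvPeak:
    def test_uniform_volume_peak_equals_value(self):
        vol = _grid(np.full((12, 12, 12), 3.7), (2.73, 2.73, 2.79))
        mask = ph.RegionMask("liver", np.zeros((12, 12, 12), bool), (2.73, 2.73, 2.79))
        mask.values[5:7, 5:7, 5:7] = True
        assert suv_peak(vol, mask) == pytest.approx(3.7)

    def test_single_hot_voxel_diluted_by_sphere_average(self):
        spacing = (2.73, 2.73, 2.79)
        vals = np.zeros((15, 15, 15))
        vals[7, 7, 7] = 100.0
        vol = _grid(vals, spacing)
        mask = ph.RegionMask("lesion", vals > 0, spacing, index=1)
        radius = (3.0 * 1000.0 / (4.0 * np.pi)) ** (1 / 3)  # 1 mL sphere, 6.2 mm
        count = _brute_sphere_count(spacing, radius)
        assert suv_peak(vol, mask) == pytest.approx(100.0 / count)

    def test_peak_never_exceeds_max(self, rng):
        spacing = (2.0, 2.0, 2.0)
        for _ in range(5):
            vals = rng.random((14, 14, 14)) * 10
            msk = rng.random((14, 14, 14)) > 0.6
            vol = _grid(vals, spacing)
            mask = ph.RegionMask("lesion", msk, spacing, index=1)
            pk = suv_peak(vol, mask)
            if pk is not None:
                assert pk <= suv_max(vol, mask) + 1e-12

    def test_undefined_when_sphere_exceeds_volume_everywhere(self):
        vol = _grid(np.ones((3, 3, 3)), (2.0, 2.0, 2.0))
        mask = ph.RegionMask("lesion", np.ones((3, 3, 3), bool), (2.0, 2.0, 2.0), index=1)
        assert suv_peak(vol, mask) is None

    def test_monotone_under_pointwise_volume_ordering(self, rng):
        spacing = (2.5, 2.5, 2.5)
        base = rng.random((12, 12, 12))
        hi = base + rng.random((12, 12, 12))
        msk = np.zeros((12, 12, 12), bool)
        msk[4:8, 4:8, 4:8] = True
        mask = ph.RegionMask("lesion", msk, spacing, index=1)
        assert suv_peak(_grid(hi, spacing), mask) >= suv_peak(_grid(base, spacing), mask)


class TestMeasureStudy:
    def test_identical_volumes_give_identical_measurements(self, small_cohort):
        s = small_cohort[0]
        vols = {"a": s.volumes["qclear"], "b": s.volumes["qclear"]}
        out = measure_study(vols, s.masks, s.meta)
        for role in out["a"]:
            assert out["a"][role].suv_max == out["b"][role].suv_max
            assert out["a"][role].suv_peak == out["b"][role].suv_peak

    def test_eroded_liver_mean_recovers_true_uptake(self, small_cohort,
                                                    small_cohort_measurements):
        for s in small_cohort:
            m = small_cohort_measurements[s.study_id]["qclear"]["liver"]
            true = s.true_uptakes["liver"]
            # blur spill-in/out is avoided by erosion; noise averages out
            assert abs(m.suv_mean - true) <= (0.10 + 0.02) * true

    def test_organ_masks_eroded_but_lesions_not(self, small_cohort,
                                                small_cohort_measurements):
        s = small_cohort[0]
        meas = small_cohort_measurements[s.study_id]["qclear"]
        target = s.volumes["qclear"].geometry
        liver_regrid = ph.regrid(s.masks["liver"], target)
        lesion_regrid = ph.regrid(s.masks["lesion_1"], target)
        assert meas["liver"].n_voxels < liver_regrid.n_voxels
        assert meas["lesion_1"].n_voxels == lesion_regrid.n_voxels

    def test_larger_of_two_equal_uptake_lesions_is_hotter_under_blur(self):
        organs = [
            ph.Organ("lesion", "sphere", (-20, 0, 0), (10, 10, 10), 8.0, index=1),
            ph.Organ("lesion", "sphere", (20, 0, 0), (24, 24, 24), 8.0, index=2),
        ]
        spec = ph.PhantomSpec((80, 80, 60), organs, background_uptake=1.0)
        truth, masks = ph.build_phantom(spec)
        profile = ph.ReconProfile("p", psf_fwhm_mm=6.0, noise_cv=0.0,
                                  matrix=(32, 32), pixel_mm=2.5, slice_mm=1.875)
        recon = ph.simulate_reconstruction(truth, profile, seed=0)
        out = measure_study({"p": recon}, masks)
        assert out["p"]["lesion_2"].suv_max > out["p"]["lesion_1"].suv_max

    def test_eroded_to_empty_organ_is_flagged_without_values(self):
        vals = np.ones((12, 12, 12))
        vol = _grid(vals, (2.0, 2.0, 2.0))
        msk = np.zeros((12, 12, 12), bool)
        msk[5:7, 5:7, 5:7] = True  # too small to survive a 3-voxel erosion
        masks = {"blood_pool": ph.RegionMask("blood_pool", msk, (2.0, 2.0, 2.0))}
        out = measure_study({"p": vol}, masks)
        m = out["p"]["blood_pool"]
        assert "eroded_empty" in m.flags
        assert m.suv_max is None and m.suv_peak is None


class TestRecoveryCoefficients:
    def test_unblurred_truth_gives_unit_recovery(self):
        truth, masks = ph.build_phantom(sphere_phantom(diameter_mm=22.0))
        rc = ph.recovery_coefficients(truth, masks, {"lesion_1": 10.0})
        assert rc.loc[0, "rc_max"] == pytest.approx(1.0)
        assert rc.loc[0, "rc_mean"] == pytest.approx(1.0)

    def test_rc_max_matches_closed_form_for_large_sphere(self):
        truth, masks = ph.build_phantom(sphere_phantom(diameter_mm=37.0, fov=81.0))
        profile = ph.ReconProfile("p", psf_fwhm_mm=5.0, noise_cv=0.0,
                                  matrix=(32, 32), pixel_mm=2.0, slice_mm=2.0)
        recon = ph.simulate_reconstruction(truth, profile, seed=0, grid=truth.geometry)
        rc = ph.recovery_coefficients(recon, masks, {"lesion_1": 10.0})
        oracle = ph.blurred_sphere_center_value(18.5, 10.0, 1.0, 5.0) / 10.0
        assert rc.loc[0, "rc_max"] == pytest.approx(oracle, rel=0.01)

    def test_rc_monotone_in_sphere_size_and_fwhm(self):
        uptakes, rc_by_fwhm = {}, {}
        spec = ph.nema_iq_preset(voxel_mm=2.0)
        truth, masks = ph.build_phantom(spec)
        sphere_masks = {k: v for k, v in masks.items() if k.startswith("sphere")}
        uptakes = {k: 10.0 for k in sphere_masks}
        for fwhm in (5.0, 7.0):
            profile = ph.ReconProfile("p", psf_fwhm_mm=fwhm, noise_cv=0.0,
                                      matrix=(80, 80), pixel_mm=4.0, slice_mm=4.0)
            recon = ph.simulate_reconstruction(truth, profile, seed=0,
                                               grid=truth.geometry)
            rc = ph.recovery_coefficients(recon, sphere_masks, uptakes)
            rc = rc.set_index("region")
            ordered = [f"sphere_{i}" for i in range(1, 7)]  # diameters 10..37 mm
            vals = rc.loc[ordered, "rc_max"].to_numpy()
            assert np.all(np.diff(vals) >= 0)  # RC saturates at 1 when large
            assert vals[1] > vals[0]
            rc_by_fwhm[fwhm] = vals
        assert np.all(rc_by_fwhm[5.0] >= rc_by_fwhm[7.0])
        assert rc_by_fwhm[5.0][0] > rc_by_fwhm[7.0][0]

    def test_limits_table_compliance_flag(self):
        truth, masks = ph.build_phantom(sphere_phantom(diameter_mm=22.0))
        rc = ph.recovery_coefficients(
            truth, masks, {"lesion_1": 10.0}, limits={"lesion_1": (0.9, 1.1)}
        )
        assert bool(rc.loc[0, "within_limits"]) is True
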