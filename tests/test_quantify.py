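"""Tests for VOI statistics, calibration, and image-quality metrics."""

import numpy as np
import pytest

from hgpair import (
    VOI,
    ActivityPair,
    CalibrationFactor,
    ImagingModel,
    JaszczakSpec,
    PhantomSpec,
    PointSource,
    UniformCylinder,
    VoxelImage,
    apply_calibration,
    cnr,
    decay_series,
    derive_calibration,
    interrod_contrast,
    iq_metrics,
    nominal_concentration,
    rasterize,
    recovery_coefficient,
    rod_rois,
    simulate_acquisition,
    uniformity_analysis,
)

from conftest import UNIFORMITY_SCHEDULE


def _counts_to_conc_factor(img, model):
    return 1.0 / (img.voxel_volume_ml * model.counts_per_mbq_s * model.scan_time)


@pytest.fixture(scope="module")
def jaszczak():
    return JaszczakSpec()


@pytest.fixture(scope="module")
def jaszczak_truth(jaszczak):
    spec = PhantomSpec(jaszczak, ActivityPair(a_m=3.57, a_g=15.1))
    return rasterize(spec, (55, 140, 140), 0.2, "g")


class TestVoiStats:
    def test_uniform_region_has_zero_sd(self):
        img = VoxelImage(np.full((16, 16, 16), 4.2), 0.5, "MBq_per_mL")
        from hgpair import voi_stats

        mean, sd, n = voi_stats(img, VOI("sphere", (4.0, 4.0, 4.0), 2.0))
        assert mean == pytest.approx(4.2)
        assert sd == pytest.approx(0.0, abs=1e-12)
        assert n > 0

    def test_two_voxel_hand_arithmetic(self):
        img = VoxelImage(np.zeros((1, 1, 4)), 1.0, "MBq_per_mL")
        img.values[0, 0, 1] = 1.0
        img.values[0, 0, 2] = 3.0
        # circle centered between the two voxels picks exactly both
        voi = VOI("circle_in_slices", (0.0, 0.0, 1.5), 0.6, (0,))
        from hgpair import voi_stats

        mean, sd, n = voi_stats(img, voi)
        assert n == 2
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(1.0)  # population SD of {1, 3}

    def test_empty_selection_raises(self):
        from hgpair import voi_stats

        img = VoxelImage(np.ones((4, 4, 4)), 1.0, "counts")
        with pytest.raises(ValueError, match="no voxels"):
            voi_stats(img, VOI("sphere", (100.0, 100.0, 100.0), 0.5))

    def test_circle_on_uniformity_phantom_matches_enumeration(self):
        """Center-inclusion semantics: the ROI mean equals a direct
        enumeration over voxel centers inside the circle."""
        spec = PhantomSpec(UniformCylinder(7.0, 20.0), ActivityPair(0.832, 3.58))
        img = rasterize(spec, (56, 48, 48), 0.5, "g")
        voi = VOI("circle_in_slices", (0.0, 0.0, 0.0), 6.0, (28,))
        from hgpair import voi_stats

        mean, _, n = voi_stats(img, voi)
        y = img.axis_coords(1)
        x = img.axis_coords(2)
        inside = (y[:, None] ** 2 + x[None, :] ** 2) <= 36.0
        assert n == int(inside.sum())
        assert mean == pytest.approx(float(img.values[28][inside].mean()))


class TestCalibration:
    def test_simple_division(self):
        img = VoxelImage(np.full((8, 8, 8), 100.0), 0.5, "counts")
        cf = derive_calibration(img, VOI("sphere", (0, 0, 0), 1.0), 66.0)
        assert cf.scale == pytest.approx(0.66)

    def test_self_consistency(self):
        img = VoxelImage(np.full((8, 8, 8), 73.5), 0.5, "counts")
        voi = VOI("sphere", (0, 0, 0), 1.0)
        cf = derive_calibration(img, voi, 15.1)
        cal = apply_calibration(img, cf)
        from hgpair import voi_stats

        assert voi_stats(cal, voi)[0] == pytest.approx(15.1, rel=1e-14)

    def test_noisy_point_source_factor_close_to_noiseless(self):
        """Poisson noise moves the derived factor by under 2%."""
        spec = PhantomSpec(PointSource(volume=0.052), ActivityPair(15.7, 66.0))
        truth = rasterize(spec, (40, 40, 40), 0.4, "g")
        model0 = ImagingModel(psf_fwhm=0.8, counts_per_mbq_s=100.0, scan_time=600.0)
        noisy_model = ImagingModel(
            psf_fwhm=0.8, counts_per_mbq_s=100.0, scan_time=600.0,
            noise="poisson", seed=11,
        )
        voi = VOI("sphere", (0.0, 0.0, 0.0), 1.5)
        cf0 = derive_calibration(simulate_acquisition(truth, model0), voi, 66.0)
        cf1 = derive_calibration(simulate_acquisition(truth, noisy_model), voi, 66.0)
        assert cf1.scale == pytest.approx(cf0.scale, rel=0.02)

    def test_calibrated_uniform_phantom_recovers_nominal(self):
        spec = PhantomSpec(UniformCylinder(6.0, 16.0), ActivityPair(0.832, 3.58))
        truth = rasterize(spec, (48, 40, 40), 0.5, "g")
        model = ImagingModel(psf_fwhm=0.8)
        counts = simulate_acquisition(truth, model)
        cal = apply_calibration(
            counts, CalibrationFactor(_counts_to_conc_factor(truth, model))
        )
        from hgpair import voi_stats

        mean, _, _ = voi_stats(cal, VOI("circle_in_slices", (0, 0, 0), 4.0, (24,)))
        assert mean == pytest.approx(3.58, rel=0.01)

    def test_zero_mean_rejected(self):
        img = VoxelImage(np.zeros((4, 4, 4)), 1.0, "counts")
        with pytest.raises(ValueError):
            derive_calibration(img, VOI("sphere", (0, 0, 0), 1.0), 66.0)

    def test_apply_requires_counts(self):
        img = VoxelImage(np.ones((4, 4, 4)), 1.0, "MBq_per_mL")
        with pytest.raises(ValueError, match="counts"):
            apply_calibration(img, CalibrationFactor(1.0))


class TestNominalConcentration:
    def test_resolution_phantom_row(self):
        assert nominal_concentration(9.65, 0.637) == pytest.approx(15.1, abs=0.05)

    def test_zero_activity(self):
        assert nominal_concentration(0.0, 5.8) == 0.0

    def test_point_source_row_exact_quotient(self):
        # the exact quotient; the printed table rounds to 66.0
        assert nominal_concentration(3.440, 0.052) == pytest.approx(66.15, abs=0.01)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            nominal_concentration(1.0, 0.0)


class TestRodRois:
    def test_one_roi_per_rod_and_disjoint_interstitials(self, jaszczak, jaszczak_truth):
        rois = rod_rois(jaszczak, jaszczak_truth)
        rods = jaszczak.sector_rods()
        for d in jaszczak.rod_diameters:
            group = rois[d]
            assert len(group["rods"]) == len(rods[d])
            assert len(group["between"]) >= 1
            # rod and interstitial ROIs must not touch
            for a in group["rods"]:
                for b in group["between"]:
                    dist = np.hypot(
                        a.center[1] - b.center[1], a.center[2] - b.center[2]
                    )
                    assert dist >= a.radius + b.radius

    def test_rod_roi_mean_is_nominal_on_truth(self, jaszczak, jaszczak_truth):
        from hgpair import voi_stats

        rois = rod_rois(jaszczak, jaszczak_truth)
        for d, group in rois.items():
            for roi in group["rods"]:
                assert voi_stats(jaszczak_truth, roi)[0] == pytest.approx(
                    15.1, rel=1e-6
                )

    def test_erosion_too_aggressive_raises(self, jaszczak):
        img = VoxelImage.centered((30, 40, 40), 1.0)
        with pytest.raises(ValueError, match="erosion"):
            rod_rois(jaszczak, img)


class TestIqMetrics:
    def test_truth_contrast_is_100_and_rc_is_1(self, jaszczak, jaszczak_truth):
        contr = interrod_contrast(jaszczak_truth, rod_rois(jaszczak, jaszczak_truth))
        rc = recovery_coefficient(
            jaszczak_truth, rod_rois(jaszczak, jaszczak_truth), 15.1
        )
        for d in jaszczak.rod_diameters:
            assert contr[d] == pytest.approx(100.0, abs=1e-9)
            assert rc[d] == pytest.approx(1.0, abs=0.02)

    def test_hand_arithmetic_contrast(self):
        # M_rod = 3, M_btw = 1 -> C = 100*(3-1)/(3+1) = 50%
        assert 100.0 * (3 - 1) / (3 + 1) == 50.0  # definition sanity
        jz = JaszczakSpec(rod_diameters=(2.0,), bore_radius=9.0, rod_length=6.0)
        img = VoxelImage.centered((16, 48, 48), 0.4)
        img.units = "MBq_per_mL"
        rois = rod_rois(jz, img)
        for roi in rois[2.0]["rods"]:
            img.values[roi.mask(img)] = 3.0
        for roi in rois[2.0]["between"]:
            img.values[roi.mask(img)] = 1.0
        assert interrod_contrast(img, rois)[2.0] == pytest.approx(50.0)

    def test_contrast_monotone_in_psf_fwhm(self, jaszczak, jaszczak_truth):
        rois = rod_rois(jaszczak, jaszczak_truth)
        prev = None
        for fwhm in (0.0, 0.5, 1.0, 1.5, 2.0):
            model = ImagingModel(psf_fwhm=fwhm)
            counts = simulate_acquisition(jaszczak_truth, model)
            cal = apply_calibration(
                counts,
                CalibrationFactor(_counts_to_conc_factor(jaszczak_truth, model)),
            )
            contr = interrod_contrast(cal, rois)
            if prev is not None:
                for d in jaszczak.rod_diameters:
                    assert contr[d] <= prev[d] + 1e-9
            prev = contr

    def test_heavy_blur_flags_unresolvable(self, jaszczak, jaszczak_truth):
        model = ImagingModel(psf_fwhm=2.5)
        counts = simulate_acquisition(jaszczak_truth, model)
        cal = apply_calibration(
            counts, CalibrationFactor(_counts_to_conc_factor(jaszczak_truth, model))
        )
        metrics = iq_metrics(cal, jaszczak, true_conc=15.1)
        small = [m for m in metrics if m.diameter <= 1.1]
        assert all(m.contrast_pct < 20.0 and not m.resolvable for m in small)

    def test_rc_monotone_in_rod_diameter_under_blur(self, jaszczak, jaszczak_truth):
        model = ImagingModel(psf_fwhm=1.0)
        counts = simulate_acquisition(jaszczak_truth, model)
        cal = apply_calibration(
            counts, CalibrationFactor(_counts_to_conc_factor(jaszczak_truth, model))
        )
        rc = recovery_coefficient(cal, rod_rois(jaszczak, cal), 15.1)
        ordered = [rc[d] for d in sorted(rc)]
        assert all(a < b for a, b in zip(ordered, ordered[1:]))
        assert all(0.0 < v <= 1.0 + 1e-9 for v in ordered)

    def test_cnr_absent_for_exactly_identical_rods(self):
        # constant-valued rods have zero inter-rod variability, so the
        # CNR is reported absent rather than infinite
        jz = JaszczakSpec(rod_diameters=(2.0,), bore_radius=9.0, rod_length=6.0)
        img = VoxelImage.centered((16, 48, 48), 0.4)
        rois = rod_rois(jz, img)
        for roi in rois[2.0]["rods"]:
            img.values[roi.mask(img)] = 3.0
        assert cnr(img, rois)[2.0] is None

    def test_cnr_seeded_regression(self, jaszczak, jaszczak_truth):
        model = ImagingModel(psf_fwhm=0.8, noise="poisson", seed=5)
        counts = simulate_acquisition(jaszczak_truth, model)
        cal = apply_calibration(
            counts, CalibrationFactor(_counts_to_conc_factor(jaszczak_truth, model))
        )
        vals = cnr(cal, rod_rois(jaszczak, cal))
        assert all(v is not None and v > 0 for v in vals.values())
        # pinned-seed regression: largest rods are easiest to separate
        assert vals[1.7] > vals[0.85]


class TestUniformityAnalysis:
    def _calibrated_series(self, spec, k, channel):
        model = ImagingModel(psf_fwhm=0.8)
        frames = decay_series(
            spec, list(UNIFORMITY_SCHEDULE), model, k,
            grid_shape=(56, 44, 44), voxel_size=0.5,
        )
        factor = CalibrationFactor(
            1.0 / ((0.5**3 / 1000.0) * model.counts_per_mbq_s * model.scan_time)
        )
        return [(t, apply_calibration(ch[channel], factor)) for t, ch in frames]

    def test_metastable_channel_recovers_physical_half_life(self, k, uniformity_spec):
        series = self._calibrated_series(uniformity_spec, k, "m")
        res = uniformity_analysis(series)
        assert res["fit"].half_life == pytest.approx(23.8, rel=1e-6)

    def test_pure_ground_channel_recovers_physical_half_life(self, k):
        spec = PhantomSpec(UniformCylinder(7.0, 22.0), ActivityPair(0.0, 3.58))
        series = self._calibrated_series(spec, k, "g")
        res = uniformity_analysis(series)
        assert float(f"{res['fit'].half_life:.3g}") == 64.1

    def test_coupled_ground_series_decays_slower_than_physical(self, k, uniformity_spec):
        """Grow-in from the metastable state makes the apparent
        ground-state half-life exceed the physical 64.14 h."""
        series = self._calibrated_series(uniformity_spec, k, "g")
        res = uniformity_analysis(series)
        assert res["fit"].half_life > 64.14

    def test_slices_are_nonconsecutive(self, k, uniformity_spec):
        series = self._calibrated_series(uniformity_spec, k, "m")
        res = uniformity_analysis(series)
        s = sorted(res["slices"])
        assert len(s) == 5
        assert all(b - a >= 2 for a, b in zip(s, s[1:]))

    def test_short_series_rejected(self, k):
        img = VoxelImage(np.ones((8, 8, 8)), 1.0, "MBq_per_mL")
        with pytest.raises(ValueError, match="three"):
            uniformity_analysis([(0.0, img), (1.0, img)])

    def test_few_slices_warns_and_uses_available(self):
        img = VoxelImage(
            np.exp(np.zeros((4, 20, 20))), 1.0, "MBq_per_mL",
            origin=(-1.5, -9.5, -9.5),
        )
        series = [
            (t, VoxelImage(img.values * v, 1.0, "MBq_per_mL", img.origin))
            for t, v in [(0.0, 1.0), (10.0, 0.5), (20.0, 0.25)]
        ]
        with pytest.warns(UserWarning, match="eligible"):
            res = uniformity_analysis(series, roi_radius=5.0)
        assert res["fit"].half_life == pytest.approx(10.0, rel=1e-6)
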