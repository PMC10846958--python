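"""Ground-truth generators: curves, lognormal calibration, images,
grid pairs and coupled cohorts."""

import numpy as np
import pytest
from hypothesis import given, strategies as hst
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

import arterynano as an
from arterynano import synthetic as syn
from arterynano.collagen import RoiBox, roi_pixel_slices
from arterynano.coreg import Transform2D


class TestForceCurveGeneration:
    def test_final_force_matches_hertz_law(self, tip):
        curve = an.generate_force_curve(10.0, tip=tip, rng_or_seed=0)
        assert curve.force_nN[-1] == pytest.approx(an.hertz_force(1.0, 10.0, tip), rel=1e-9)

    def test_zero_force_at_and_before_contact_point(self, tip):
        curve = an.generate_force_curve(10.0, tip=tip, rng_or_seed=0)
        z0 = curve.truth["contact_point_um"]
        pre = curve.piezo_height_um <= z0
        assert pre.sum() > 20
        np.testing.assert_allclose(curve.force_nN[pre], 0.0, atol=1e-12)

    def test_doubling_ramp_depth_quadruples_final_force(self, tip):
        f1 = an.generate_force_curve(7.0, tip=tip, ramp=an.RampSpec(depth_um=0.5), rng_or_seed=0)
        f2 = an.generate_force_curve(7.0, tip=tip, ramp=an.RampSpec(depth_um=1.0), rng_or_seed=0)
        assert f2.force_nN[-1] == pytest.approx(4 * f1.force_nN[-1], rel=1e-9)

    def test_post_contact_follows_hertz_in_indentation_depth(self, tip):
        curve = an.generate_force_curve(4.9, tip=tip, rng_or_seed=1)
        z0 = curve.truth["contact_point_um"]
        d_um = curve.force_nN / (1000.0 * curve.spring_constant_N_per_m)
        delta = (curve.piezo_height_um - z0) - d_um
        post = delta > 0
        np.testing.assert_allclose(
            curve.force_nN[post], an.hertz_force(delta[post], 4.9, tip), rtol=1e-9
        )

    def test_precontact_region_carries_only_baseline_terms(self, tip):
        noise = an.NoiseModel(baseline_offset_nN=0.5, baseline_slope_nN_per_um=0.2)
        curve = an.generate_force_curve(10.0, tip=tip, noise=noise, rng_or_seed=2)
        z0 = curve.truth["contact_point_um"]
        pre = curve.piezo_height_um < z0
        baseline = 0.5 + 0.2 * curve.piezo_height_um[pre]
        np.testing.assert_allclose(curve.force_nN[pre], baseline, atol=1e-9)

    def test_seed_determinism_bit_for_bit(self):
        noise = an.NoiseModel(deflection_noise_sd_nN=0.1, contact_jitter_sd_um=0.1)
        a = an.generate_force_curve(5.0, noise=noise, rng_or_seed=42)
        b = an.generate_force_curve(5.0, noise=noise, rng_or_seed=42)
        assert np.array_equal(a.piezo_height_um, b.piezo_height_um)
        assert np.array_equal(a.deflection_nm, b.deflection_nm)

    def test_rejects_nonpositive_modulus_and_depth(self):
        with pytest.raises(ValueError):
            an.generate_force_curve(-1.0)
        with pytest.raises(ValueError):
            an.RampSpec(depth_um=0.0)


class TestLognormalCalibration:
    @given(
        median=hst.floats(0.5, 50.0),
        iqr_ratio=hst.floats(0.0, 3.0),
    )
    def test_analytic_parameters_reproduce_requested_quartiles(self, median, iqr_ratio):
        iqr = iqr_ratio * median
        mu, sigma = an.lognormal_from_median_iqr(median, iqr)
        z75 = 0.6744897501960817
        assert np.exp(mu) == pytest.approx(median, rel=1e-12)
        q1, q3 = np.exp(mu - sigma * z75), np.exp(mu + sigma * z75)
        assert q3 - q1 == pytest.approx(iqr, rel=1e-9, abs=1e-9)

    def test_iid_sample_median_matches_analytic_solution(self):
        group = syn.GroupParams("healthy_wall", 11.0, 8.6, n_rois=200)
        moduli = an.sample_group_moduli(group, rng_or_seed=3, method="iid")
        assert np.median(moduli) == pytest.approx(11.0, rel=0.05)

    def test_zero_iqr_gives_degenerate_constant_field(self):
        group = syn.GroupParams("uniform", 5.0, 0.0, n_rois=10)
        assert np.all(an.sample_group_moduli(group, rng_or_seed=0) == 5.0)

    def test_roi_dataset_counts(self):
        rois = an.generate_roi_dataset([syn.GroupParams("g", 10.0, 2.0, n_rois=4)], rng_or_seed=0)
        assert len(rois) == 4
        assert sum(len(r.curves) for r in rois) == 100


class TestPolarizedImages:
    @pytest.mark.parametrize("coverage", [0.0, 5.0, 35.0, 50.0, 75.0, 95.0, 100.0])
    def test_coverage_truth_matches_independent_pixel_count(self, coverage):
        box = RoiBox("r", 5.0, 5.0, 50.0)
        img, truth = an.generate_polarized_image((120, 120), 0.5, [(box, coverage)], rng_or_seed=7)
        rows, cols = roi_pixel_slices(box, 0.5, img.shape)
        bright_frac = 100.0 * np.count_nonzero(img[rows, cols] >= 75) / img[rows, cols].size
        assert bright_frac == pytest.approx(truth["r"], abs=1e-9)
        assert truth["r"] == pytest.approx(coverage, abs=0.5)

    def test_background_below_and_fibres_above_threshold(self):
        box = RoiBox("r", 5.0, 5.0, 50.0)
        img, _ = an.generate_polarized_image((120, 120), 0.5, [(box, 0.0)], rng_or_seed=8)
        assert img.max() < 75  # zero coverage: nothing bright anywhere in the ROI
        img, _ = an.generate_polarized_image((120, 120), 0.5, [(box, 100.0)], rng_or_seed=8)
        rows, cols = roi_pixel_slices(box, 0.5, img.shape)
        assert img[rows, cols].min() >= 75

    def test_invalid_coverage_rejected(self):
        box = RoiBox("r", 5.0, 5.0, 50.0)
        with pytest.raises(ValueError):
            an.generate_polarized_image((120, 120), 0.5, [(box, 101.0)], rng_or_seed=0)


class TestGridPairs:
    def test_identity_zero_noise_gives_identical_landmarks(self):
        pair = an.generate_grid_pair(Transform2D.identity(), rng_or_seed=0)
        np.testing.assert_array_equal(pair.landmarks.src_um, pair.landmarks.dst_um)

    def test_pure_translation_shifts_all_landmarks(self):
        t = Transform2D.similarity(translation_um=(10.0, 0.0))
        pair = an.generate_grid_pair(t, rng_or_seed=0)
        np.testing.assert_allclose(
            pair.landmarks.dst_um - pair.landmarks.src_um, [[10.0, 0.0]] * len(pair.landmarks)
        )

    def test_rotation_preserves_pairwise_distances(self):
        t = Transform2D.similarity(rotation_deg=5.0, translation_um=(200.0, 200.0))
        pair = an.generate_grid_pair(t, rng_or_seed=0)
        d_src = pdist(pair.landmarks.src_um)
        d_dst = pdist(pair.landmarks.dst_um)
        np.testing.assert_allclose(d_dst, d_src, rtol=1e-9)

    def test_singular_transform_rejected(self):
        with pytest.raises(Exception):
            Transform2D(np.array([[1.0, 0, 0], [1.0, 0, 0], [0, 0, 1.0]]))


class TestCoregisteredCohort:
    def _group(self, n):
        return syn.GroupParams("healthy_wall", 11.0, 8.6, n_rois=n, median_density_pct=32.4)

    def test_perfect_coupling_gives_unit_correlation(self):
        pairs = an.generate_coregistered_cohort([self._group(30)], rho_true=1.0, rng_or_seed=0)
        r = pearsonr([p.log_E for p in pairs], [p.density_pct for p in pairs]).statistic
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_zero_coupling_gives_near_zero_correlation(self):
        pairs = an.generate_coregistered_cohort([self._group(10000)], rho_true=0.0, rng_or_seed=1)
        r = pearsonr([p.log_E for p in pairs], [p.density_pct for p in pairs]).statistic
        assert abs(r) < 0.03

    def test_cohort_size_honoured(self):
        groups = [self._group(43), syn.GroupParams("cap", 4.9, 2.9, 24, median_density_pct=16.2)]
        pairs = an.generate_coregistered_cohort(groups, rho_true=0.6, rng_or_seed=2)
        assert len(pairs) == 67

    def test_out_of_range_correlation_rejected(self):
        with pytest.raises(ValueError):
            an.generate_coregistered_cohort([self._group(5)], rho_true=1.5, rng_or_seed=0)
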