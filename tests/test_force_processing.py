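"""Curve processing chain: I/O, baseline, contact point, Hertz fit, QC,
ROI aggregation, and recovery of generator ground truth."""

import numpy as np
import pytest

import arterynano as an
from arterynano import force as fp
from arterynano.errors import ContactNotFoundError, FormatError, ProcessingError


def _clean_curve(true_E=10.0, tip=an.TipGeometry(), seed=0, **kw):
    return an.generate_force_curve(true_E, tip=tip, rng_or_seed=seed, **kw)


class TestCurveIO:
    def test_round_trip(self, tmp_path, tip):
        curve = _clean_curve(roi_id="roi_7")
        path = an.write_force_curve(curve, tmp_path / "c.tsv")
        back = an.read_force_curve(path)
        assert back.n_samples == curve.n_samples
        assert back.roi_id == "roi_7"
        assert back.spring_constant_N_per_m == pytest.approx(0.6)
        np.testing.assert_allclose(back.deflection_nm, curve.deflection_nm)

    def test_shuffled_heights_raise_non_monotone(self, tmp_path):
        curve = _clean_curve()
        path = an.write_force_curve(curve, tmp_path / "c.tsv")
        import pandas as pd

        tab = pd.read_csv(path, sep="\t").sample(frac=1, random_state=0)
        tab.to_csv(path, sep="\t", index=False)
        with pytest.raises(FormatError, match="non-monotone"):
            an.read_force_curve(path)

    def test_missing_spring_constant_raises(self, tmp_path):
        curve = _clean_curve()
        path = an.write_force_curve(curve, tmp_path / "c.tsv")
        path.with_suffix(".json").write_text("{}")
        with pytest.raises(FormatError, match="spring_constant"):
            an.read_force_curve(path)

    def test_unit_normalization_leaves_fit_invariant(self, tmp_path, tip):
        """Heights in nm / deflections in um must fit to the same modulus."""
        import json

        import pandas as pd

        curve = _clean_curve()
        ref = an.process_curve(curve, tip)
        pd.DataFrame(
            {
                "piezo_height_nm": curve.piezo_height_um * 1000.0,
                "deflection_um": curve.deflection_nm / 1000.0,
            }
        ).to_csv(tmp_path / "c.tsv", sep="\t", index=False)
        (tmp_path / "c.json").write_text(json.dumps({"spring_constant_N_per_m": 0.6}))
        alt = an.process_curve(an.read_force_curve(tmp_path / "c.tsv"), tip)
        assert alt.E_kPa == pytest.approx(ref.E_kPa, rel=1e-9)


class TestBaseline:
    def test_offset_and_tilt_removed(self):
        noise = an.NoiseModel(baseline_offset_nN=5.0, baseline_slope_nN_per_um=0.5)
        curve = _clean_curve(noise=noise)
        corrected = an.correct_baseline(curve)
        z0 = curve.truth["contact_point_um"]
        window = curve.piezo_height_um < 0.9 * z0
        pre = corrected.force_nN[window]
        assert abs(pre.mean()) < 1e-9
        slope = np.polyfit(curve.piezo_height_um[window], pre, 1)[0]
        assert abs(slope) < 1e-6

    def test_flat_curve_unchanged(self):
        curve = _clean_curve()
        corrected = an.correct_baseline(curve)
        np.testing.assert_allclose(corrected.deflection_nm, curve.deflection_nm, atol=1e-9)

    def test_too_few_samples_raise(self):
        curve = _clean_curve()
        with pytest.raises(ProcessingError):
            an.correct_baseline(curve, fit_fraction=0.05)


class TestContactPoint:
    def test_zero_noise_estimate_within_one_sample_spacing(self):
        curve = _clean_curve(seed=3)
        z0 = an.detect_contact_point(an.correct_baseline(curve))
        spacing = np.diff(curve.piezo_height_um).mean()
        assert abs(z0 - curve.truth["contact_point_um"]) < spacing

    def test_all_zero_curve_flagged_no_contact(self):
        curve = fp.ForceCurve(np.linspace(0, 2, 100), np.zeros(100), 0.6)
        with pytest.raises(ContactNotFoundError):
            an.detect_contact_point(curve)

    def test_contact_at_first_sample(self, tip):
        z = np.linspace(0.0, 1.0, 120)
        force = an.hertz_force(z, 8.0, tip)  # contact exactly at z[0]
        curve = fp.ForceCurve(z, force / 0.6, 0.6)
        z0 = an.detect_contact_point(curve)
        assert z0 <= z[0] + (z[1] - z[0])


class TestIndentation:
    def test_rigid_substrate_gives_zero_depth(self):
        z = np.linspace(0.0, 2.0, 100)
        z0 = 1.0
        deflection_um = np.clip(z - z0, 0, None)  # all travel into deflection
        curve = fp.ForceCurve(z, deflection_um * 1000.0, 0.6)
        delta, _ = an.compute_indentation(curve, z0)
        np.testing.assert_allclose(delta, 0.0, atol=1e-12)

    def test_force_is_spring_constant_times_deflection(self):
        curve = fp.ForceCurve(np.linspace(0, 1, 60), np.full(60, 10.0), 0.6)
        np.testing.assert_allclose(curve.force_nN, 6.0)

    def test_zero_noise_series_satisfies_generating_law(self, tip):
        curve = _clean_curve(true_E=4.9, tip=tip, seed=5)
        delta, force = an.compute_indentation(curve, curve.truth["contact_point_um"])
        np.testing.assert_allclose(force, an.hertz_force(delta, 4.9, tip), rtol=1e-9)


class TestHertzFit:
    def test_scaling_force_scales_modulus(self, tip):
        delta = np.linspace(0, 1, 50)
        force = an.hertz_force(delta, 10.0, tip)
        e1 = an.fit_hertz(delta, force, tip).E_kPa
        e2 = an.fit_hertz(delta, 2 * force, tip).E_kPa
        assert e2 == pytest.approx(2 * e1, rel=1e-12)

    def test_poisson_factor_rescales_modulus(self):
        delta = np.linspace(0, 1, 50)
        force = an.hertz_force(delta, 10.0, an.TipGeometry(poisson_ratio=0.0))
        e0 = an.fit_hertz(delta, force, an.TipGeometry(poisson_ratio=0.0)).E_kPa
        e5 = an.fit_hertz(delta, force, an.TipGeometry(poisson_ratio=0.5)).E_kPa
        assert e5 == pytest.approx(0.75 * e0, rel=1e-12)

    def test_insufficient_depth_raises(self, tip):
        with pytest.raises(ProcessingError):
            an.fit_hertz(np.zeros(50), np.zeros(50), tip)


class TestQc:
    def _fit(self, **kw):
        base = dict(E_kPa=10.0, contact_point_um=1.0, max_indentation_um=1.5, rms_residual_nN=0.0)
        base.update(kw)
        return fp.HertzFit(**base)

    def test_depth_rule_rejects_beyond_tenth_of_thickness(self):
        curve = _clean_curve()  # thickness 20 um -> limit 2.0 um
        verdict = an.qc_filter(self._fit(max_indentation_um=2.5), curve)
        assert not verdict.accepted and "depth" in verdict.reason
        assert an.qc_filter(self._fit(max_indentation_um=1.5), curve).accepted

    def test_relative_rms_cap(self):
        curve = _clean_curve()
        peak = np.max(curve.force_nN)
        verdict = an.qc_filter(self._fit(rms_residual_nN=0.3 * peak), curve)
        assert not verdict.accepted and verdict.reason == "poor_fit"

    def test_discard_accounting_totals(self, tip, study_noise):
        rng = np.random.default_rng(11)
        fits = [
            an.process_curve(an.generate_force_curve(3.0, tip=tip, noise=study_noise, rng_or_seed=rng), tip)
            for _ in range(25)
        ]
        rec = an.aggregate_roi(fits, "g", roi_id="r0")
        assert rec.n_accepted + rec.n_rejected == 25


class TestAggregate:
    def test_median_of_25(self):
        fits = [fp.HertzFit(e, 0, 0, 0) for e in range(1, 26)]
        assert an.aggregate_roi(fits, "g").median_E_kPa == 13.0

    def test_even_count_uses_mean_of_central_pair(self):
        fits = [fp.HertzFit(e, 0, 0, 0) for e in range(1, 25)]
        assert an.aggregate_roi(fits, "g").median_E_kPa == 12.5

    def test_all_rejected_roi_unusable(self):
        fits = [fp.HertzFit(np.nan, 0, 0, 0, accepted=False, reason="no_contact") for _ in range(25)]
        rec = an.aggregate_roi(fits, "g")
        assert not rec.usable and np.isnan(rec.median_E_kPa)


class TestRecovery:
    def test_zero_noise_chain_recovers_truth_exactly(self, tip):
        curve = _clean_curve(true_E=11.0, tip=tip, seed=9)
        fit = an.process_curve(curve, tip)
        assert fit.accepted
        assert abs(fit.E_kPa - 11.0) / 11.0 < 1e-6
        spacing = np.diff(curve.piezo_height_um).mean()
        assert abs(fit.contact_point_um - curve.truth["contact_point_um"]) < spacing

    def test_noise_robustness_median_relative_error_under_5pct(self, tip, study_noise):
        rng = np.random.default_rng(21)
        errors = []
        for _ in range(500):
            curve = an.generate_force_curve(4.9, tip=tip, noise=study_noise, rng_or_seed=rng)
            fit = an.process_curve(curve, tip)
            if fit.accepted:
                errors.append(abs(fit.E_kPa - 4.9) / 4.9)
        assert len(errors) > 450
        assert np.median(errors) < 0.05

    def test_fitted_modulus_monotone_in_true_modulus(self, tip):
        """Same noise realization, increasing stiffness -> increasing fit."""
        fitted = []
        for true_e in [2.0, 5.0, 11.0, 30.0]:
            curve = an.generate_force_curve(
                true_e, tip=tip, noise=an.NoiseModel(deflection_noise_sd_nN=0.05), rng_or_seed=77
            )
            fitted.append(an.process_curve(curve, tip).E_kPa)
        assert np.all(np.diff(fitted) > 0)
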