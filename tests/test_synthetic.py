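"""Synthetic-data generators: determinism, noise calibration, and
round-trip agreement between generated landmarks and the analysis chain."""

import numpy as np
import pytest

from cardiosense import (
    AdhesionCourseParams,
    DAY_PROFILES,
    DrugEffectKeyframes,
    analyze_trace,
    apply_drug_model,
    circuit_impedance,
    curve_from_experiment,
    default_frequency_grid,
    default_keyframes,
    normalized_ci_course,
    normalized_resistance_course,
    recovery_profile,
    simulate_adhesion_course,
    simulate_beating_trace,
    simulate_spectrum,
)


class TestSpectrumGenerator:
    def test_zero_noise_equals_forward_model(self, ref_params):
        sim = simulate_spectrum(ref_params, noise_rel=0.0, seed=3)
        model = circuit_impedance(ref_params, default_frequency_grid())
        assert np.array_equal(sim.z, model.z)

    def test_seeded_determinism(self, ref_params):
        a = simulate_spectrum(ref_params, noise_rel=0.01, seed=5)
        b = simulate_spectrum(ref_params, noise_rel=0.01, seed=5)
        c = simulate_spectrum(ref_params, noise_rel=0.01, seed=6)
        assert np.array_equal(a.z, b.z)
        assert not np.array_equal(a.z, c.z)

    def test_noise_level_calibrated(self, ref_params):
        """Empirical relative perturbation sd matches noise_rel within 10%."""
        grid = np.logspace(2, np.log10(2e6), 1000)
        model = circuit_impedance(ref_params, grid)
        sim = simulate_spectrum(ref_params, frequencies=grid, noise_rel=0.01, seed=1)
        rel = (sim.z - model.z).real / np.abs(model.z)
        assert np.std(rel) == pytest.approx(0.01, rel=0.1)

    def test_negative_noise_rejected(self, ref_params):
        with pytest.raises(ValueError):
            simulate_spectrum(ref_params, noise_rel=-0.01)


class TestAdhesionCourse:
    def test_landmarks_noise_off(self):
        """100% at 0 h, 118% at 36 h, ~113% at 72 h."""
        rows = normalized_resistance_course(simulate_adhesion_course())
        by_t = {t: v for t, v in rows}
        assert by_t[0.0] == 100.0
        assert by_t[36.0] == pytest.approx(118.0, abs=0.5)
        assert by_t[72.0] == pytest.approx(113.0, abs=0.5)

    def test_sampling_every_3h_over_72h(self):
        course = simulate_adhesion_course()
        assert course.times_h[0] == 0.0 and course.times_h[-1] == 72.0
        assert np.allclose(np.diff(course.times_h), 3.0)

    def test_determinism_with_noise(self):
        p = AdhesionCourseParams(noise_rel=0.02)
        a = simulate_adhesion_course(p, seed=9)
        b = simulate_adhesion_course(p, seed=9)
        assert np.array_equal(a.z_mag, b.z_mag)


class TestBeatingTraces:
    def test_day_profile_amplitude_ratios(self):
        """Day 7 / day 4 amplitude ratio is exactly 4.00."""
        amp = {d: DAY_PROFILES[d].amplitude for d in (4, 5, 6, 7)}
        ratios = [100 * amp[d] / amp[4] for d in (4, 5, 6, 7)]
        assert ratios == pytest.approx([100.0, 166.4, 243.56, 400.0], abs=0.01)

    def test_frequency_falls_and_duration_widens_with_day(self):
        freqs = [DAY_PROFILES[d].frequency for d in (4, 5, 6, 7)]
        durs = [DAY_PROFILES[d].duration for d in (4, 5, 6, 7)]
        assert np.all(np.diff(freqs) < 0) and np.all(np.diff(durs) > 0)

    def test_no_jitter_trace_is_exactly_periodic(self):
        trace = simulate_beating_trace(day=4, noise_sd=0.0, jitter_cv=0.0)
        table = analyze_trace(trace)[0]
        intervals = np.diff(table["peak_index"].to_numpy())
        # snapped to the sample grid: intervals vary by at most 1 sample
        assert intervals.max() - intervals.min() <= 1

    def test_detected_rate_matches_nominal(self):
        """Mean detected rate over 100 seeds within 2% of nominal."""
        rates = [
            analyze_trace(
                simulate_beating_trace(day=7, noise_sd=50e-9, jitter_cv=0.02, seed=s)
            )[1].beating_frequency
            for s in range(100)
        ]
        assert np.mean(rates) == pytest.approx(1.8, rel=0.02)

    def test_determinism(self):
        a = simulate_beating_trace(day=6, noise_sd=50e-9, jitter_cv=0.05, seed=2)
        b = simulate_beating_trace(day=6, noise_sd=50e-9, jitter_cv=0.05, seed=2)
        assert np.array_equal(a.samples, b.samples)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_beating_trace(amplitude=-1e-6, frequency=1.0, beat_duration=0.25)
        with pytest.raises(ValueError):
            simulate_beating_trace(amplitude=1e-6, frequency=1.0, beat_duration=0.25,
                                   sampling_rate=100.0)


class TestDrugModel:
    def test_verapamil_300_force_anchors(self):
        """Analyzed force hits 45% at +12 h and 51% at +24 h (noise off)."""
        exp = apply_drug_model("verapamil", 300.0, [12.0, 24.0], seed=1)
        curve = curve_from_experiment(exp)
        assert curve.force_pct[1] == pytest.approx(45.0, abs=1.0)
        assert curve.force_pct[2] == pytest.approx(51.0, abs=1.0)

    def test_e4031_ci_anchor_and_no_recovery(self):
        exp = apply_drug_model("e4031", 10.0, [4, 8, 12, 16, 20, 24], seed=1)
        curve = curve_from_experiment(exp)
        assert curve.ci_pct[-1] == pytest.approx(72.0, abs=1.0)
        assert not recovery_profile(curve.times_h, curve.ci_pct).recovered

    def test_verapamil_1000_ci_recovers(self):
        exp = apply_drug_model("verapamil", 1000.0, [4, 8, 12, 16, 20, 24], seed=1)
        curve = curve_from_experiment(exp)
        prof = recovery_profile(curve.times_h, curve.ci_pct)
        assert prof.minimum_pct == pytest.approx(65.0, abs=1.0)
        assert prof.time_of_minimum_h == 12.0
        assert prof.value_at_horizon_pct == pytest.approx(75.0, abs=1.0)
        assert prof.recovered

    def test_all_packaged_anchors_round_trip(self):
        """Generator -> analysis reproduces every calibrated anchor
        within +-1 percentage point with noise off."""
        for drug in ("verapamil", "e4031"):
            kf = default_keyframes(drug)
            for dose in kf.doses:
                times = sorted(
                    {t for t, _ in kf.force[dose] if t > 0}
                    | {t for t, _ in kf.ci[dose] if t > 0}
                )
                exp = apply_drug_model(drug, dose, times, seed=0, jitter_cv=0.0)
                curve = curve_from_experiment(exp)
                by_t_force = dict(zip(curve.times_h, curve.force_pct))
                by_t_ci = dict(zip(curve.times_h, curve.ci_pct))
                for t, pct in kf.force[dose]:
                    assert by_t_force[t] == pytest.approx(pct, abs=1.0), (drug, dose, t)
                for t, pct in kf.ci[dose]:
                    assert by_t_ci[t] == pytest.approx(pct, abs=1.0), (drug, dose, t)

    def test_e4031_30_irregularity_and_widening(self):
        """Interval CV and beat duration both rise by +12 h at 30 nM."""
        exp = apply_drug_model("e4031", 30.0, [12.0, 24.0], seed=3)
        pre = analyze_trace(exp.traces[0.0])[1]
        mid = analyze_trace(exp.traces[12.0])[1]
        assert mid.interval_cv > pre.interval_cv
        assert mid.mean_duration > pre.mean_duration

    def test_verapamil_minimum_force_monotone_in_dose(self):
        """Packaged calibration: stronger dose, deeper force suppression."""
        minima = []
        for dose in (150.0, 300.0, 500.0, 1000.0):
            exp = apply_drug_model("verapamil", dose, [4, 8, 12, 16, 20, 24], seed=0,
                                   jitter_cv=0.0)
            curve = curve_from_experiment(exp)
            minima.append(curve.force_pct.min())
        assert np.all(np.diff(minima) <= 0)

    def test_null_keyframes_match_predrug_generator(self):
        null = DrugEffectKeyframes(
            drug="sham",
            force={100.0: [(0.0, 100.0), (24.0, 100.0)]},
            ci={100.0: [(0.0, 100.0), (24.0, 100.0)]},
        )
        exp = apply_drug_model("sham", 100.0, [12.0], keyframes=null, seed=4)
        curve = curve_from_experiment(exp)
        assert np.allclose(curve.force_pct, 100.0, atol=0.2)
        assert np.allclose(curve.ci_pct, 100.0, atol=1e-6)

    def test_timepoint_beyond_keyframes_rejected(self):
        with pytest.raises(ValueError):
            apply_drug_model("verapamil", 300.0, [30.0], seed=0)

    def test_uncalibrated_dose_interpolated_and_flagged(self):
        exp = apply_drug_model("e4031", 15.0, [12.0, 24.0], seed=0)
        assert exp.interpolated_dose
        curve = curve_from_experiment(exp)
        # between the 10 and 20 nM endpoints
        assert 66.5 < curve.ci_pct[-1] < 72.0

    def test_keyframe_validation(self):
        with pytest.raises(ValueError):
            DrugEffectKeyframes(drug="bad", force={1.0: [(0.0, 90.0), (12.0, 50.0)]},
                                ci={1.0: [(0.0, 100.0), (12.0, 80.0)]})


class TestChannelIndependence:
    def test_impedance_unaffected_by_displacement_channel(self):
        """Perturbing the displacement channel leaves the impedance
        outputs bit-identical (the channels are strain-independent)."""
        exp_a = apply_drug_model("verapamil", 300.0, [12.0, 24.0], seed=1)
        exp_b = apply_drug_model("verapamil", 300.0, [12.0, 24.0], seed=1,
                                 noise_sd=200e-9, jitter_cv=0.3)
        assert np.array_equal(exp_a.course.z_mag, exp_b.course.z_mag)
        assert np.array_equal(exp_a.course.z_real, exp_b.course.z_real)
        for t in exp_a.spectra:
            assert np.array_equal(exp_a.spectra[t].z, exp_b.spectra[t].z)
        # and the displacement channel ignores the impedance noise knob
        exp_c = apply_drug_model("verapamil", 300.0, [12.0, 24.0], seed=1,
                                 noise_rel=0.05)
        for t in exp_a.traces:
            assert np.array_equal(exp_a.traces[t].samples, exp_c.traces[t].samples)
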