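"""Simulator ground truth: RR process, waveform templates, cohort generator."""

import numpy as np
import pytest
from scipy.stats import norm

from tbivitals.modeling import auroc
from tbivitals.signal_processing import detect_ppg_pulses, detect_r_peaks
from tbivitals.synthetic import (
    CohortGenParams,
    MorphParams,
    RRGenParams,
    ecg_fiducial_truth,
    inject_artifacts,
    ppg_fiducial_truth,
    simulate_binormal_scores,
    simulate_cohort,
    simulate_rr_series,
    synthesize_ecg,
    synthesize_ppg,
)
from tbivitals.types import GenerationError, ParameterError

FS = 240.0


class TestRRSeries:
    def test_zero_variance_gives_constant_intervals(self):
        _, rr = simulate_rr_series(RRGenParams(mean_rr=800, sdnn_target=0, n_beats=100))
        assert np.all(rr == 800.0)

    def test_sdnn_target_is_hit(self):
        _, rr = simulate_rr_series(RRGenParams(mean_rr=800, sdnn_target=50, n_beats=5000, seed=1))
        assert 45.0 <= rr.std(ddof=1) <= 55.0
        assert np.all(rr > 0)

    def test_rmssd_target_is_approximated(self):
        _, rr = simulate_rr_series(
            RRGenParams(mean_rr=800, sdnn_target=50, rmssd_target=35, n_beats=5000, seed=4)
        )
        rmssd = np.sqrt(np.mean(np.diff(rr) ** 2))
        assert abs(rmssd - 35.0) < 7.0

    def test_determinism(self):
        p = RRGenParams(mean_rr=750, sdnn_target=40, n_beats=500, seed=11)
        bt1, rr1 = simulate_rr_series(p)
        bt2, rr2 = simulate_rr_series(p)
        np.testing.assert_array_equal(rr1, rr2)
        np.testing.assert_array_equal(bt1, bt2)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(mean_rr=0), dict(sdnn_target=-1), dict(n_beats=1), dict(respiratory_mod_freq=0)],
    )
    def test_invalid_params_raise(self, kwargs):
        with pytest.raises(ParameterError):
            RRGenParams(**kwargs)


class TestECGSynthesis:
    def test_r_peaks_recoverable_at_ground_truth(self, beat_times_10, morph):
        record = synthesize_ecg(beat_times_10, morph, FS, noise_sd=0.0)
        peaks = detect_r_peaks(record)
        truth = ecg_fiducial_truth(beat_times_10, morph, FS)["r"]
        assert peaks.size == 10
        assert np.max(np.abs(peaks - truth)) <= 1

    def test_qr_rising_amplitude_matches_template(self, beat_times_10):
        morph = MorphParams(q_depth=0.2, r_amp=1.0)
        record = synthesize_ecg(beat_times_10, morph, FS, noise_sd=0.0)
        truth = ecg_fiducial_truth(beat_times_10, morph, FS)
        rise = record.samples[truth["r"]] - record.samples[truth["q"]]
        assert np.allclose(rise, morph.q_depth + morph.r_amp, rtol=0.05)

    def test_empty_beat_times_give_empty_record(self, morph):
        record = synthesize_ecg(np.array([]), morph, FS)
        assert len(record) == 0

    def test_overlapping_complexes_raise(self, morph):
        with pytest.raises(GenerationError):
            synthesize_ecg(np.array([0.5, 0.55]), morph, FS)

    def test_determinism_with_noise(self, beat_times_10, morph):
        a = synthesize_ecg(beat_times_10, morph, FS, noise_sd=0.05, seed=3)
        b = synthesize_ecg(beat_times_10, morph, FS, noise_sd=0.05, seed=3)
        np.testing.assert_array_equal(a.samples, b.samples)


class TestPPGSynthesis:
    def test_notch_at_declared_delay(self, beat_times_10):
        from tbivitals.ppg_features import detect_dicrotic_notch

        morph = MorphParams(notch_delay_frac=0.45, notch_depth_frac=0.15)
        record = synthesize_ppg(beat_times_10, morph, FS, noise_sd=0.0)
        ann = detect_ppg_pulses(record)
        notch = detect_dicrotic_notch(record, ann)
        truth = ppg_fiducial_truth(beat_times_10, morph, FS)
        det = notch["notch_index"].to_numpy()
        present = det >= 0
        assert present.mean() >= 0.95
        # notch sits notch_delay_frac * period = 360 ms after the pulse foot
        assert np.max(np.abs(det[present] - truth["notch"][: det.size][present])) <= 2

    def test_no_notch_when_depth_zero(self, beat_times_10):
        from tbivitals.ppg_features import detect_dicrotic_notch

        morph = MorphParams(notch_depth_frac=0.0)
        record = synthesize_ppg(beat_times_10, morph, FS, noise_sd=0.0)
        notch = detect_dicrotic_notch(record, detect_ppg_pulses(record))
        assert (notch["notch_index"].to_numpy() < 0).mean() >= 0.95

    def test_peak_to_peak_intervals_match_construction(self, beat_times_10, morph):
        record = synthesize_ppg(beat_times_10, morph, FS, noise_sd=0.0)
        ann = detect_ppg_pulses(record)
        pp = np.diff(ann.fiducials["peak"])
        assert pp.size == 9
        assert np.max(np.abs(pp - 0.8 * FS)) <= 1

    def test_one_peak_one_foot_per_pulse(self, beat_times_10, morph):
        record = synthesize_ppg(beat_times_10, morph, FS, noise_sd=0.0)
        ann = detect_ppg_pulses(record)
        truth = ppg_fiducial_truth(beat_times_10, morph, FS)
        assert ann.fiducials["peak"].size == 10
        np.testing.assert_allclose(ann.fiducials["peak"], truth["peak"], atol=1)
        np.testing.assert_allclose(ann.fiducials["foot"], truth["foot"], atol=1)

    def test_notch_must_follow_systolic_peak(self):
        with pytest.raises(ParameterError):
            MorphParams(ppg_rise_frac=0.5, notch_delay_frac=0.4, notch_depth_frac=0.2)


class TestArtifacts:
    def test_dropout_flatlines_exact_span(self, morph):
        record = synthesize_ecg(0.5 + np.arange(30) * 0.8, morph, FS)
        out = inject_artifacts(record, "dropout", {"start": 10.0, "duration": 2.0})
        i0, i1 = int(10 * FS), int(12 * FS)
        assert np.all(out.samples[i0:i1] == out.samples[i0])
        np.testing.assert_array_equal(out.samples[:i0], record.samples[:i0])
        np.testing.assert_array_equal(out.samples[i1:], record.samples[i1:])

    def test_spike_changes_exactly_one_sample(self, morph):
        record = synthesize_ecg(0.5 + np.arange(5) * 0.8, morph, FS)
        out = inject_artifacts(record, "spike", {"time": 2.0, "amplitude": 5.0})
        assert int((out.samples != record.samples).sum()) == 1

    def test_span_outside_record_raises(self, morph):
        record = synthesize_ecg(0.5 + np.arange(5) * 0.8, morph, FS)
        with pytest.raises(ParameterError):
            inject_artifacts(record, "dropout", {"start": record.duration - 1, "duration": 5.0})

    def test_determinism(self, morph):
        record = synthesize_ecg(0.5 + np.arange(5) * 0.8, morph, FS)
        spec = {"start": 1.0, "duration": 0.5, "freq": 0.3, "amplitude": 0.2}
        a = inject_artifacts(record, "baseline_wander", spec, seed=9)
        b = inject_artifacts(record, "baseline_wander", spec, seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)


class TestCohortGenerator:
    def test_no_signal_gives_half_auroc(self):
        feats, _ = simulate_cohort(
            CohortGenParams(n_patients=100, nd_prevalence=0.2, true_coefficients={}), ["f0"]
        )
        assert feats.attrs["analytic_auroc"] == 0.5

    def test_binormal_closed_form(self):
        # separation d' = 1.19 -> AUROC = Phi(d'/sqrt(2)) ~ 0.80
        assert abs(norm.cdf(1.19 / np.sqrt(2)) - 0.80) < 1e-3
        scores, labels = simulate_binormal_scores(10**6, auroc=0.80, prevalence=0.5, seed=2)
        assert abs(auroc(scores, labels) - 0.80) < 0.005

    def test_realized_prevalence(self):
        _, cohort = simulate_cohort(
            CohortGenParams(n_patients=2000, nd_prevalence=0.17, true_coefficients={"f0": 1.0}, seed=7),
            ["f0", "f1"],
        )
        assert 0.12 <= cohort["nd"].mean() <= 0.22

    def test_analytic_auroc_matches_empirical_generating_score(self):
        feats, cohort = simulate_cohort(
            CohortGenParams(n_patients=10**5, nd_prevalence=0.17, true_coefficients={"f0": 1.2}, seed=5),
            ["f0"],
        )
        emp = auroc(feats.attrs["true_score"], cohort["nd"].to_numpy())
        assert abs(emp - feats.attrs["analytic_auroc"]) < 0.01

    def test_empty_schema_raises(self):
        with pytest.raises(ParameterError):
            simulate_cohort(CohortGenParams(), [])

    def test_coefficients_outside_schema_raise(self):
        with pytest.raises(ParameterError):
            simulate_cohort(CohortGenParams(true_coefficients={"zz": 1.0}), ["f0"])

    def test_determinism(self):
        p = CohortGenParams(n_patients=50, nd_prevalence=0.3, true_coefficients={"f0": 1.0}, seed=3)
        f1, c1 = simulate_cohort(p, ["f0", "f1"])
        f2, c2 = simulate_cohort(p, ["f0", "f1"])
        assert f1.equals(f2) and c1.equals(c2)
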