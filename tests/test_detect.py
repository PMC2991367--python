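"""Detection stage: filtering, convolution, gating, localization, measures."""

import dataclasses

import numpy as np
import pytest

from matchedpsc import (
    DetectionConfig,
    FilterBank,
    Trace,
    compose_trial,
    convolve_bank,
    detect,
    detection_threshold,
    gate_windows,
    highpass_zero_phase,
    invert_polarity,
    match_events,
    measure_event,
    score_peak_criteria,
    suprathreshold_candidates,
)
from matchedpsc.detect import EventCandidate


def _stub_bank(bank, mu=28.4, sigma=14.5):
    return dataclasses.replace(bank, mu_cmax=mu, sigma_cmax=sigma)


class TestHighpass:
    def test_zero_in_zero_out(self):
        tr = Trace(samples=np.zeros(1000))
        assert np.all(highpass_zero_phase(tr).samples == 0.0)

    def test_dc_rejected(self):
        tr = Trace(samples=np.full(5000, 100.0))
        out = highpass_zero_phase(tr).samples
        assert np.max(np.abs(out[1000:-1000])) < 1e-6

    def test_sinusoid_gain_matches_butterworth_squared(self):
        fs, f = 10_000.0, 200.0
        t = np.arange(40_000) / fs
        tr = Trace(samples=np.sin(2 * np.pi * f * t), sampling_rate=fs)
        out = highpass_zero_phase(tr).samples
        measured = np.max(np.abs(out[10_000:30_000]))
        # analytic 5th-order high-pass magnitude, applied forward + reverse
        gain = (1.0 / np.sqrt(1.0 + (10.0 / f) ** 10)) ** 2
        assert measured == pytest.approx(gain, rel=0.01)

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            highpass_zero_phase(Trace(samples=np.zeros(10)))


class TestInvertPolarity:
    def test_samplewise_negation_and_flag(self):
        tr = Trace(samples=np.array([1.0, -2.0, 3.0]))
        out = invert_polarity(tr)
        np.testing.assert_array_equal(out.samples, [-1.0, 2.0, -3.0])
        assert out.polarity == "inverted"

    def test_involution(self):
        tr = Trace(samples=np.arange(5, dtype=float))
        back = invert_polarity(invert_polarity(tr))
        np.testing.assert_array_equal(back.samples, tr.samples)
        assert back.polarity == tr.polarity


class TestThresholds:
    def test_detection_threshold_worked_values(self, bank):
        b = _stub_bank(bank)
        assert detection_threshold(b, -1.2) == pytest.approx(11.0)
        assert detection_threshold(b, 4.0) == pytest.approx(86.4)

    def test_zero_spread_degenerates_to_mu(self, bank):
        b = _stub_bank(bank, sigma=0.0)
        for k in (-2.0, 0.0, 3.0):
            assert detection_threshold(b, k) == b.mu_cmax


class TestSuprathresholdCandidates:
    def test_hand_computed_center_of_mass(self):
        row = np.zeros(30)
        row[10:13] = [2.0, 4.0, 2.0]
        cands = suprathreshold_candidates(row[None, :], 1.0, dt_ms=1.0)
        assert len(cands) == 1
        assert cands[0].t_cm == pytest.approx((2 * 10 + 4 * 11 + 2 * 12) / 8.0)

    def test_no_crossing_no_candidates(self):
        row = np.zeros((2, 50))
        assert suprathreshold_candidates(row, 0.5, dt_ms=0.1) == []

    def test_symmetric_run_centers(self):
        row = np.zeros(101)
        row[40:61] = np.bartlett(21) + 1.0
        cands = suprathreshold_candidates(row[None, :], 0.5, dt_ms=0.1)
        assert len(cands) == 1
        assert cands[0].t_cm == pytest.approx(50 * 0.1, abs=1e-9)

    def test_nonfinite_threshold_rejected(self):
        with pytest.raises(ValueError):
            suprathreshold_candidates(np.zeros((1, 10)), np.nan, 0.1)


class TestGateWindows:
    def _cand(self, t_cm, s, e, peak):
        return EventCandidate(t_cm=t_cm, source_template=0, start_index=s,
                              end_index=e, conv_peak=peak, t_hat=t_cm)

    def test_direct_window_dismissal(self, bank):
        b = _stub_bank(bank)
        conv = np.zeros((1, 3000))
        c = self._cand(105.0, 1040, 1060, 40.0)  # 5 ms after laser at 100 ms
        cfg = DetectionConfig()
        assert gate_windows([c], conv, 100.0, cfg, b, 0.1) == []

    def test_outlier_window_dismissal(self, bank):
        b = _stub_bank(bank)  # outlier threshold 86.4 pA
        conv = np.zeros((1, 3000))
        conv[0, 1190:1210] = 90.0
        c = self._cand(120.0, 1190, 1209, 90.0)  # 20 ms after laser onset
        assert gate_windows([c], conv, 100.0, DetectionConfig(), b, 0.1) == []

    def test_late_subthreshold_candidate_retained(self, bank):
        b = _stub_bank(bank)
        conv = np.zeros((1, 3000))
        conv[0, 1490:1510] = 40.0
        c = self._cand(150.0, 1490, 1509, 40.0)  # 50 ms post-onset, below 86.4
        assert gate_windows([c], conv, 100.0, DetectionConfig(), b, 0.1) == [c]

    def test_no_laser_no_gating(self, bank):
        c = self._cand(5.0, 40, 60, 500.0)
        out = gate_windows([c], np.zeros((1, 100)), None,
                           DetectionConfig(), bank, 0.1)
        assert out == [c]


class TestPeakScoring:
    def test_three_criterion_normalization_and_averages(self):
        scores, avg = score_peak_criteria(
            counts=[12, 4], n_filters=18,
            amplitudes=[71.46, 65.84], second_derivs=[0.45, 0.16])
        np.testing.assert_allclose(scores[0], [66.67, 100.0, 100.0], atol=0.005)
        assert scores[1][0] == pytest.approx(22.22, abs=0.005)
        # printed value truncated from 92.1355
        assert scores[1][1] == pytest.approx(92.13, abs=0.01)
        # stated normalization gives 35.56 for the third criterion
        assert scores[1][2] == pytest.approx(35.56, abs=0.005)
        assert avg[0] == pytest.approx(88.89, abs=0.005)
        assert avg[0] > avg[1]  # first peak selected

    def test_zero_amplitudes_do_not_divide_by_zero(self):
        scores, avg = score_peak_criteria([1, 1], 10, [0.0, 0.0], [0.0, 0.0])
        assert np.all(np.isfinite(scores))


class TestMeasureEvent:
    def test_triangle_ramp_measures(self):
        fs = 10_000.0
        x = np.zeros(200)
        x[50:81] = np.linspace(0.0, -30.0, 31)  # 3 ms ramp to -30 pA
        tr = Trace(samples=x, sampling_rate=fs)
        ev = measure_event(tr, 50, 80, 120, DetectionConfig())
        assert ev.peak_amplitude == pytest.approx(30.0)
        assert ev.rise_time == pytest.approx(3.0)
        assert ev.summed_input == pytest.approx(90.0)  # 2 * (1/2 * 30 * 3)

    def test_flat_segment_measures_zero(self):
        tr = Trace(samples=np.zeros(100))
        ev = measure_event(tr, 10, 30, 50, DetectionConfig())
        assert ev.peak_amplitude == 0.0
        assert ev.summed_input == 0.0

    def test_rise_time_is_peak_minus_onset(self):
        tr = Trace(samples=-np.bartlett(200) * 10, sampling_rate=10_000.0)
        ev = measure_event(tr, 55, 99, 150, DetectionConfig())
        assert ev.rise_time == pytest.approx(4.4)

    def test_latency_relative_to_laser(self):
        tr = Trace(samples=np.zeros(2000), laser_onset=100.0)
        ev = measure_event(tr, 1400, 1450, 1500, DetectionConfig())
        assert ev.latency == pytest.approx(45.0)


class TestDetectEndToEnd:
    def test_pure_weak_noise_yields_no_events(self, library, noise, bank,
                                              det_config):
        rng = np.random.default_rng(11)
        tr, truth = compose_trial([], library, noise, 100.0, rng)
        assert truth.peak_times.size == 0
        assert detect(tr, bank, det_config) == []

    def test_single_event_localized_within_tolerance(self, library, noise,
                                                     bank, det_config):
        rng = np.random.default_rng(12)
        tr, truth = compose_trial([100.0], library, noise, 9.0, rng)
        events = detect(tr, bank, det_config)
        assert len(events) >= 1
        best = min(abs(e.t_p - truth.peak_times[0]) for e in events)
        assert best <= 1.5

    def test_two_events_in_one_suprathreshold_run(self, library, noise, bank,
                                                  det_config):
        # clean pair 8 ms apart: conv runs fuse, both events must come back
        rng = np.random.default_rng(13)
        tr, truth = compose_trial([100.0, 108.0], library, noise, 1e6, rng)
        events = detect(tr, bank, det_config)
        m = match_events(truth.peak_times, [e.t_p for e in events])
        assert m.n_correct == 2

    def test_dc_offset_invariance(self, library, noise, bank, det_config):
        rng = np.random.default_rng(14)
        tr, _ = compose_trial([80.0, 150.0], library, noise, 9.0, rng)
        shifted = tr.with_samples(tr.samples + 250.0)
        a = detect(tr, bank, det_config)
        b = detect(shifted, bank, det_config)
        assert [e.peak_index for e in a] == [e.peak_index for e in b]

    def test_event_ordering_and_interval_invariants(self, library, noise,
                                                    bank, det_config):
        rng = np.random.default_rng(15)
        tr, _ = compose_trial([50.0, 90.0, 140.0, 190.0], library, noise,
                              6.0, rng)
        events = detect(tr, bank, det_config)
        t_ps = [e.t_p for e in events]
        assert t_ps == sorted(t_ps)
        assert len(set(t_ps)) == len(t_ps)
        for e in events:
            assert e.onset < e.t_p <= e.offset
            assert e.rise_time == pytest.approx(e.t_p - e.onset)

    def test_epsc_ipsc_polarity_symmetry(self, library, noise, bank,
                                         det_config):
        rng = np.random.default_rng(16)
        inward, _ = compose_trial([70.0, 130.0], library, noise, 9.0, rng)
        outward = inward.with_samples(-inward.samples)  # IPSC-like recording
        a = detect(inward, bank, det_config)
        b = detect(invert_polarity(outward), bank, det_config)
        assert [e.peak_index for e in a] == [e.peak_index for e in b]
        for ea, eb in zip(a, b):
            assert eb.peak_amplitude == pytest.approx(ea.peak_amplitude)

    def test_direct_response_window_excludes_early_events(self, library,
                                                          noise, bank,
                                                          det_config):
        rng = np.random.default_rng(17)
        tr, truth = compose_trial([105.0, 160.0], library, noise, 9.0, rng)
        tr = dataclasses.replace(tr, laser_onset=100.0)
        events = detect(tr, bank, det_config)
        for e in events:
            assert e.latency is None or e.latency >= \
                det_config.direct_window_ms - 1.5

    def test_empty_trace_yields_empty_list(self, bank, det_config):
        assert detect(Trace(samples=np.empty(0)), bank, det_config) == []


class TestOverlapSplitting:
    def test_split_shares_boundary_between_events(self, library, noise, bank,
                                                  det_config):
        rng = np.random.default_rng(21)
        tr, truth = compose_trial([100.0, 108.0], library, noise, 1e6, rng)
        events = detect(tr, bank, det_config)
        assert len(events) == 2
        first, second = events
        assert first.offset == pytest.approx(second.onset)

    def test_subcutoff_rebound_not_split(self, library, noise, bank):
        # second bump attenuated below the amplitude cutoff: one event only
        rng = np.random.default_rng(22)
        w = library.waveforms[0]
        n = 2150
        x = np.zeros(n)
        x[900 : 900 + w.size] += w
        x[980 : 980 + w.size] += 0.08 * w
        tr = Trace(samples=x)
        cfg = DetectionConfig(amplitude_cutoff=0.3)
        events = detect(tr, bank, cfg)
        assert len(events) == 1
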