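"""Training stage: segment extraction, polynomial templates, pooled stats."""

import json

import numpy as np
import pytest

from matchedpsc import (
    BaselineMismatchWarning,
    DegenerateSegmentError,
    FilterBank,
    MarkedEvent,
    Trace,
    build_bank,
    extract_segment,
    fit_template,
    template_statistics,
    train_template,
)


def _epsc_trace(n=400, onset=100, rise=1.0, decay=4.0, amp=50.0, fs=10_000.0):
    """Trace with one clean double-exponential EPSC embedded at `onset`."""
    t = np.arange(n) / fs * 1000.0
    x = np.zeros(n)
    tt = t[onset:] - t[onset]
    w = np.exp(-tt / decay) - np.exp(-tt / rise)
    x[onset:] = -amp * w / w.max()
    return Trace(samples=x, sampling_rate=fs)


class TestExtractSegment:
    def test_flat_trace_yields_zero_segment(self):
        tr = Trace(samples=np.full(100, 7.0))
        seg = extract_segment(tr, MarkedEvent(10, 40))
        assert np.all(seg == 0.0)

    def test_degenerate_mark_rejected(self):
        with pytest.raises(ValueError):
            MarkedEvent(40, 40)
        with pytest.raises(ValueError):
            MarkedEvent(41, 40)

    def test_out_of_bounds_mark_rejected(self):
        tr = Trace(samples=np.zeros(50))
        with pytest.raises(IndexError):
            extract_segment(tr, MarkedEvent(10, 60))

    def test_embedded_waveform_recovered_exactly(self):
        tr = _epsc_trace()
        tr2 = tr.with_samples(tr.samples - 12.5)  # holding-current offset
        seg = extract_segment(tr2, MarkedEvent(100, 280))
        np.testing.assert_allclose(seg, tr.samples[100:281], atol=1e-12)

    def test_baseline_mismatch_warns(self):
        tr = _epsc_trace()
        with pytest.warns(BaselineMismatchWarning):
            extract_segment(tr, MarkedEvent(100, 140))  # offset mid-decay


class TestFitTemplate:
    def test_exact_polynomial_reproduced(self):
        x = np.linspace(-1, 1, 101)
        seg = 3.0 - 2.0 * x + 0.5 * x**5 - x**8
        model = fit_template(seg, order=8)
        fitted = model.template_samples * np.sum(np.abs(seg)) \
            * np.sum(np.abs(model.template_samples)) / np.sum(np.abs(model.template_samples))
        # residual of the L1-normalized fit against the L1-normalized input
        ref = seg / np.sum(np.abs(seg))
        resid = np.max(np.abs(model.template_samples - ref))
        assert resid < 1e-8 * np.max(np.abs(ref))

    def test_unit_l1_norm(self):
        tr = _epsc_trace()
        seg = extract_segment(tr, MarkedEvent(100, 280))
        model = fit_template(seg)
        assert np.sum(np.abs(model.template_samples)) == pytest.approx(1.0, rel=1e-9)

    def test_order8_beats_lower_orders(self):
        tr = _epsc_trace(rise=1.0, decay=5.0)
        seg = extract_segment(tr, MarkedEvent(100, 240))
        x = np.linspace(-1, 1, seg.size)

        def resid(order):
            from numpy.polynomial import polynomial as P
            c = P.polyfit(x, seg, order)
            return np.sqrt(np.mean((P.polyval(x, c) - seg) ** 2))

        assert resid(8) <= min(resid(k) for k in range(2, 8))

    def test_scale_invariance(self):
        tr = _epsc_trace()
        seg = extract_segment(tr, MarkedEvent(100, 280))
        a = fit_template(seg).template_samples
        b = fit_template(17.3 * seg).template_samples
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateSegmentError):
            fit_template(np.zeros(50))
        with pytest.raises(DegenerateSegmentError):
            fit_template(np.ones(5), order=8)


class TestTemplateStatistics:
    def test_symmetric_event_lead_equals_trail(self):
        n = 201
        seg = -np.bartlett(n) * 30.0
        x = np.zeros(400)
        x[50 : 50 + n] = seg
        tr = Trace(samples=x)
        mark = MarkedEvent(50, 50 + n - 1, peak_index=50 + n // 2)
        model = template_statistics(tr, mark, fit_template(x[50 : 50 + n]))
        assert model.lead == pytest.approx(model.trail)

    def test_lead_trail_from_mark_geometry(self):
        # onset 4.4 ms before the peak, offset 10.2 ms after, at 10 kHz
        tr = _epsc_trace(n=600, onset=100, rise=2.0, decay=4.0)
        peak = 100 + int(np.argmin(tr.samples))
        peak = int(np.argmin(tr.samples))
        mark = MarkedEvent(peak - 44, peak + 102, peak_index=peak)
        model = train_template(tr, mark)
        assert model.lead == pytest.approx(4.4)
        assert model.trail == pytest.approx(10.2)
        assert model.duration == pytest.approx(14.6)

    def test_cmax_matches_bruteforce_convolution(self):
        x = np.zeros(20)
        x[5:10] = [0.0, -2.0, -4.0, -2.0, 0.0]
        tr = Trace(samples=x)
        mark = MarkedEvent(5, 9, peak_index=7)
        seg = extract_segment(tr, mark)
        model = fit_template(seg, order=2)
        model = template_statistics(tr, mark, model)
        # brute-force full convolution oracle
        w = model.template_samples
        best = -np.inf
        for k in range(len(seg) + len(w) - 1):
            acc = 0.0
            for i in range(len(seg)):
                j = k - i
                if 0 <= j < len(w):
                    acc += seg[i] * w[j]
            best = max(best, acc)
        assert model.c_max == pytest.approx(best, rel=1e-12)

    def test_outward_event_rejected(self):
        tr = _epsc_trace()
        tr = tr.with_samples(-tr.samples)
        with pytest.raises(DegenerateSegmentError):
            train_template(tr, MarkedEvent(100, 280))


class TestBuildBank:
    def _models(self, c_maxes):
        tr = _epsc_trace()
        base = train_template(tr, MarkedEvent(100, 280))
        import dataclasses
        return [dataclasses.replace(base, c_max=c) for c in c_maxes]

    def test_pooled_stats_hand_computed(self):
        with pytest.warns(UserWarning):
            bank = build_bank(self._models([10.0, 20.0, 30.0]))
        assert bank.mu_cmax == pytest.approx(20.0)
        assert bank.sigma_cmax == pytest.approx(10.0)  # sample SD, n-1

    def test_single_template_zero_spread(self):
        with pytest.warns(UserWarning):
            bank = build_bank(self._models([42.0]))
        assert bank.sigma_cmax == 0.0
        assert bank.n_filters == 1

    def test_empty_bank_rejected(self):
        with pytest.raises(ValueError):
            build_bank([])

    def test_mean_and_sd_recovered_for_constructed_bank(self):
        # 18 c_max values engineered to mean 28.4 pA, SD 14.5 pA
        rng = np.random.default_rng(3)
        v = rng.normal(size=18)
        v = (v - v.mean()) / v.std(ddof=1)
        v = 28.4 + 14.5 * v
        bank = build_bank(self._models(v))
        assert bank.mu_cmax == pytest.approx(28.4)
        assert bank.sigma_cmax == pytest.approx(14.5)

    def test_serialization_roundtrip(self, tmp_path, bank):
        path = tmp_path / "bank.json"
        bank.save(path)
        loaded = FilterBank.load(path)
        assert loaded.n_filters == bank.n_filters
        assert loaded.mu_cmax == bank.mu_cmax
        assert loaded.sigma_cmax == bank.sigma_cmax
        for a, b in zip(bank.templates, loaded.templates):
            np.testing.assert_allclose(a.template_samples, b.template_samples,
                                       atol=1e-12)
            assert b.shift == pytest.approx(a.shift, abs=1e-12)
            assert b.c_max == pytest.approx(a.c_max, abs=1e-12)

    def test_unknown_schema_rejected(self, bank):
        d = bank.to_dict()
        d["schema_version"] = 99
        with pytest.raises(ValueError):
            FilterBank.from_dict(d)
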