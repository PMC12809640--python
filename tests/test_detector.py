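"""TSW detector: correctness on synthetic traces with exact ground truth."""

import math

import numpy as np
import pytest

from nanopulse import (
    EventRecord,
    SquarePulseSpec,
    TSWConfig,
    TSWDetector,
    clamp_w2,
    compute_nsigma,
    compute_z,
    simulate_square_trace,
)
from nanopulse.bench import match_events


def _square_trace(dwell_s=1e-3, n_events=12, seed=3, **kw):
    rate = kw.pop("event_rate", 1.0 / (dwell_s + 0.02))
    spec = SquarePulseSpec(
        event_rate=rate,
        dwell_s=dwell_s,
        duration_s=(n_events + 1) / rate + 0.1,
        seed=seed,
        **kw,
    )
    return simulate_square_trace(spec), spec


class TestPrimitives:
    def test_nsigma(self):
        assert compute_nsigma(-500.0, 0.0, 50.0) == pytest.approx(10.0)
        with pytest.raises(ValueError):
            compute_nsigma(1.0, 0.0, 0.0)

    def test_z_oracle_and_symmetry(self):
        z = compute_z(0.0, -500.0, 50.0, 30.0, 5000, 50)
        ref = 500.0 / math.sqrt(50.0**2 / 5000 + 30.0**2 / 50)
        assert z == pytest.approx(ref)
        assert compute_z(1.0, 2.0, 3.0, 4.0, 10, 20) == pytest.approx(
            -compute_z(2.0, 1.0, 3.0, 4.0, 10, 20)
        )
        with pytest.raises(ValueError):
            compute_z(0.0, 1.0, 1.0, 1.0, 1, 50)

    def test_clamp(self):
        assert clamp_w2(-900.0, 0.0, 50.0) == -250.0
        assert clamp_w2(900.0, 0.0, 50.0) == 250.0
        assert clamp_w2(100.0, 0.0, 50.0) == 100.0
        with pytest.raises(ValueError):
            clamp_w2(0.0, 0.0, 0.0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TSWConfig(fs=0.0)
        with pytest.raises(ValueError):
            TSWConfig(fs=1e5, n2=1)
        with pytest.raises(ValueError):
            TSWConfig(fs=1e5, baseline_mode="mode")
        cfg = TSWConfig(fs=500_000.0)
        assert cfg.n1_init == 5000
        assert cfg.max_event_samples == 250_000


class TestDetection:
    def test_counts_and_dwell_1ms(self):
        (trace, truth), spec = _square_trace()
        events = TSWDetector(TSWConfig(fs=spec.fs)).detect(trace)
        matches = match_events(truth, events)
        assert all(m is not None for m in matches)
        assert len(events) <= len(truth) + 2  # at most a couple of noise hits
        dwells = np.array([events[m].dwell_s for m in matches])
        assert abs(np.median(dwells) - spec.dwell_s) / spec.dwell_s < 0.02

    def test_long_event_within_one_percent(self):
        (trace, truth), spec = _square_trace(dwell_s=0.128, n_events=3, event_rate=0.5)
        events = TSWDetector(TSWConfig(fs=spec.fs)).detect(trace)
        matches = match_events(truth, events)
        assert all(m is not None for m in matches)
        for m in matches:
            assert abs(events[m].dwell_s - 0.128) / 0.128 < 0.01

    def test_amplitude_summaries(self):
        (trace, truth), spec = _square_trace(n_events=8)
        events = TSWDetector(TSWConfig(fs=spec.fs)).detect(trace)
        for m in match_events(truth, events):
            ev = events[m]
            # negative-going 500 pA pulse on a zero baseline
            assert ev.baseline_pA == pytest.approx(0.0, abs=20.0)
            assert ev.delta_i_mean == pytest.approx(-500.0, abs=60.0)
            assert abs(ev.i_max) >= abs(ev.i_min) > 0
            assert not ev.clog

    def test_positive_going_pulses(self):
        (trace, truth), spec = _square_trace(n_events=8, baseline_pA=-10_000.0)
        events = TSWDetector(TSWConfig(fs=spec.fs)).detect(trace)
        matches = match_events(truth, events)
        assert all(m is not None for m in matches)
        for m in matches:
            assert events[m].delta_i_mean == pytest.approx(500.0, abs=60.0)

    def test_polarity_filter(self):
        (trace, truth), spec = _square_trace(n_events=8)
        cfg = TSWConfig(fs=spec.fs, polarity="positive")
        events = TSWDetector(cfg).detect(trace)
        # pulses are negative-going; a positive-only detector must skip them
        matched = [m for m in match_events(truth, events) if m is not None]
        assert len(matched) == 0

    def test_clog_flag(self):
        fs = 100_000.0
        rng = np.random.default_rng(5)
        n = int(3.0 * fs)
        trace = rng.normal(0.0, 50.0, n)
        start = int(1.0 * fs)
        trace[start : start + int(0.8 * fs)] -= 500.0  # longer than 0.5 s guard
        cfg = TSWConfig(fs=fs)
        events = TSWDetector(cfg).detect(trace)
        assert any(ev.clog for ev in events)

    def test_baseline_mode_mean(self):
        (trace, truth), spec = _square_trace(n_events=6)
        cfg = TSWConfig(fs=spec.fs, baseline_mode="mean")
        events = TSWDetector(cfg).detect(trace)
        assert all(m is not None for m in match_events(truth, events))


class TestStreamingContract:
    def test_chunking_invariance(self):
        (trace, _), spec = _square_trace(dwell_s=200e-6, n_events=10, seed=9)
        results = []
        for chunk_size in (977, 10_000, trace.size):
            det = TSWDetector(TSWConfig(fs=spec.fs))
            results.append(det.detect(trace, chunk_size=chunk_size))
        ref = results[0]
        for events in results[1:]:
            assert len(events) == len(ref)
            for a, b in zip(ref, events):
                assert a.start_index == b.start_index
                assert a.end_index == b.end_index
                assert a.dwell_s == pytest.approx(b.dwell_s, abs=0.0)
                assert a.baseline_pA == pytest.approx(b.baseline_pA, abs=0.0)

    def test_sample_at_a_time(self):
        fs = 20_000.0
        spec = SquarePulseSpec(
            fs=fs, fc=2000.0, dwell_s=2e-3, event_rate=2.0, duration_s=2.0, seed=2
        )
        trace, truth = simulate_square_trace(spec)
        det_bulk = TSWDetector(TSWConfig(fs=fs, max_event_samples=2000))
        ref = det_bulk.detect(trace)
        det = TSWDetector(TSWConfig(fs=fs, max_event_samples=2000))
        got = []
        for x in trace:
            ev = det.process_sample(float(x))
            if ev is not None:
                got.append(ev)
        assert [(e.start_index, e.end_index) for e in got] == [
            (e.start_index, e.end_index) for e in ref
        ]

    def test_determinism(self):
        (trace, _), spec = _square_trace(n_events=6, seed=11)
        e1 = TSWDetector(TSWConfig(fs=spec.fs)).detect(trace)
        e2 = TSWDetector(TSWConfig(fs=spec.fs)).detect(trace)
        assert [(e.start_index, e.end_index, e.dwell_s) for e in e1] == [
            (e.start_index, e.end_index, e.dwell_s) for e in e2
        ]

    def test_baseline_property_and_flush(self):
        fs = 100_000.0
        rng = np.random.default_rng(0)
        det = TSWDetector(TSWConfig(fs=fs))
        with pytest.raises(ValueError):
            _ = det.baseline
        det.process(rng.normal(100.0, 5.0, 20_000))
        assert det.baseline == pytest.approx(100.0, abs=1.0)
        assert det.sigma1 == pytest.approx(5.0, rel=0.2)
        det.flush_baseline()
        with pytest.raises(ValueError):
            _ = det.baseline

    def test_baseline_trace_tracks_drift(self):
        fs = 100_000.0
        rng = np.random.default_rng(1)
        n = 60_000
        drift = np.linspace(0.0, 40.0, n)
        det = TSWDetector(TSWConfig(fs=fs))
        i0 = det.baseline_trace(rng.normal(0.0, 5.0, n) + drift)
        tail = i0[-1000:]
        assert np.all(np.isfinite(tail))
        assert np.median(tail) == pytest.approx(drift[-1], abs=2.0)

    def test_non_finite_rejected(self):
        det = TSWDetector(TSWConfig(fs=1e5))
        with pytest.raises(ValueError):
            det.process(np.array([1.0, np.nan]))

    def test_reference_current(self):
        (trace, truth), spec = _square_trace(n_events=4)
        det = TSWDetector(TSWConfig(fs=spec.fs)).set_reference_current(0.0)
        events = det.detect(trace)
        m = match_events(truth, events)[0]
        assert events[m].delta_ref == pytest.approx(-500.0, abs=60.0)

    def test_event_record_to_dict(self):
        ev = EventRecord(
            start_index=10, end_index=20, dwell_s=1e-4, baseline_pA=0.0,
            sigma_pA=50.0, delta_i_mean=-480.0, i_min=-450.0, i_max=-520.0,
            samples=np.zeros(10),
        )
        d = ev.to_dict()
        assert d["start_index"] == 10 and "samples" not in d
        assert len(ev.to_dict(with_samples=True)["samples"]) == 10
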