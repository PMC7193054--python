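"""LFP noise estimation, threshold detection and event classification."""

import numpy as np
import pytest

from zfscreen import (
    DetectionParams,
    LFPTrace,
    detect_events,
    estimate_noise,
    summarize_ep,
)
from zfscreen.errors import DegenerateNoiseError, InputError
from zfscreen.lfp import EpileptiformEvent, NoiseEstimate, MAD_TO_SIGMA
from zfscreen.synthetic import _biphasic, _polyspike, simulate_lfp_trace

from conftest import child_seed

FS = 1000.0


def _trace(samples, condition="test"):
    return LFPTrace(subject_id="s", condition=condition, sampling_rate=FS,
                    samples=np.asarray(samples, dtype=float))


def _noise_trace(sigma, seconds=600, seed=0):
    rng = np.random.default_rng(seed)
    return _trace(rng.standard_normal(int(seconds * FS)) * sigma)


def _inject(samples, wave, at_s):
    out = samples.copy()
    i0 = int(at_s * FS)
    out[i0:i0 + wave.size] += wave
    return out


class TestEstimateNoise:
    def test_constant_trace_gives_zero(self):
        assert estimate_noise(_trace(np.full(1000, 2.5))).sigma == 0.0

    def test_pure_gaussian_recovers_sigma(self):
        est = estimate_noise(_noise_trace(0.35, seconds=600, seed=1))
        assert est.sigma == pytest.approx(0.35, abs=0.01)

    def test_insensitive_to_injected_spikes(self):
        """With 10 large spikes, sigma matches the event-free oracle within 2%."""
        x = _noise_trace(1.0, seconds=600, seed=2).samples
        wave = _biphasic(0.5, 6.0, FS)
        starts = np.arange(10) * 50.0 + 5.0
        y = x.copy()
        for s in starts:
            y = _inject(y, wave, s)
        mask = np.ones(y.size, bool)
        for s in starts:
            mask[int(s * FS): int(s * FS) + wave.size] = False
        oracle = MAD_TO_SIGMA * np.median(np.abs(x[mask] - np.median(x[mask])))
        assert estimate_noise(_trace(y)).sigma == pytest.approx(oracle, rel=0.02)

    def test_empty_trace_rejected(self):
        with pytest.raises(InputError):
            estimate_noise(_trace([]))


class TestDetectEvents:
    def test_noise_only_trace_yields_nothing(self):
        trace = _noise_trace(0.35, seconds=600, seed=3)
        assert detect_events(trace, estimate_noise(trace)) == []

    def test_single_interictal_transient(self):
        x = _noise_trace(0.35, seconds=60, seed=4).samples
        y = _inject(x, _biphasic(0.6, 4 * 0.35, FS), 30.0)
        events = detect_events(_trace(y), NoiseEstimate(0.35, "known"))
        assert len(events) == 1
        assert events[0].event_class == "interictal"
        assert events[0].duration < 1.0

    def test_polyspike_burst_is_ictal(self):
        x = _noise_trace(0.35, seconds=60, seed=5).samples
        y = _inject(x, _polyspike(3.1, 6 * 0.35, FS), 30.0)
        events = detect_events(_trace(y), NoiseEstimate(0.35, "known"))
        assert len(events) == 1
        assert events[0].event_class == "ictal"
        assert events[0].n_spikes >= 3
        assert events[0].duration == pytest.approx(3.1, abs=0.3)

    def test_subthreshold_bump_ignored(self):
        x = _noise_trace(0.35, seconds=60, seed=6).samples
        y = _inject(x, _biphasic(0.6, 2 * 0.35, FS), 30.0)
        assert detect_events(_trace(y), NoiseEstimate(0.35, "known")) == []

    def test_degenerate_noise_raises_for_nonconstant_trace(self):
        trace = _noise_trace(0.35, seconds=10, seed=7)
        with pytest.raises(DegenerateNoiseError):
            detect_events(trace, NoiseEstimate(0.0, "broken"))
        # constant trace with zero sigma is simply empty
        assert detect_events(_trace(np.zeros(1000)), NoiseEstimate(0.0, "ok")) == []

    def test_events_sorted_disjoint_and_exclusively_classed(self, cfg):
        trace, _ = simulate_lfp_trace(cfg, seed=child_seed(30, 0))
        events = detect_events(trace, estimate_noise(trace))
        prev_end = -1.0
        for ev in events:
            assert ev.start > prev_end
            prev_end = ev.end
            assert ev.event_class in ("interictal", "ictal")
            assert ev.n_spikes >= 1

    def test_raising_threshold_never_adds_events(self, cfg):
        for i in range(5):
            trace, _ = simulate_lfp_trace(cfg, seed=child_seed(31, i))
            noise = estimate_noise(trace)
            counts = [
                len(detect_events(
                    trace, noise,
                    DetectionParams(threshold_factor=f, ictal_factor=max(5.0, f)),
                ))
                for f in (3.0, 3.5, 4.0, 5.0, 6.0)
            ]
            assert counts == sorted(counts, reverse=True)


def _match_fraction(truth_events, detected, min_overlap=0.5):
    matched = 0
    for te in truth_events:
        for de in detected:
            lo, hi = max(te.start, de.start), min(te.end, de.end)
            if hi > lo and (hi - lo) / (te.end - te.start) >= min_overlap:
                matched += 1
                break
    return matched / max(1, len(truth_events))


class TestDetectionAccuracy:
    def test_recall_and_precision_on_default_amplitudes(self, cfg):
        """>=95% of true events recovered, <=5% of detections unmatched (20 traces)."""
        recalls, precisions = [], []
        for i in range(20):
            trace, gt = simulate_lfp_trace(cfg, seed=child_seed(32, i))
            events = detect_events(trace, estimate_noise(trace))
            recalls.append(_match_fraction(gt.events, events))
            # precision: detected events matched by some truth interval
            class _E:
                def __init__(self, s, e):
                    self.start, self.end = s, e
            precisions.append(
                _match_fraction(
                    [_E(d.start, d.end) for d in events],
                    [_E(t.start, t.end) for t in gt.events],
                )
            )
        assert np.mean(recalls) >= 0.95
        assert np.mean(precisions) >= 0.95

    def test_duration_recovery(self, cfg):
        """Pooled detected durations recover the configured means (20 traces)."""
        inter, ictal = [], []
        for i in range(20):
            trace, _ = simulate_lfp_trace(cfg, seed=child_seed(33, i))
            for ev in detect_events(trace, estimate_noise(trace)):
                (inter if ev.event_class == "interictal" else ictal).append(ev.duration)
        assert np.mean(inter) == pytest.approx(cfg.interictal_duration_mean, abs=0.05)
        assert np.mean(ictal) == pytest.approx(cfg.ictal_duration_mean, abs=0.5)


class TestSummarize:
    def test_empty_event_list(self):
        stats = summarize_ep([], 600.0)
        assert stats.total_count == 0
        assert stats.mean_interictal_duration is None
        assert stats.mean_ictal_duration is None

    def test_counts_normalized_to_10min(self):
        events = [
            EpileptiformEvent(10.0 * k, 10.0 * k + 0.5, 1.5, 2, "interictal")
            for k in range(3)
        ] + [EpileptiformEvent(100.0, 103.0, 2.5, 8, "ictal")]
        stats = summarize_ep(events, 600.0)
        assert (stats.interictal_count, stats.ictal_count, stats.total_count) == (3, 1, 4)
        half = summarize_ep(events, 300.0)
        assert half.total_count == 8  # scaled to the 10-min reporting epoch

    def test_total_is_sum_of_classes(self, cfg):
        trace, _ = simulate_lfp_trace(cfg, seed=child_seed(34, 0))
        events = detect_events(trace, estimate_noise(trace))
        stats = summarize_ep(events, trace.duration)
        assert stats.total_count == pytest.approx(
            stats.interictal_count + stats.ictal_count
        )

    def test_out_of_bounds_event_rejected(self):
        with pytest.raises(InputError):
            summarize_ep([EpileptiformEvent(599.0, 601.0, 2.0, 1, "interictal")], 600.0)
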