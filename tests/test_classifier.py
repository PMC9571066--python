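import numpy as np
import pytest

from hfomorph import (
    DEFAULT_SWEEP_MS,
    DynamicThreshold,
    EventFeatures,
    EventWindow,
    MorphParams,
    Signal1D,
    SyntheticSpec,
    classify_event,
    extract_features,
    feature_signal,
    fit_threshold,
    generate_recording,
    make_ripple,
    make_spike,
    sweep_open_windows,
)
from hfomorph.classifier import sweep_with_counts

from conftest import FS


def embedded(wave, n=8000, start=3000):
    x = np.zeros(n)
    x[start : start + len(wave)] += wave.samples
    return Signal1D(x, FS), EventWindow(start, start + len(wave))


#: smoothing reduced to a single sample so morphology acts on raw |diff|
RAW_MP = MorphParams(smooth_ms=0.1, close_ms=0.1, open_ms=4.0)


class TestFeatureSignal:
    def test_constant_segment_gives_zeros(self):
        x = Signal1D(np.full(5000, 3.0), FS)
        out = feature_signal(x, EventWindow(2000, 2500))
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_spike_feature_has_single_dominant_hump_at_flank(self):
        signal, event = embedded(make_spike(80.0, 20.0, FS))
        feat = feature_signal(signal, event)
        peak = np.argmax(feat.samples)
        # hump sits on the fast upstroke (first quarter of the padded segment)
        ctx = int(round(100.0 * FS / 1000.0))
        rise = int(round(10.0 * FS / 1000.0))
        assert ctx - 10 <= peak <= ctx + rise + 10
        # single dominant hump: nothing elsewhere comes close
        outside = np.concatenate([feat.samples[: ctx - 60], feat.samples[ctx + 2 * rise + 60 :]])
        assert np.max(outside) < 0.25 * feat.samples[peak]

    def test_ripple_feature_bounded_by_smoothed_derivative(self):
        freq, amp = 120.0, 1.5
        signal, event = embedded(make_ripple(freq, 60.0, amp, FS))
        feat = feature_signal(signal, event)
        bound = 2 * np.pi * freq * amp / FS
        assert np.max(feat.samples) <= bound * 1.05

    def test_context_clamped_at_recording_edges(self):
        x = Signal1D(np.arange(1000, dtype=float), FS)
        out = feature_signal(x, EventWindow(0, 300))  # 100 ms context would start at -500
        assert len(out) == 300 + 500

    def test_event_outside_signal_rejected(self):
        x = Signal1D(np.zeros(1000) + np.arange(1000.0), FS)
        with pytest.raises(ValueError):
            feature_signal(x, EventWindow(800, 1200))


class TestExtractFeatures:
    def test_narrow_feature_hump_truncated_to_background(self):
        # 2 ms ramp pulse -> |diff| support ~2 ms < 4 ms opening window
        x = np.zeros(8000)
        x[3000:3005] = [2.0, 4.0, 6.0, 4.0, 2.0]
        f = extract_features(Signal1D(x, FS), EventWindow(2990, 3020), RAW_MP)
        assert f.envelope_peak == pytest.approx(2.0)  # max |diff|
        assert f.truncated_level == pytest.approx(0.0, abs=1e-12)

    def test_wide_feature_hump_survives_opening(self):
        # 40 ms triangular ramp -> |diff| is a 100-sample plateau >> 4 ms window
        ramp = np.concatenate([np.linspace(0, 10, 101), np.linspace(10, 0, 101)[1:]])
        x = np.zeros(8000)
        x[3000 : 3000 + ramp.size] += ramp
        f = extract_features(Signal1D(x, FS), EventWindow(3000, 3000 + ramp.size), RAW_MP)
        assert f.truncated_level == pytest.approx(f.envelope_peak, rel=1e-9)

    def test_zero_segment_gives_zero_features(self):
        x = Signal1D(np.zeros(5000), FS)
        f = extract_features(x, EventWindow(2000, 2400))
        assert (f.envelope_peak, f.truncated_level) == (0.0, 0.0)

    def test_truncated_never_exceeds_envelope(self, default_recording):
        signal, truth = default_recording
        for e in truth.events:
            for open_ms in (1.0, 4.0, 8.0):
                f = extract_features(signal, e, MorphParams(open_ms=open_ms))
                assert f.truncated_level <= f.envelope_peak + 1e-12

    def test_invalid_feature_pair_rejected(self):
        with pytest.raises(ValueError):
            EventFeatures(envelope_peak=1.0, truncated_level=2.0, open_ms_used=4.0)


class TestFitThreshold:
    def test_single_event(self, default_recording):
        signal, truth = default_recording
        e = truth.events[0]
        th = fit_threshold([(signal, e)])
        assert th.value == extract_features(signal, e).truncated_level
        assert th.n_training_events == 1
        assert th.open_ms == 4.0

    def test_adding_events_never_lowers_threshold(self, default_recording):
        signal, truth = default_recording
        events = [(signal, e) for e in truth.events]
        previous = -np.inf
        for k in range(1, len(events) + 1):
            value = fit_threshold(events[:k]).value
            assert value >= previous
            previous = value

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            fit_threshold([])

    def test_threshold_separates_classes_on_synthetic_set(self):
        spec = SyntheticSpec(n_spikes=5, n_ripples=20, seed=9)
        signal, truth = generate_recording(spec)
        th = fit_threshold([(signal, e) for e in truth.events], MorphParams(open_ms=5.4))
        spikes = [extract_features(signal, e, MorphParams(open_ms=5.4)) for e in truth.by_label("spike")]
        ripples = [extract_features(signal, e, MorphParams(open_ms=5.4)) for e in truth.by_label("ripple")]
        assert all(f.envelope_peak > th.value for f in spikes)
        assert all(f.envelope_peak <= th.value for f in ripples)


class TestClassifyEvent:
    def test_infinite_threshold_means_ripple(self):
        f = EventFeatures(5.0, 4.0, 4.0)
        th = DynamicThreshold(np.inf, 1, 4.0)
        assert classify_event(f, th) == "ripple"

    def test_zero_threshold_with_positive_features_means_spike(self):
        f = EventFeatures(0.1, 0.05, 4.0)
        th = DynamicThreshold(0.0, 1, 4.0)
        assert classify_event(f, th) == "spike"

    def test_mismatched_open_ms_rejected(self):
        f = EventFeatures(1.0, 0.5, 4.0)
        th = DynamicThreshold(0.7, 3, 5.0)
        with pytest.raises(ValueError, match="opening window"):
            classify_event(f, th)

    def test_fitted_threshold_separates_spike_from_ripple(self, default_recording):
        signal, truth = default_recording
        th = fit_threshold([(signal, e) for e in truth.events], MorphParams(open_ms=5.4))
        mp = MorphParams(open_ms=5.4)
        spike = truth.by_label("spike")[0]
        ripple = truth.by_label("ripple")[0]
        assert classify_event(extract_features(signal, spike, mp), th) == "spike"
        assert classify_event(extract_features(signal, ripple, mp), th) == "ripple"

    def test_classification_monotone_in_threshold(self, default_recording):
        signal, truth = default_recording
        f = extract_features(signal, truth.events[0])
        calls = [
            classify_event(f, DynamicThreshold(v, 1, 4.0))
            for v in np.linspace(0.0, 2 * f.envelope_peak, 25)
        ]
        # once a ripple, never back to spike as the threshold keeps rising
        first_ripple = calls.index("ripple") if "ripple" in calls else len(calls)
        assert all(c == "ripple" for c in calls[first_ripple:])


class TestSweep:
    def test_default_grid_is_the_published_one(self):
        assert DEFAULT_SWEEP_MS == (1, 2, 3, 3.4, 4, 4.6, 5, 5.4, 6, 7, 8)

    def test_one_window_gives_one_point(self, default_recording, labeled_candidates):
        signal, _ = default_recording
        points = sweep_open_windows([(signal, e) for e in labeled_candidates], (4.0,))
        assert len(points) == 1
        assert points[0].window_ms == 4.0

    def test_sensitivity_nondecreasing_in_window_size(self, default_recording, labeled_candidates):
        signal, _ = default_recording
        points = sweep_open_windows([(signal, e) for e in labeled_candidates])
        ses = [p.sensitivity for p in points]
        assert all(a <= b + 1e-12 for a, b in zip(ses, ses[1:]))

    def test_tp_plus_fn_equals_true_spikes_in_every_row(self, default_recording, labeled_candidates):
        signal, _ = default_recording
        n_spikes = sum(e.label == "spike" for e in labeled_candidates)
        _, counts = sweep_with_counts([(signal, e) for e in labeled_candidates])
        assert all(c.tp + c.fn == n_spikes for c in counts)

    def test_no_spikes_in_training_rejected(self, default_recording):
        signal, truth = default_recording
        ripples_only = [(signal, e) for e in truth.by_label("ripple")]
        with pytest.raises(ValueError, match="spike"):
            sweep_open_windows(ripples_only)

    def test_unknown_labels_rejected(self, default_recording):
        signal, truth = default_recording
        events = [(signal, truth.events[0].relabel("spike")), (signal, truth.events[1].relabel("unlabeled"))]
        with pytest.raises(ValueError, match="labels"):
            sweep_open_windows(events)

    def test_determinism(self, default_recording, labeled_candidates):
        signal, _ = default_recording
        training = [(signal, e) for e in labeled_candidates]
        assert sweep_open_windows(training) == sweep_open_windows(training)

    def test_distance_consistent_with_se_fdr(self, default_recording, labeled_candidates):
        signal, _ = default_recording
        for p in sweep_open_windows([(signal, e) for e in labeled_candidates]):
            assert p.distance == pytest.approx(np.hypot(p.fdr, 1.0 - p.sensitivity))


class TestMorphParams:
    def test_published_defaults(self):
        mp = MorphParams()
        assert (mp.smooth_ms, mp.close_ms, mp.open_ms, mp.context_ms) == (10.0, 1.0, 4.0, 100.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            MorphParams(open_ms=0.0)
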