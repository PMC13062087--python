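import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from respsense import physio
from respsense.signal import ContinuousSignal
from respsense.circstats import rayleigh_test
from respsense.synth import gen_pupil, gen_respiration


def _sine_signal(n_cycles=10, fs=100.0, amp=1.5, f=0.25):
    t = np.arange(int(n_cycles / f * fs)) / fs
    return ContinuousSignal(amp * np.sin(2 * np.pi * f * t), fs=fs)


class TestNormalizeAndClip:
    def test_below_threshold_is_plain_zscore(self):
        sig = _sine_signal()
        out = physio.normalize_and_clip(sig)
        x = sig.samples
        np.testing.assert_allclose(out.samples, (x - x.mean()) / x.std())
        assert np.abs(out.samples).max() < 2.5

    def test_spike_replaced_by_interpolation(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2000)
        x[1000] = 40.0
        out = physio.normalize_and_clip(ContinuousSignal(x, fs=100.0))
        assert np.abs(out.samples).max() <= 2.5
        # the spike sample must now lie between its neighbours
        assert out.samples[999] <= out.samples[1000] <= out.samples[1001] or \
            out.samples[1001] <= out.samples[1000] <= out.samples[999]

    def test_idempotent(self):
        sig, _ = gen_respiration(300, rate=15, sigh_prob=0.2, seed=4)
        once = physio.normalize_and_clip(sig)
        twice = physio.normalize_and_clip(once)
        np.testing.assert_allclose(twice.samples, once.samples, atol=1e-12)

    def test_all_bad_raises(self):
        with pytest.raises(ValueError):
            physio.normalize_and_clip(ContinuousSignal(np.ones(100), fs=10.0))

    def test_sigh_does_not_change_cycle_count(self):
        base_kw = dict(rate=15.0, cycle_jitter=0.05, amp_jitter=0.05, seed=7)
        sig, truth = gen_respiration(300, sigh_prob=0.3, **base_kw)
        clean = physio.normalize_and_clip(sig)
        peaks, _ = physio.detect_extrema(clean)
        assert peaks.size == truth["peak_times_s"].size


class TestDetectExtrema:
    def test_sinusoid_counts(self):
        sig = physio.normalize_and_clip(_sine_signal(n_cycles=10))
        peaks, troughs = physio.detect_extrema(sig)
        assert peaks.size == 10
        assert troughs.size == 10

    def test_small_ripple_ignored(self):
        fs = 100.0
        t = np.arange(int(40 * fs)) / fs
        x = 1.5 * np.sin(2 * np.pi * 0.25 * t) + 0.1 * np.sin(2 * np.pi * 3 * t)
        peaks, troughs = physio.detect_extrema(ContinuousSignal(x, fs=fs),
                                               min_prominence=1.0)
        assert peaks.size == 10  # ripple extrema stay below prominence 1

    def test_jittered_trace_recovers_cycle_count(self):
        sig, truth = gen_respiration(400, rate=15, cycle_jitter=0.1,
                                     amp_jitter=0.1, sigh_prob=0.0, seed=2)
        clean = physio.normalize_and_clip(sig)
        peaks, _ = physio.detect_extrema(clean)
        assert peaks.size == truth["peak_times_s"].size

    def test_flat_signal_raises(self):
        with pytest.raises(ValueError):
            physio.detect_extrema(ContinuousSignal(np.zeros(100) + 1e-9, fs=10))


class TestInterpolatePhase:
    def test_half_cycle_ramps(self):
        rp = physio.interpolate_phase(201, peak_idx=[100], trough_idx=[0, 200])
        assert rp.phase[0] == -np.pi
        assert rp.phase[100] == 0.0
        assert rp.phase[50] == pytest.approx(-np.pi / 2)
        assert rp.phase[150] == pytest.approx(np.pi / 2)
        assert rp.phase[200] == -np.pi  # trough starts the next inspiration

    def test_undefined_outside_extrema(self):
        rp = physio.interpolate_phase(300, peak_idx=[100], trough_idx=[50, 150])
        assert np.all(~np.isfinite(rp.phase[:50]))
        assert np.all(~np.isfinite(rp.phase[151:]))

    def test_non_alternating_raises(self):
        with pytest.raises(ValueError):
            physio.interpolate_phase(100, peak_idx=[10, 20], trough_idx=[50])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.integers(5, 40), min_size=3, max_size=10))
    def test_phase_monotone_within_half_cycles(self, gaps):
        """Phase rises strictly within each half-cycle for any extrema set."""
        idx = np.cumsum([0] + gaps)
        troughs = idx[::2]
        peaks = idx[1::2]
        rp = physio.interpolate_phase(int(idx[-1]) + 1, peaks, troughs)
        for i0, i1 in zip(idx[:-1], idx[1:]):
            seg = rp.phase[i0:i1]
            assert np.all(np.diff(seg) > 0)


class TestPhaseAtEvents:
    def test_events_at_landmarks(self):
        rp = physio.interpolate_phase(201, peak_idx=[100], trough_idx=[0, 200])
        out = physio.phase_at_events(rp, [100, 50])
        np.testing.assert_allclose(out, [0.0, -np.pi / 2])

    def test_undefined_event_is_nan(self):
        rp = physio.interpolate_phase(300, peak_idx=[100], trough_idx=[50, 150])
        out = physio.phase_at_events(rp, [10, 100])
        assert np.isnan(out[0]) and out[1] == 0.0

    def test_uniform_events_give_uniform_phases(self):
        sig, _ = gen_respiration(2100, rate=15, cycle_jitter=0.0,
                                 amp_jitter=0.0, sigh_prob=0.0, seed=0)
        clean = physio.normalize_and_clip(sig)
        peaks, troughs = physio.detect_extrema(clean)
        rp = physio.interpolate_phase(len(clean), peaks, troughs)
        rng = np.random.default_rng(8)
        events = rng.integers(peaks[0], peaks[-1], 500)
        phases = physio.phase_at_events(rp, events)
        _, p = rayleigh_test(phases[np.isfinite(phases)])
        assert p > 0.05


class TestBreathingRate:
    @pytest.mark.parametrize("peaks_s, expected", [
        ([0, 4, 8, 12], 15.0),
        ([0, 3, 5], 24.0),
    ])
    def test_examples(self, peaks_s, expected):
        fs = 10.0
        idx = (np.asarray(peaks_s) * fs).astype(int)
        assert physio.breathing_rate(idx, fs) == pytest.approx(expected)

    def test_round_trip_exact(self):
        sig, _ = gen_respiration(305, rate=12, cycle_jitter=0.0,
                                 amp_jitter=0.0, sigh_prob=0.0, seed=0)
        clean = physio.normalize_and_clip(sig)
        peaks, _ = physio.detect_extrema(clean)
        assert physio.breathing_rate(peaks, sig.fs) == pytest.approx(12.0, abs=1e-6)

    def test_too_few_peaks(self):
        with pytest.raises(ValueError):
            physio.breathing_rate([10], 100.0)


class TestPupil:
    def test_area_to_diameter(self):
        assert physio.area_to_diameter(np.pi) == pytest.approx(2.0)

    def test_output_is_robust_zscored(self):
        area, _ = gen_pupil(120, blink_rate=8, seed=3)
        out = physio.preprocess_pupil(area)
        assert np.median(out.samples) == pytest.approx(0.0, abs=1e-9)
        mad = np.median(np.abs(out.samples - np.median(out.samples)))
        assert 1.4826 * mad == pytest.approx(1.0, abs=1e-9)

    def test_blink_recovery(self):
        area, truth = gen_pupil(300, blink_rate=15, seed=6)
        out = physio.preprocess_pupil(area)
        inserted = truth["blink_onsets_s"].size
        assert inserted > 0
        assert out.extra["n_blinks"] >= 0.9 * inserted

    def test_no_dropouts_survive(self):
        area, truth = gen_pupil(200, blink_rate=15, seed=9)
        clean_diam = physio.preprocess_pupil(area, remove_blink_response=False)
        # raw trace has near-zero dropouts; the cleaned robust-z trace
        # must not retain excursions of that size
        assert clean_diam.samples.min() > -6

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            physio.preprocess_pupil(ContinuousSignal(np.ones(100), fs=10.0))
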