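import numpy as np
import pandas as pd
import pytest

from respsense import spectral
from respsense.circstats import phase_regression
from respsense.epochs import RoiEpochs
from respsense.synth import PowerModSpec, gen_roi_timeseries


def _epochs_from(data, fs=300.0, t0=-1.85):
    n_t = data.shape[-1]
    times = t0 + np.arange(n_t) / fs
    return RoiEpochs(data=data, fs=fs, times=times,
                     channel_rois=["A"] * data.shape[1])


class TestSegmentEpochs:
    def test_epoch_length(self):
        fs_in = 600.0
        x = np.random.default_rng(0).standard_normal((2, int(120 * fs_in)))
        ep = spectral.segment_epochs(x, fs_in, ["A", "B"], [10.0, 50.0, 100.0])
        assert ep.data.shape == (3, 2, 780)  # 2.6 s at 300 Hz

    def test_constant_input_preserved(self):
        x = np.full((1, 60000), 3.14)
        ep = spectral.segment_epochs(x, 600.0, ["A"], [20.0])
        np.testing.assert_allclose(ep.data, 3.14, atol=1e-6)

    def test_sinusoid_amplitude_after_resampling(self):
        fs_in = 600.0
        t = np.arange(int(60 * fs_in)) / fs_in
        x = np.sin(2 * np.pi * 10 * t)[None, :]
        ep = spectral.segment_epochs(x, fs_in, ["A"], [30.0])
        amp = np.sqrt(2) * ep.data.std()
        assert amp == pytest.approx(1.0, rel=0.01)

    def test_edge_trials_dropped(self):
        x = np.zeros((1, 3000))
        ep = spectral.segment_epochs(x, 300.0, ["A"], [0.5, 5.0, 9.9])
        assert ep.n_trials == 1
        np.testing.assert_array_equal(ep.trial_index, [1])


class TestDiscardInitialTrials:
    def test_paper_design_counts(self, full_design):
        out = spectral.discard_initial_trials(full_design, n=10)
        assert len(out) == 660

    def test_zero_is_identity(self, full_design):
        out = spectral.discard_initial_trials(full_design, n=0)
        pd.testing.assert_frame_equal(out, full_design.reset_index(drop=True))

    def test_order_preserved(self, full_design):
        out = spectral.discard_initial_trials(full_design, n=10)
        assert out.groupby("run")["trial"].apply(
            lambda s: s.is_monotonic_increasing).all()


class TestMotionGlm:
    def _motion(self, n=6000, seed=0):
        rng = np.random.default_rng(seed)
        from scipy.signal import butter, sosfiltfilt
        sos = butter(2, 0.02, output="sos")
        return sosfiltfilt(sos, rng.standard_normal((6, n)), axis=-1)

    def test_linear_coupling_removed(self):
        motion = self._motion()
        parcel = 0.5 * motion[2]
        resid = spectral.motion_glm_clean(parcel, motion)
        assert resid.std() < 0.01 * parcel.std()

    def test_orthogonal_signal_untouched(self):
        rng = np.random.default_rng(1)
        motion = self._motion(seed=2)
        parcel = rng.standard_normal(6000)
        resid = spectral.motion_glm_clean(parcel, motion)
        assert np.corrcoef(resid, parcel)[0, 1] > 0.99

    def test_quadratic_coupling_removed(self):
        motion = self._motion(seed=3)
        parcel = motion[0] ** 2
        resid = spectral.motion_glm_clean(parcel, motion)
        explained = 1 - resid.var() / parcel.var()
        assert explained > 0.95


class TestWhitening:
    def test_constant_becomes_zero(self):
        ep = _epochs_from(np.full((2, 1, 100), 5.0))
        out = spectral.whiten_derivative(ep)
        np.testing.assert_array_equal(out.data, 0.0)
        assert out.data.shape[-1] == 99

    def test_gain_closed_form(self):
        f = np.array([1.0, 10.0, 100.0])
        np.testing.assert_allclose(spectral.derivative_gain(f, 300.0),
                                   2 * np.sin(np.pi * f / 300.0))

    def test_flattens_aperiodic_component(self):
        """First-difference gain ~ f inverts a 1/f amplitude (1/f^2 power)
        aperiodic background over the analysis band."""
        rng = np.random.default_rng(4)
        n = 3000
        white = rng.standard_normal((20, 1, n))
        W = np.fft.rfft(white, axis=-1)
        f = np.fft.rfftfreq(n, 1 / 300.0)
        scale = np.zeros_like(f)
        scale[1:] = 1 / f[1:]
        pink = np.fft.irfft(W * scale, n=n, axis=-1)
        ep = _epochs_from(pink, t0=0.0)
        wh = spectral.whiten_derivative(ep)
        spec = spectral.multitaper_psd(wh, fmin=5, fmax=40, window=None)
        logp = np.log(spec.power.mean(axis=(0, 1)))
        slope = np.polyfit(np.log(spec.freqs), logp, 1)[0]
        assert abs(slope) < 0.3


class TestMultitaperPsd:
    def test_white_noise_flat_and_parseval(self):
        rng = np.random.default_rng(5)
        ep = _epochs_from(rng.standard_normal((50, 1, 600)), t0=0.0)
        spec = spectral.multitaper_psd(ep, fmin=1, fmax=149, window=None,
                                       smoothing_hz=2.0)
        mean_psd = spec.power.mean(axis=(0, 1))
        # integrated power approximates the unit variance
        total = np.trapezoid(mean_psd, spec.freqs)
        assert total == pytest.approx(1.0, rel=0.1)
        assert mean_psd.max() / mean_psd.min() < 2.0

    def test_sinusoid_peak_location(self):
        t = np.arange(480) / 300.0
        x = np.sin(2 * np.pi * 10 * t)[None, None, :]
        ep = _epochs_from(np.repeat(x, 3, axis=0), t0=-1.6)
        spec = spectral.multitaper_psd(ep, fmin=2, fmax=40)
        assert spec.freqs[np.argmax(spec.power[0, 0])] == pytest.approx(10, abs=1)

    def test_taper_count_convention(self):
        assert spectral.n_tapers_for(2.0, 480, 300.0) == 5  # NW = 3.2

    def test_too_small_smoothing_raises(self):
        ep = _epochs_from(np.random.default_rng(6).standard_normal((2, 1, 150)),
                          t0=0.0)
        with pytest.raises(ValueError, match="Hz"):
            spectral.multitaper_psd(ep, smoothing_hz=0.5, window=None)


class TestTfr:
    def test_amplitude_step_localised(self):
        fs = 300.0
        t = np.arange(780) / fs - 1.85
        carrier = np.sin(2 * np.pi * 10 * t)
        x = np.where(t > -0.5, carrier, 0.1 * carrier)[None, None, :]
        ep = _epochs_from(np.repeat(x, 2, axis=0))
        power, times = spectral.tfr_multitaper(ep, freqs=[10.0])
        p = power[0, 0, 0]
        early = p[(times > -1.5) & (times < -0.9)].mean()
        late = p[(times > -0.1) & (times < 0.5)].mean()
        assert late > 10 * early

    def test_zero_signal_zero_power(self):
        ep = _epochs_from(np.zeros((1, 1, 780)))
        power, _ = spectral.tfr_multitaper(ep, freqs=[8.0, 12.0])
        np.testing.assert_allclose(power, 0.0, atol=1e-20)


@pytest.fixture(scope="module")
def modulated():
    rng = np.random.default_rng(7)
    n = 600
    sched = pd.DataFrame({"trial": np.arange(n)})
    phases = rng.uniform(-np.pi, np.pi, n)
    ep, _ = gen_roi_timeseries(
        sched, phases,
        power_mod={"V1": PowerModSpec(f0=10, depth=0.2, phase=np.pi / 4)},
        rois=("V1",), seed=8)
    spec = spectral.multitaper_psd(ep, fmin=1, fmax=40)
    return spec, phases


class TestPhaseBinnedPower:
    def test_moving_mode_bookkeeping(self, modulated):
        spec, phases = modulated
        pb = spectral.phase_binned_power(spec, phases, n_bins=30, mode="moving")
        # window width / step = (pi/5) / (pi/15) = 3 windows per trial
        assert pb.n_per_bin.sum() == 3 * len(phases)

    def test_nonoverlap_partition(self, modulated):
        spec, phases = modulated
        pb = spectral.phase_binned_power(spec, phases, n_bins=30,
                                         mode="nonoverlap")
        assert pb.n_per_bin.sum() == len(phases)

    def test_depth_and_phase_recovery(self, modulated):
        spec, phases = modulated
        pb = spectral.phase_binned_power(spec, phases, n_bins=30, mode="moving")
        band = (pb.freqs >= 8) & (pb.freqs <= 12)
        prof = pb.power[:, band, :].mean(axis=(0, 1))
        fit = phase_regression(pb.bin_centres, prof)
        assert fit.amplitude / fit.b0 == pytest.approx(0.2, abs=0.05)
        err = np.abs(np.angle(np.exp(1j * (fit.preferred_phase - np.pi / 4))))
        assert np.degrees(err) <= 20
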