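"""Spectral estimation on ROI epochs.

Multitaper estimates use DPSS tapers; ``smoothing_hz`` throughout is the
one-sided spectral smoothing (+/- around each frequency), i.e. the
FieldTrip ``tapsmofrq`` convention, corresponding to a full taper bandwidth
of twice that value. Aperiodic (1/f) activity is suppressed by first-order
derivative whitening: the first difference acts as a high-pass time-domain
filter with gain 2*sin(pi*f/fs), approximately inverting a 1/f amplitude
spectrum below Nyquist.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from mne.time_frequency import psd_array_multitaper, tfr_array_multitaper
from scipy import signal as sps

from .circstats import bin_by_phase, moving_window_membership, phase_bin_centres
from .epochs import RoiEpochs

logger = logging.getLogger(__name__)

#: epoch segmentation window around target onset, seconds
EPOCH_WINDOW = (-1.85, 0.75)
#: prestimulus analysis window, seconds
PRESTIM_WINDOW = (-1.6, 0.0)
#: common resampling rate for neural and respiratory traces, Hz
FS_TARGET = 300.0


# --------------------------------------------------------------------------
# segmentation and trial bookkeeping
# --------------------------------------------------------------------------

def segment_epochs(signals: np.ndarray, fs_in: float, channel_rois: list,
                   target_onsets_s, window: tuple = EPOCH_WINDOW,
                   fs_out: float = FS_TARGET,
                   trial_index=None) -> RoiEpochs:
    """Cut continuous per-ROI series into target-locked epochs.

    The continuous data are resampled to ``fs_out`` with a polyphase
    anti-aliasing filter, then windowed to ``window`` around each onset.
    Onsets whose window falls outside the recording are dropped and logged.
    """
    signals = np.atleast_2d(np.asarray(signals, float))
    onsets = np.asarray(target_onsets_s, float)
    if trial_index is None:
        trial_index = np.arange(onsets.size)
    trial_index = np.asarray(trial_index)

    if fs_out != fs_in:
        frac = Fraction(fs_out / fs_in).limit_denominator(1000)
        signals = sps.resample_poly(signals, frac.numerator, frac.denominator,
                                    axis=-1)
    n_samp = int(round((window[1] - window[0]) * fs_out))
    times = window[0] + np.arange(n_samp) / fs_out

    epochs, kept = [], []
    for i, onset in enumerate(onsets):
        start = int(round((onset + window[0]) * fs_out))
        stop = start + n_samp
        if start < 0 or stop > signals.shape[-1]:
            logger.warning("trial %d dropped: window outside recording", i)
            continue
        epochs.append(signals[:, start:stop])
        kept.append(i)
    if not epochs:
        raise ValueError("no trial window fits inside the recording")
    return RoiEpochs(data=np.stack(epochs), fs=fs_out, times=times,
                     channel_rois=list(channel_rois),
                     trial_index=trial_index[kept])


def discard_initial_trials(trials: pd.DataFrame, n: int = 10,
                           run_col: str = "run") -> pd.DataFrame:
    """Drop the first ``n`` trials of each run (staircase initiation)."""
    if run_col not in trials.columns:
        raise ValueError(f"missing {run_col!r} column")
    keep = trials.groupby(run_col, sort=False).cumcount() >= n
    for run, g in trials.groupby(run_col):
        if len(g) <= n:
            warnings.warn(f"run {run} has <= {n} trials; nothing remains")
    return trials.loc[keep].reset_index(drop=True)


# --------------------------------------------------------------------------
# head-motion GLM cleanup
# --------------------------------------------------------------------------

def motion_glm_clean(parcel_ts: np.ndarray, motion6: np.ndarray,
                     poly_order: int = 3) -> np.ndarray:
    """Regress head-movement signals out of parcel time courses.

    The design holds the six rigid-body coordinates plus their temporal
    derivatives (12 signals), each expanded to polynomial orders 1-3
    (36 movement regressors), alongside a polynomial drift basis of order
    ``poly_order``. Returns the residual time courses.
    """
    y = np.atleast_2d(np.asarray(parcel_ts, float))
    motion = np.asarray(motion6, float)
    if motion.shape[0] != 6:
        raise ValueError("motion6 must be (6, n_times)")
    if motion.shape[1] != y.shape[1]:
        raise ValueError("motion signals must align with the data")

    deriv = np.gradient(motion, axis=1)
    base = np.vstack([motion, deriv])  # 12 signals
    base = (base - base.mean(axis=1, keepdims=True))
    sd = base.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    base = base / sd
    regs = [base**order for order in (1, 2, 3)]  # 36 regressors
    t = np.linspace(-1, 1, y.shape[1])
    drift = np.vstack([np.polynomial.legendre.Legendre.basis(d)(t)
                       for d in range(poly_order + 1)])
    X = np.vstack([np.vstack(regs), drift]).T

    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("rank-deficient motion design; using ridge fallback")
        lam = 1e-6 * np.trace(X.T @ X) / X.shape[1]
        beta = np.linalg.solve(X.T @ X + lam * np.eye(X.shape[1]), X.T @ y.T)
    else:
        beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    resid = y - (X @ beta).T
    return resid if np.asarray(parcel_ts).ndim > 1 else resid[0]


# --------------------------------------------------------------------------
# whitening and multitaper spectra
# --------------------------------------------------------------------------

def whiten_derivative(epochs: RoiEpochs) -> RoiEpochs:
    """First-difference whitening per trial and channel.

    Epoch length shrinks by one sample; the time axis drops its first
    point. The filter gain at frequency f is ``2 sin(pi f / fs)``.
    """
    if epochs.data.shape[-1] < 2:
        raise ValueError("epochs too short to difference")
    return RoiEpochs(data=np.diff(epochs.data, axis=-1), fs=epochs.fs,
                     times=epochs.times[1:], channel_rois=list(epochs.channel_rois),
                     trial_index=epochs.trial_index)


def derivative_gain(f, fs: float):
    """Magnitude response of the first-difference filter."""
    return 2.0 * np.sin(np.pi * np.asarray(f, float) / fs)


@dataclass
class SpectrumSet:
    """Per-trial multitaper power spectra (trials, channels, freqs)."""

    power: np.ndarray
    freqs: np.ndarray
    channel_rois: list
    trial_index: np.ndarray
    smoothing_hz: float

    @property
    def rois(self) -> list:
        seen = []
        for r in self.channel_rois:
            if r not in seen:
                seen.append(r)
        return seen

    def roi_power(self, roi: str) -> np.ndarray:
        """(trials, freqs) power averaged over the channels of one ROI."""
        idx = [i for i, r in enumerate(self.channel_rois) if r == roi]
        if not idx:
            raise KeyError(f"unknown ROI {roi!r}")
        return self.power[:, idx, :].mean(axis=1)


def n_tapers_for(smoothing_hz: float, n_times: int, fs: float) -> int:
    """floor(2 NW) - 1 for time-half-bandwidth NW = smoothing_hz * T."""
    nw = smoothing_hz * n_times / fs
    return int(2 * nw) - 1


def multitaper_psd(epochs: RoiEpochs, fmin: float = 1.0, fmax: float = 40.0,
                   smoothing_hz: float = 2.0,
                   window: tuple | None = PRESTIM_WINDOW) -> SpectrumSet:
    """Per-trial DPSS multitaper power spectral density.

    ``smoothing_hz`` is the one-sided smoothing; the number of tapers is
    floor(2 NW) - 1 with NW = smoothing_hz * T. Raises if the window is too
    short for a single taper at the requested smoothing.
    """
    ep = epochs if window is None else epochs.crop(*window)
    n_times = ep.data.shape[-1]
    if n_tapers_for(smoothing_hz, n_times, ep.fs) < 1:
        min_s = ep.fs / n_times  # NW >= 1  <=>  smoothing >= fs / n_times
        raise ValueError(
            f"smoothing {smoothing_hz} Hz too small for a {n_times / ep.fs:.3g} s "
            f"window; need at least {min_s:.3g} Hz")
    psd, freqs = psd_array_multitaper(
        ep.data, sfreq=ep.fs, fmin=fmin, fmax=fmax,
        bandwidth=2 * smoothing_hz, low_bias=False, adaptive=False,
        normalization="full", verbose="error")
    return SpectrumSet(power=psd, freqs=freqs,
                       channel_rois=list(ep.channel_rois),
                       trial_index=ep.trial_index, smoothing_hz=smoothing_hz)


def tfr_multitaper(epochs: RoiEpochs, freqs, n_cycles=None,
                   time_bandwidth: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window multitaper time-frequency power.

    Returns (power, times) with power shaped
    (trials, channels, freqs, times).
    """
    freqs = np.asarray(freqs, float)
    if n_cycles is None:
        n_cycles = np.maximum(freqs / 2.0, 3.0)
    power = tfr_array_multitaper(
        epochs.data, sfreq=epochs.fs, freqs=freqs, n_cycles=n_cycles,
        time_bandwidth=time_bandwidth, output="power", verbose="error")
    return power, epochs.times


# --------------------------------------------------------------------------
# phase-binned power
# --------------------------------------------------------------------------

@dataclass
class PhaseBinnedSpectra:
    """ROI/channel x frequency x respiration-phase-bin mean power."""

    power: np.ndarray
    freqs: np.ndarray
    bin_centres: np.ndarray
    n_per_bin: np.ndarray
    channel_rois: list


def phase_binned_power(spectra: SpectrumSet, phases, n_bins: int = 30,
                       mode: str = "moving",
                       half_width: float = np.pi / 10) -> PhaseBinnedSpectra:
    """Mean power spectrum per respiration-phase bin.

    ``mode="moving"``: overlapping windows of half-width pi/10 at ``n_bins``
    equally spaced centres (each trial contributes to
    window-width / step windows). ``mode="nonoverlap"``: equal partition of
    the circle, each trial in exactly one bin. Empty bins yield NaN and are
    logged.
    """
    phases = np.asarray(phases, float)
    if phases.size != spectra.power.shape[0]:
        raise ValueError("need one phase per trial")
    centres = phase_bin_centres(n_bins)
    ok = np.isfinite(phases)
    if mode == "moving":
        member = np.zeros((n_bins, phases.size), bool)
        member[:, ok] = moving_window_membership(phases[ok], centres, half_width)
    elif mode == "nonoverlap":
        member = np.zeros((n_bins, phases.size), bool)
        idx = bin_by_phase(phases[ok], n_bins)
        member[idx, np.flatnonzero(ok)] = True
    else:
        raise ValueError("mode must be 'moving' or 'nonoverlap'")

    n_ch, n_f = spectra.power.shape[1:]
    out = np.full((n_ch, n_f, n_bins), np.nan)
    n_per = member.sum(axis=1)
    for k in range(n_bins):
        if n_per[k] == 0:
            logger.warning("phase bin %d empty", k)
            continue
        out[:, :, k] = spectra.power[member[k]].mean(axis=0)
    return PhaseBinnedSpectra(power=out, freqs=spectra.freqs,
                              bin_centres=centres, n_per_bin=n_per,
                              channel_rois=list(spectra.channel_rois))
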