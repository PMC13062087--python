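"""Respiration and pupil preprocessing, and respiratory phase extraction.

The respiratory phase convention used throughout the package: the trough
(start of inspiration) carries phase -pi, peak inspiration carries phase 0,
and expiration spans 0 -> pi, approached from below. Phase is linearly
interpolated within each half-cycle, so it is piecewise linear in time and
exactly single-valued at the extrema. Samples before the first and after
the last detected extremum have no defined phase and are marked NaN.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal import ContinuousSignal

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# normalisation and artefact clipping
# --------------------------------------------------------------------------

def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("constant signal cannot be z-scored")
    return (x - x.mean()) / sd


def _interpolate_runs(x: np.ndarray, bad: np.ndarray) -> np.ndarray:
    """Linearly interpolate contiguous runs of ``bad`` samples.

    Runs are anchored at the nearest retained sample on each side; runs
    touching a recording edge are filled with the nearest retained value.
    """
    if bad.all():
        raise ValueError("entire trace exceeds the clipping threshold")
    out = x.copy()
    idx = np.arange(x.size)
    out[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return out


def normalize_and_clip(signal: ContinuousSignal, clip_z: float = 2.5,
                       max_passes: int = 20) -> ContinuousSignal:
    """z-score a trace and clip high-amplitude excursions (e.g. sighs).

    Contiguous runs with \\|z\\| > ``clip_z`` are replaced by linear
    interpolation between the flanking retained samples, so that unusually
    high-amplitude breaths do not bias subsequent peak detection. Because
    interpolation changes mean and variance, the z-score/clip pass is
    repeated until no sample exceeds the threshold; the returned trace is a
    fixed point of the operation (applying it again is the identity).
    """
    if len(signal) < 3:
        raise ValueError("signal too short to normalise")
    x = _zscore(signal.samples)
    for _ in range(max_passes):
        bad = np.abs(x) > clip_z
        if not bad.any():
            break
        x = _zscore(_interpolate_runs(x, bad))
    else:  # pragma: no cover - pathological traces only
        warnings.warn("clipping did not converge; residual excursions remain")
    return signal.copy_with(samples=x, units="z")


# --------------------------------------------------------------------------
# extrema detection and phase interpolation
# --------------------------------------------------------------------------

def detect_extrema(signal: ContinuousSignal, min_prominence: float = 1.0):
    """Detect inspiratory peaks and expiratory troughs.

    Peaks are found on the normalised trace and troughs on its negation,
    both with a minimum prominence criterion (default 1 z-unit). The merged
    sequence is forced to alternate: of two consecutive same-type extrema
    the more extreme one is kept.

    Returns
    -------
    (peak_idx, trough_idx) : tuple of int arrays
    """
    x = signal.samples
    peaks, _ = sps.find_peaks(x, prominence=min_prominence)
    troughs, _ = sps.find_peaks(-x, prominence=min_prominence)
    if peaks.size == 0 and troughs.size == 0:
        raise ValueError("no extrema found at the requested prominence")

    # merge and enforce alternation
    kind = np.concatenate([np.ones(peaks.size, int), np.zeros(troughs.size, int)])
    idx = np.concatenate([peaks, troughs])
    order = np.argsort(idx)
    idx, kind = idx[order], kind[order]
    keep_idx: list[int] = []
    keep_kind: list[int] = []
    for i, k in zip(idx, kind):
        if keep_kind and keep_kind[-1] == k:
            prev = keep_idx[-1]
            better = x[i] > x[prev] if k == 1 else x[i] < x[prev]
            if better:
                keep_idx[-1] = int(i)
        else:
            keep_idx.append(int(i))
            keep_kind.append(int(k))
    keep_idx_arr = np.array(keep_idx)
    keep_kind_arr = np.array(keep_kind)
    return keep_idx_arr[keep_kind_arr == 1], keep_idx_arr[keep_kind_arr == 0]


@dataclass
class RespPhase:
    """Respiratory phase vector with the extrema that define it.

    ``phase`` has one angle per signal sample, NaN where undefined (before
    the first / after the last extremum). Phase is -pi at troughs, 0 at
    peaks, and lies in [-pi, pi).
    """

    phase: np.ndarray
    peak_idx: np.ndarray
    trough_idx: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.phase)


def interpolate_phase(signal_len: int, peak_idx: np.ndarray,
                      trough_idx: np.ndarray) -> RespPhase:
    """Linear phase ramps per half-cycle: trough->peak maps to -pi..0 and
    peak->trough maps to 0..pi (exclusive of the trough, which starts the
    next inspiration at -pi)."""
    peak_idx = np.asarray(peak_idx, int)
    trough_idx = np.asarray(trough_idx, int)
    kind = np.concatenate([np.ones(peak_idx.size, int), np.zeros(trough_idx.size, int)])
    idx = np.concatenate([peak_idx, trough_idx])
    order = np.argsort(idx)
    idx, kind = idx[order], kind[order]
    if idx.size < 2:
        raise ValueError("need at least one trough-peak pair")
    if np.any(kind[1:] == kind[:-1]):
        raise ValueError("extrema must alternate between peaks and troughs")

    phase = np.full(signal_len, np.nan)
    for (i0, k0), (i1, _k1) in zip(zip(idx[:-1], kind[:-1]), zip(idx[1:], kind[1:])):
        seg = np.arange(i0, i1)
        frac = (seg - i0) / (i1 - i0)
        if k0 == 0:  # trough -> peak: -pi .. 0
            phase[seg] = -np.pi + np.pi * frac
        else:  # peak -> trough: 0 .. pi (trough itself excluded)
            phase[seg] = np.pi * frac
    # last extremum gets its defining value
    phase[idx[-1]] = 0.0 if kind[-1] == 1 else -np.pi
    return RespPhase(phase=phase, peak_idx=peak_idx, trough_idx=trough_idx)


def phase_at_events(phase: RespPhase, event_samples) -> np.ndarray:
    """Respiratory phase angle at each event sample.

    Events falling in the undefined region (before the first or after the
    last extremum) are returned as NaN and logged.
    """
    ev = np.asarray(event_samples, int)
    if np.any(ev < 0) or np.any(ev >= phase.phase.size):
        raise IndexError("event sample outside the signal")
    out = phase.phase[ev]
    n_missing = int(np.sum(~np.isfinite(out)))
    if n_missing:
        logger.warning("%d events fall outside the defined phase range", n_missing)
    return out


def breathing_rate(peak_idx: np.ndarray, fs: float) -> float:
    """Breathing rate in breaths/min from the mean inter-peak interval."""
    peak_idx = np.asarray(peak_idx)
    if peak_idx.size < 2:
        raise ValueError("need at least two peaks to estimate a rate")
    mean_interval_s = np.mean(np.diff(peak_idx)) / fs
    return 60.0 / mean_interval_s


# --------------------------------------------------------------------------
# pupil preprocessing
# --------------------------------------------------------------------------

def area_to_diameter(area: np.ndarray) -> np.ndarray:
    """Convert pupil area to diameter, ``d = 2*sqrt(area/pi)``."""
    return 2.0 * np.sqrt(np.clip(np.asarray(area, float), 0.0, None) / np.pi)


def robust_zscore(x: np.ndarray) -> np.ndarray:
    """(x - median) / (1.4826 * MAD)."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise ValueError("zero MAD; cannot robust-z-score")
    return (x - med) / (1.4826 * mad)


def detect_blinks(x: np.ndarray, fs: float, floor: float | None = None,
                  vel_z: float = 6.0, pad_s: float = 0.1) -> np.ndarray:
    """Boolean blink mask: dropout floor plus a velocity criterion, padded.

    ``floor`` defaults to 30% of the median trace value (lid closure cuts
    the measured pupil to a small fraction of its size); samples at or
    below it, and samples whose first difference exceeds ``vel_z`` robust
    z-units, are flagged and the mask is dilated by ``pad_s`` seconds on
    each side.
    """
    if floor is None:
        floor = 0.3 * np.median(x)
    bad = x <= floor
    vel = np.diff(x, prepend=x[0])
    mad = np.median(np.abs(vel - np.median(vel)))
    if mad > 0:
        bad |= np.abs(vel - np.median(vel)) > vel_z * 1.4826 * mad
    pad = int(round(pad_s * fs))
    if pad > 0 and bad.any():
        kernel = np.ones(2 * pad + 1)
        bad = np.convolve(bad.astype(float), kernel, mode="same") > 0
    return bad


def _double_gamma(t: np.ndarray, t1: float, t2: float) -> np.ndarray:
    h = (t / t1) ** 4 * np.exp(-t / t1) - 0.4 * (t / t2) ** 4 * np.exp(-t / t2)
    return h / np.max(np.abs(h))


def _remove_blink_response(x: np.ndarray, fs: float, onsets: np.ndarray) -> np.ndarray:
    """Regress out a canonical blink response (double-gamma kernel, duration
    fitted coarsely per recording) convolved with the blink onset train."""
    if onsets.size == 0:
        return x
    impulses = np.zeros_like(x)
    impulses[onsets] = 1.0
    t = np.arange(int(2.0 * fs)) / fs + 1e-3
    best = None
    for t1 in (0.2, 0.3, 0.5):
        kern = _double_gamma(t, t1, 2.5 * t1)
        reg = np.convolve(impulses, kern)[: x.size]
        design = np.column_stack([np.ones_like(x), reg])
        beta, res, *_ = np.linalg.lstsq(design, x, rcond=None)
        rss = res[0] if res.size else np.sum((x - design @ beta) ** 2)
        if best is None or rss < best[0]:
            best = (rss, design @ np.array([0.0, beta[1]]))
    return x - best[1]


def preprocess_pupil(area: ContinuousSignal, *, blink_floor: float | None = None,
                     second_pass_z: float = 6.0, band: tuple = (0.01, 10.0),
                     remove_blink_response: bool = True) -> ContinuousSignal:
    """Standard pupillometry cleanup chain.

    Steps: area -> diameter conversion (``d = 2*sqrt(area/pi)``, linearising
    the size measure); blink detection and linear interpolation; a second,
    relaxed artefact pass at ``second_pass_z`` robust z-units; optional
    removal of the canonical blink response; zero-phase (two-pass) 2nd-order
    Butterworth band-pass 0.01-10 Hz; robust z-scoring (median/MAD).
    """
    if area.fs <= 20:
        raise ValueError("pupil preprocessing expects fs > 20 Hz")
    diameter = area_to_diameter(area.samples)

    bad = detect_blinks(diameter, area.fs, floor=blink_floor)
    if bad.mean() > 0.5:
        raise ValueError("more than 50% of samples flagged as blink")
    onsets = np.flatnonzero(np.diff(bad.astype(int), prepend=0) == 1)
    x = _interpolate_runs(diameter, bad) if bad.any() else diameter

    # relaxed second artefact pass on the blink-interpolated trace
    z = robust_zscore(x)
    bad2 = np.abs(z) > second_pass_z
    if bad2.any() and not bad2.all():
        x = _interpolate_runs(x, bad2)

    if remove_blink_response:
        x = _remove_blink_response(x, area.fs, onsets)

    nyq = area.fs / 2
    sos = sps.butter(2, [band[0] / nyq, band[1] / nyq], btype="band", output="sos")
    x = sps.sosfiltfilt(sos, x)
    x = robust_zscore(x)
    return area.copy_with(samples=x, units="z",
                          extra={**area.extra, "n_blinks": int(onsets.size)})
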