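"""Synthetic session generator with known ground truth.

Every generator emulates one component of a cued near-threshold detection
experiment — quasi-periodic respiration, a 2x2 cue/timing trial design, a
detection observer whose threshold is sinusoidally modulated by respiratory
phase, QUEST-controlled contrast, phase-modulated ROI oscillations over a
1/f background with optional phase-dependent directed VAR coupling, and a
pupil trace with blinks — and emits its ground-truth parameters alongside
the data so that every downstream estimator can be validated by parameter
recovery. All generators are deterministic given (parameters, seed).

Respiratory phase convention matches the analysis side: trough (start of
inspiration) = -pi, peak inspiration = 0, expiration spans 0 -> pi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circstats import wrap_angle
from .epochs import RoiEpochs
from .psychometrics import (GUESS_RATE_3AFC, QuestState, psychometric,
                            quest_propose, quest_update)
from .signal import ContinuousSignal

CONDITIONS = ("C+T+", "C+T-", "C-T+", "C-T-")


# --------------------------------------------------------------------------
# trial design
# --------------------------------------------------------------------------

@dataclass
class DesignSpec:
    """2x2 cue (C) x timing (T) design.

    Defaults reproduce the experiment geometry: 6 runs of 120 trials
    (30 per condition per run, 180 per condition overall), 1600 ms
    fixation, 50 ms target, 500 ms response delay.
    """

    n_runs: int = 6
    per_condition_per_run: int = 30
    fixation_ms: float = 1600.0
    target_ms: float = 50.0
    delay_ms: float = 500.0
    inter_trial_ms: tuple = (1200.0, 2200.0)
    seed: int = 0

    @property
    def trials_per_run(self) -> int:
        return 4 * self.per_condition_per_run


def gen_design(spec: DesignSpec) -> pd.DataFrame:
    """Generate a randomised, balanced trial schedule.

    Within each run, every condition appears ``per_condition_per_run``
    times with left/right target sides balanced exactly; trial order is
    shuffled within run. Onset times accrue continuously across the
    session (runs are concatenated). Raises if the per-condition count is
    odd (sides could not balance).
    """
    if spec.n_runs <= 0 or spec.per_condition_per_run <= 0:
        raise ValueError("counts must be positive")
    if spec.per_condition_per_run % 2:
        raise ValueError("per_condition_per_run must be even to balance sides")
    rng = np.random.default_rng(spec.seed)

    rows = []
    t = 0.0
    trial_id = 0
    for run in range(spec.n_runs):
        conds, sides = [], []
        for cond in CONDITIONS:
            half = spec.per_condition_per_run // 2
            conds += [cond] * spec.per_condition_per_run
            sides += ["left"] * half + ["right"] * half
        order = rng.permutation(len(conds))
        for k in order:
            fix_onset = t
            target_onset = fix_onset + spec.fixation_ms / 1000.0
            rows.append({
                "run": run, "trial": trial_id, "condition": conds[k],
                "cued": conds[k][1] == "+", "timed": conds[k][3] == "+",
                "side": sides[k], "fix_onset_s": fix_onset,
                "target_onset_s": target_onset,
            })
            iti = rng.uniform(*spec.inter_trial_ms) / 1000.0
            t = target_onset + (spec.target_ms + spec.delay_ms) / 1000.0 + iti
            trial_id += 1
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# respiration
# --------------------------------------------------------------------------

def gen_respiration(duration: float, fs: float = 300.0, rate: float = 15.0,
                    cycle_jitter: float = 0.08, amp_jitter: float = 0.1,
                    sigh_prob: float = 0.02, seed: int = 0):
    """Quasi-periodic respiration belt trace.

    Each cycle is one period of ``-amp * cos`` (trough at cycle start =
    onset of inspiration), with log-normal jitter on period and amplitude.
    With probability ``sigh_prob`` a cycle becomes a sigh: its amplitude is
    scaled by a factor drawn from U(2.5, 3), producing excursions beyond
    z = 2.5 after normalisation (the case the clipping step exists for).

    Returns
    -------
    signal : ContinuousSignal
    truth : dict
        Ground truth with ``phase`` (per-sample respiratory phase in the
        package convention), ``peak_times_s``, ``trough_times_s``,
        ``sigh_cycle`` flags, and the configured parameters.
    """
    if rate <= 0:
        raise ValueError("breathing rate must be positive")
    if fs <= 2 * rate / 60:
        raise ValueError("sampling rate too low for the breathing rate")
    base_period = 60.0 / rate
    if duration <= base_period:
        raise ValueError("duration must exceed one breathing cycle")
    rng = np.random.default_rng(seed)

    n = int(round(duration * fs))
    tt = np.arange(n) / fs
    samples = np.zeros(n)
    phase = np.full(n, np.nan)
    trough_times, peak_times, sighs = [], [], []
    t0 = 0.0
    while t0 < duration:
        period = base_period * (np.exp(rng.normal(0.0, cycle_jitter))
                                if cycle_jitter > 0 else 1.0)
        amp = np.exp(rng.normal(0.0, amp_jitter)) if amp_jitter > 0 else 1.0
        is_sigh = sigh_prob > 0 and rng.random() < sigh_prob
        if is_sigh:
            amp *= rng.uniform(2.5, 3.0)
        i0 = int(np.ceil(t0 * fs))
        i1 = min(int(np.ceil((t0 + period) * fs)), n)
        if i1 > i0:
            u = (tt[i0:i1] - t0) / period  # cycle fraction in [0, 1)
            samples[i0:i1] = -amp * np.cos(2 * np.pi * u)
            phase[i0:i1] = wrap_angle(2 * np.pi * u - np.pi)
        trough_times.append(t0)
        peak_times.append(t0 + period / 2)
        sighs.append(bool(is_sigh))
        t0 += period

    truth = {
        "phase": phase,
        "trough_times_s": np.array(trough_times),
        "peak_times_s": np.array([p for p in peak_times if p < duration]),
        "sigh_cycle": np.array(sighs),
        "rate_bpm": rate, "cycle_jitter": cycle_jitter,
        "amp_jitter": amp_jitter, "sigh_prob": sigh_prob,
    }
    return ContinuousSignal(samples=samples, fs=fs, units="a.u."), truth


# --------------------------------------------------------------------------
# observer and behavioural session
# --------------------------------------------------------------------------

@dataclass
class ObserverModel:
    """Cumulative-Gaussian detection observer with a respiration-phase-
    modulated threshold.

    The effective threshold is ``m(theta) = m0 - A cos(theta - phi0)``:
    ``phi0`` is the respiratory phase of maximal sensitivity (lowest
    threshold), default late inspiration (-pi/3), and ``A`` the modulation
    amplitude in contrast units. Contrast is dimensionless in [0, 1].
    """

    guess_rate: float = GUESS_RATE_3AFC
    lapse_rate: float = 0.02
    base_threshold: float = 0.5
    slope: float = 0.15
    mod_amplitude: float = 0.1
    mod_phase: float = -np.pi / 3

    def __post_init__(self):
        if not 0 <= self.guess_rate < 1:
            raise ValueError("guess rate must be in [0, 1)")
        if not 0 <= self.lapse_rate < 0.5:
            raise ValueError("lapse rate must be in [0, 0.5)")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if self.base_threshold - abs(self.mod_amplitude) <= 0:
            raise ValueError("effective threshold must stay positive")

    def threshold_at(self, theta) -> np.ndarray:
        return self.base_threshold - self.mod_amplitude * np.cos(
            np.asarray(theta, float) - self.mod_phase)

    def p_hit(self, contrast, theta) -> np.ndarray:
        return psychometric(contrast, self.threshold_at(theta), self.slope,
                            self.guess_rate, self.lapse_rate)


def simulate_session(schedule: pd.DataFrame, phase_at_target: np.ndarray,
                     observer: ObserverModel | None = None,
                     quest_cfg: dict | None = None, seed: int = 0):
    """Run the observer through a QUEST-controlled session.

    One staircase spans the whole session; each trial's contrast is the
    QUEST proposal, the outcome is Bernoulli under the observer's
    phase-dependent psychometric function, and the staircase is updated
    with the outcome.

    Returns (trial table, truth dict). The trial table carries run,
    condition, side, contrast, hit and ``phase_rad`` (respiratory phase at
    target onset).
    """
    observer = observer or ObserverModel()
    phases = np.asarray(phase_at_target, float)
    if phases.size != len(schedule):
        raise ValueError("phase must be defined at every target onset")
    if np.any(~np.isfinite(phases)):
        raise ValueError("phase must be defined at every target onset")
    rng = np.random.default_rng(seed)
    cfg = dict(quest_cfg or {})
    target_p = cfg.pop("target_p", 0.60)
    state = QuestState.initialize(gamma=observer.guess_rate,
                                  target_p=target_p, **cfg)

    out = schedule.copy().reset_index(drop=True)
    contrasts = np.zeros(len(out))
    hits = np.zeros(len(out), bool)
    for i in range(len(out)):
        c = min(quest_propose(state), 1.0)
        p = float(observer.p_hit(c, phases[i]))
        hit = bool(rng.random() < p)
        state = quest_update(state, c, hit)
        contrasts[i] = c
        hits[i] = hit
    out["contrast"] = contrasts
    out["hit"] = hits.astype(int)
    out["phase_rad"] = phases
    truth = {
        "observer": observer, "target_p": target_p,
        "quest_final_threshold": state.mean_threshold,
    }
    return out, truth


# --------------------------------------------------------------------------
# ROI time series
# --------------------------------------------------------------------------

@dataclass
class PowerModSpec:
    """Respiration-phase modulation of band-limited oscillatory power.

    Oscillation variance follows ``P0 * (1 + depth * cos(theta - phase))``
    with the phase taken at target onset (trials are later sorted by that
    angle, so modulating the whole epoch by the onset phase matches the
    analysis logic).
    """

    f0: float = 10.0
    depth: float = 0.2
    phase: float = 0.0
    pole_radius: float = 0.95

    def __post_init__(self):
        if not 0 <= self.depth < 1:
            raise ValueError("modulation depth must be in [0, 1) "
                             "(depth >= 1 gives negative power)")


@dataclass
class CouplingSpec:
    """Phase-dependent directed VAR coupling between two ROI blocks.

    The first component of the source ROI drives the first component of
    the target ROI at lag 1 with coefficient ``strength * gain(theta)``;
    ``gain`` must be nonnegative and 2*pi-periodic (default
    ``1 + cos(theta - gain_phase)``). ``direction`` is ``"a->b"`` or
    ``"b->a"``. The VAR order is 2 (the within-channel resonances), with
    the coupling injected in the cross-term only.
    """

    roi_a: str = "INS"
    roi_b: str = "TPJ"
    direction: str = "a->b"
    f0: float = 20.0
    pole_radius: float = 0.95
    strength: float = 0.15
    gain_phase: float = 0.0
    gain: object = None

    def gain_at(self, theta) -> np.ndarray:
        if self.gain is not None:
            g = np.asarray(self.gain(theta), float)
        else:
            g = 1.0 + np.cos(np.asarray(theta, float) - self.gain_phase)
        if np.any(g < -1e-12):
            raise ValueError("gain(theta) must be nonnegative")
        return np.clip(g, 0.0, None)


def _ar2_coeffs(f0: float, r: float, fs: float) -> tuple[float, float]:
    w = 2 * np.pi * f0 / fs
    return 2 * r * np.cos(w), -r * r


def _oneoverf_noise(rng, shape, fs):
    """1/f-amplitude noise, unit variance, along the last axis."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    W = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, 1 / fs)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    x = np.fft.irfft(W * scale, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def gen_roi_timeseries(schedule: pd.DataFrame, phase_at_target: np.ndarray,
                       power_mod: dict | None = None,
                       coupling: CouplingSpec | None = None,
                       rois: tuple = ("V1", "INS", "TPJ"),
                       fs: float = 300.0, window: tuple = (-1.85, 0.75),
                       n_channels: int = 3, osc_var: float = 1.0,
                       bg_var: float = 0.2, seed: int = 0):
    """Epoched ROI time series with known spectral and coupling structure.

    Each channel is a band-limited AR(2) oscillation over a 1/f background.
    ROIs named in ``power_mod`` (mapping roi -> :class:`PowerModSpec`) have
    their oscillation innovation variance scaled by
    ``1 + depth * cos(theta - phase)`` per trial. If ``coupling`` is given,
    the first channels of the two named ROIs form a bivariate VAR(2) whose
    cross-coefficient is scaled by ``gain(theta)`` of the trial's phase.

    Returns (RoiEpochs, truth dict). Truth includes per-trial VAR
    coefficient matrices for the coupled pair (for parametric GC oracles).
    """
    phases = np.asarray(phase_at_target, float)
    n_trials = len(schedule)
    if phases.size != n_trials:
        raise ValueError("need one phase per trial")
    power_mod = power_mod or {}
    for spec in power_mod.values():
        if spec.depth >= 1:
            raise ValueError("modulation depth must be < 1")
    rng = np.random.default_rng(seed)

    n_t = int(round((window[1] - window[0]) * fs))
    burn = 300
    total = n_t + burn
    times = window[0] + np.arange(n_t) / fs

    channel_rois = [r for r in rois for _ in range(n_channels)]
    data = np.zeros((n_trials, len(channel_rois), n_t))

    coupled = {}
    if coupling is not None:
        src, dst = ((coupling.roi_a, coupling.roi_b)
                    if coupling.direction == "a->b"
                    else (coupling.roi_b, coupling.roi_a))
        if src not in rois or dst not in rois:
            raise ValueError("coupling ROIs must be in the roi list")
        coupled = {"src": src, "dst": dst}

    def mod_scale(roi):
        if roi in power_mod:
            s = power_mod[roi]
            return np.sqrt(1.0 + s.depth * np.cos(phases - s.phase))
        return np.ones(n_trials)

    def roi_f0_r(roi):
        if roi in power_mod:
            return power_mod[roi].f0, power_mod[roi].pole_radius
        if coupling is not None and roi in (coupling.roi_a, coupling.roi_b):
            return coupling.f0, coupling.pole_radius
        return 10.0, 0.9

    truth_var = None
    ch = 0
    for roi in rois:
        f0, r = roi_f0_r(roi)
        a1, a2 = _ar2_coeffs(f0, r, fs)
        scale = mod_scale(roi)
        for j in range(n_channels):
            in_pair = coupled and roi in (coupled["src"], coupled["dst"]) and j == 0
            if in_pair:
                ch += 1
                continue  # the coupled pair is generated jointly below
            eps = rng.standard_normal((n_trials, total)) * scale[:, None]
            x = np.zeros((n_trials, total))
            for t in range(2, total):
                x[:, t] = a1 * x[:, t - 1] + a2 * x[:, t - 2] + eps[:, t]
            x = x[:, burn:]
            sd = x.std()
            x = x / (sd if sd > 0 else 1.0) * np.sqrt(osc_var)
            bg = _oneoverf_noise(rng, (n_trials, n_t), fs) * np.sqrt(bg_var)
            data[:, ch, :] = x + bg
            ch += 1

    if coupled:
        # regenerate the source/target pair jointly so the lagged coupling
        # is exact in the stored epochs (VAR(2), coupling at lag 1)
        si = [i for i, r_ in enumerate(channel_rois) if r_ == coupled["src"]][0]
        di = [i for i, r_ in enumerate(channel_rois) if r_ == coupled["dst"]][0]
        f0s, rs = roi_f0_r(coupled["src"])
        f0d, rd = roi_f0_r(coupled["dst"])
        a1, a2 = _ar2_coeffs(f0s, rs, fs)
        b1, b2 = _ar2_coeffs(f0d, rd, fs)
        g = coupling.strength * coupling.gain_at(phases)
        scale_s = mod_scale(coupled["src"])
        scale_d = mod_scale(coupled["dst"])
        eps_x = rng.standard_normal((n_trials, total)) * scale_s[:, None]
        eps_y = rng.standard_normal((n_trials, total)) * scale_d[:, None]
        x = np.zeros((n_trials, total))
        y = np.zeros((n_trials, total))
        for t in range(2, total):
            x[:, t] = a1 * x[:, t - 1] + a2 * x[:, t - 2] + eps_x[:, t]
            y[:, t] = (b1 * y[:, t - 1] + b2 * y[:, t - 2]
                       + g * x[:, t - 1] + eps_y[:, t])
        x, y = x[:, burn:], y[:, burn:]
        norm = x.std()
        x, y = x / norm * np.sqrt(osc_var), y / norm * np.sqrt(osc_var)
        bgx = _oneoverf_noise(rng, (n_trials, n_t), fs) * np.sqrt(bg_var)
        bgy = _oneoverf_noise(rng, (n_trials, n_t), fs) * np.sqrt(bg_var)
        data[:, si, :] = x + bgx
        data[:, di, :] = y + bgy
        # per-trial VAR(2) coefficient matrices in (src, dst) channel order
        A1 = np.zeros((n_trials, 2, 2))
        A2 = np.zeros((n_trials, 2, 2))
        A1[:, 0, 0], A2[:, 0, 0] = a1, a2
        A1[:, 1, 1], A2[:, 1, 1] = b1, b2
        A1[:, 1, 0] = g
        truth_var = {"A1": A1, "A2": A2,
                     "innovation_sd": np.stack([scale_s, scale_d], axis=1),
                     "src": coupled["src"], "dst": coupled["dst"]}

    epochs = RoiEpochs(data=data, fs=fs, times=times,
                       channel_rois=channel_rois,
                       trial_index=schedule["trial"].to_numpy()
                       if "trial" in schedule else np.arange(n_trials))
    truth = {
        "power_mod": power_mod, "coupling": coupling, "var": truth_var,
        "osc_var": osc_var, "bg_var": bg_var, "fs": fs,
    }
    return epochs, truth


# --------------------------------------------------------------------------
# pupil
# --------------------------------------------------------------------------

def gen_pupil(duration: float, fs: float = 120.0, blink_rate: float = 12.0,
              resp_coupling: float = 0.0, resp_phase: np.ndarray | None = None,
              coupling_phase: float = -np.pi / 2, baseline_mm: float = 4.0,
              seed: int = 0):
    """Pupil area trace with blink artefacts and optional respiratory
    coupling of diameter.

    ``blink_rate`` is blinks per minute; each blink is a 100-250 ms dropout
    of the area signal toward zero. With ``resp_coupling > 0`` and a
    respiratory phase vector (sampled at the same rate), diameter gains a
    component ``resp_coupling * cos(theta - coupling_phase)`` mm — maximal
    dilation during inspiration by default.

    Returns (area signal, truth dict with inserted blink onset times).
    """
    if fs < 60:
        raise ValueError("pupil generator expects fs >= 60 Hz")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    # smooth spontaneous fluctuations (~0.3 Hz low-pass random walk)
    slow = _oneoverf_noise(rng, (1, n), fs)[0]
    from scipy.signal import butter, sosfiltfilt
    sos = butter(2, 0.5 / (fs / 2), output="sos")
    slow = sosfiltfilt(sos, slow)
    slow = 0.3 * slow / max(slow.std(), 1e-12)

    diameter = baseline_mm + slow
    if resp_coupling > 0:
        if resp_phase is None:
            raise ValueError("resp_phase required when resp_coupling > 0")
        theta = np.asarray(resp_phase, float)[:n]
        diameter = diameter + resp_coupling * np.cos(theta - coupling_phase)
    area = np.pi * (diameter / 2.0) ** 2

    blink_onsets = []
    if blink_rate > 0:
        n_blinks = rng.poisson(blink_rate * duration / 60.0)
        onsets = np.sort(rng.uniform(0.2, duration - 0.5, size=n_blinks))
        for onset in onsets:
            width = rng.uniform(0.10, 0.25)
            i0, i1 = int(onset * fs), min(int((onset + width) * fs), n)
            if i1 <= i0:
                continue
            prof = np.ones(i1 - i0) * 0.02
            ramp = max(int(0.02 * fs), 1)
            prof[:ramp] = np.linspace(1, 0.02, ramp)
            prof[-ramp:] = np.linspace(0.02, 1, ramp)
            area[i0:i1] *= prof
            blink_onsets.append(onset)

    truth = {
        "blink_onsets_s": np.array(blink_onsets),
        "resp_coupling": resp_coupling, "coupling_phase": coupling_phase,
        "baseline_mm": baseline_mm,
    }
    return ContinuousSignal(samples=area, fs=fs, units="area"), truth
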