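"""QUEST adaptive staircase and respiration-phase-resolved psychometrics.

The psychometric function throughout is a cumulative Gaussian,

    Psi(x) = gamma + (1 - gamma - lambda) * Phi((x - m) / sigma)

with threshold m, width sigma, guess rate gamma (fixed at 1/3 for the
three-response single-interval task) and lapse rate lambda. Contrast is
dimensionless in [0, 1]; the staircase works on a log10-contrast grid.

QUEST parameterises its internal psychometric function so that the tracked
"threshold" T is the log-contrast at which performance equals the target
probability (the staircase criterion, 0.60 here). Placing each trial at the
posterior mean of T therefore drives the empirical hit rate toward the
criterion, even under observer/model slope mismatch: at the fixed point the
posterior concentrates where the model prediction at the tested contrast
matches the observer's true hit probability.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import norm

from .circstats import moving_window_membership, wrap_angle
from .inference import fdr_bh

logger = logging.getLogger(__name__)

GUESS_RATE_3AFC = 1.0 / 3.0


def psychometric(x, m, sigma, gamma, lam):
    """Cumulative-Gaussian psychometric function Psi(x; m, sigma, gamma, lam)."""
    x = np.asarray(x, float)
    return gamma + (1.0 - gamma - lam) * norm.cdf((x - m) / sigma)


# --------------------------------------------------------------------------
# QUEST
# --------------------------------------------------------------------------

@dataclass
class QuestState:
    """Grid posterior over the log10-contrast at criterion performance.

    ``beta`` is the model slope per log10 unit, ``delta`` the assumed lapse
    and ``gamma`` the guess rate. ``target_p`` is the tracked hit
    probability; the likelihood is shifted so that a stimulus placed exactly
    at the threshold T yields ``target_p``.
    """

    grid: np.ndarray
    posterior: np.ndarray
    beta: float = 3.5
    delta: float = 0.01
    gamma: float = GUESS_RATE_3AFC
    target_p: float = 0.60
    edge_warned: bool = field(default=False, repr=False)

    def __post_init__(self):
        if not (self.gamma < self.target_p < 1 - self.delta):
            raise ValueError("target_p must lie in (gamma, 1 - delta)")
        self.posterior = np.asarray(self.posterior, float)
        s = self.posterior.sum()
        if not np.isfinite(s) or s <= 0:
            raise ValueError("degenerate posterior")
        self.posterior = self.posterior / s

    @classmethod
    def initialize(cls, grid_lo: float = -3.0, grid_hi: float = 0.0,
                   n_grid: int = 241, prior_mean: float = -1.0,
                   prior_sd: float = 1.0, **kwargs) -> "QuestState":
        grid = np.linspace(grid_lo, grid_hi, n_grid)
        prior = norm.pdf(grid, prior_mean, prior_sd)
        return cls(grid=grid, posterior=prior, **kwargs)

    # internal psychometric model, anchored at the criterion
    def _criterion_shift(self) -> float:
        frac = (self.target_p - self.gamma) / (1.0 - self.gamma - self.delta)
        return float(norm.ppf(frac))

    def p_hit(self, log_contrast: float, threshold_grid=None) -> np.ndarray:
        t = self.grid if threshold_grid is None else np.asarray(threshold_grid)
        z = self.beta * (log_contrast - t) + self._criterion_shift()
        return self.gamma + (1.0 - self.gamma - self.delta) * norm.cdf(z)

    @property
    def mean_threshold(self) -> float:
        return float(np.sum(self.grid * self.posterior))


def quest_propose(state: QuestState) -> float:
    """Next test contrast (linear units): posterior mean of the tracked
    log-contrast threshold."""
    if not np.all(np.isfinite(state.posterior)):
        raise ValueError("degenerate posterior")
    return float(10.0 ** state.mean_threshold)


def quest_update(state: QuestState, contrast: float, hit: bool) -> QuestState:
    """Bayes update of the posterior with one trial outcome."""
    if contrast <= 0:
        raise ValueError("contrast must be positive")
    lik = state.p_hit(np.log10(contrast))
    if not hit:
        lik = 1.0 - lik
    post = state.posterior * lik
    s = post.sum()
    if s <= 0:
        raise ValueError("posterior collapsed to zero mass")
    post = post / s
    new = replace(state, posterior=post)
    edge_mass = post[0] + post[-1]
    if edge_mass > 0.1 and not state.edge_warned:
        warnings.warn("QUEST posterior mass accumulating at the grid edge")
        new.edge_warned = True
    return new


# --------------------------------------------------------------------------
# Bayesian psychometric fitting
# --------------------------------------------------------------------------

@dataclass
class PsychFit:
    """MAP estimates and marginal credible intervals for (m, sigma, lambda).

    The threshold ``m`` is the contrast at the midpoint of the unscaled
    sigmoid (Phi = 0.5), independent of guess and lapse rates.
    """

    m: float
    sigma: float
    gamma: float
    lam: float
    ci: dict = field(default_factory=dict)
    posterior_sd: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def predict(self, x):
        return psychometric(x, self.m, self.sigma, self.gamma, self.lam)


def _default_grids(contrasts: np.ndarray):
    lo, hi = np.min(contrasts), np.max(contrasts)
    span = max(hi - lo, 0.05)
    m_grid = np.linspace(lo - 0.5 * span, hi + 0.5 * span, 61)
    sigma_grid = np.geomspace(max(span / 50, 1e-3), 2 * span, 31)
    lam_grid = np.linspace(0.0, 0.2, 11)
    return m_grid, sigma_grid, lam_grid


def fit_psychometric(contrasts, outcomes, gamma: float = GUESS_RATE_3AFC,
                     priors: dict | None = None,
                     grids: tuple | None = None) -> PsychFit:
    """Grid-based Bayesian fit of the cumulative-Gaussian psychometric
    function with fixed guess rate.

    Parameters
    ----------
    contrasts, outcomes : arrays
        Per-trial stimulus contrast and binary hit/miss outcome.
    gamma : float
        Fixed guess rate.
    priors : dict, optional
        Gaussian priors as ``{"m": (mean, sd), "sigma": (mean, sd)}`` used by
        the phase-resolved refit. The lapse rate always carries a
        Beta(1, 20)-shaped prior favouring small lapses.
    grids : tuple of arrays, optional
        Explicit (m_grid, sigma_grid, lam_grid).

    Returns the posterior mode (MAP) with marginal 95% credible intervals
    and marginal posterior SDs per parameter.
    """
    c = np.asarray(contrasts, float)
    y = np.asarray(outcomes, float)
    if c.size != y.size or c.size == 0:
        raise ValueError("contrasts and outcomes must be equal-length, non-empty")
    flags: list[str] = []
    if np.unique(c[y == 1]).size == 0 or np.unique(c[y == 0]).size == 0:
        flags.append("degenerate: only one outcome class present")
    if grids is None:
        grids = _default_grids(c)
    m_grid, sigma_grid, lam_grid = (np.asarray(g, float) for g in grids)

    # log-likelihood on the (m, sigma, lam) grid, vectorised over trials
    M = m_grid[:, None, None, None]
    S = sigma_grid[None, :, None, None]
    L = lam_grid[None, None, :, None]
    psi = gamma + (1 - gamma - L) * norm.cdf((c[None, None, None, :] - M) / S)
    psi = np.clip(psi, 1e-9, 1 - 1e-9)
    ll = np.sum(np.where(y[None, None, None, :] > 0.5, np.log(psi),
                         np.log1p(-psi)), axis=-1)

    # priors
    logp = ll
    logp = logp + stats.beta.logpdf(np.clip(lam_grid, 1e-9, 0.5), 1, 20)[None, None, :] \
        if lam_grid.size > 1 else logp
    if priors:
        if "m" in priors:
            mu, sd = priors["m"]
            logp = logp + norm.logpdf(m_grid, mu, sd)[:, None, None]
        if "sigma" in priors:
            mu, sd = priors["sigma"]
            logp = logp + norm.logpdf(sigma_grid, mu, sd)[None, :, None]

    logp = logp - logp.max()
    post = np.exp(logp)
    post /= post.sum()

    i, j, k = np.unravel_index(np.argmax(post), post.shape)
    if i in (0, m_grid.size - 1):
        flags.append("threshold estimate at grid edge")

    def marginal(axis_keep, grid):
        axes = tuple(a for a in range(3) if a != axis_keep)
        marg = post.sum(axis=axes)
        cdf = np.cumsum(marg)
        lo = grid[np.searchsorted(cdf, 0.025)]
        hi = grid[min(np.searchsorted(cdf, 0.975), grid.size - 1)]
        mean = np.sum(grid * marg)
        sd = np.sqrt(max(np.sum(grid**2 * marg) - mean**2, 0.0))
        return (float(lo), float(hi)), float(sd)

    ci_m, sd_m = marginal(0, m_grid)
    ci_s, sd_s = marginal(1, sigma_grid)
    ci_l, sd_l = marginal(2, lam_grid)
    if flags:
        for msg in flags:
            logger.warning("psychometric fit: %s", msg)
    return PsychFit(
        m=float(m_grid[i]), sigma=float(sigma_grid[j]), gamma=gamma,
        lam=float(lam_grid[k]),
        ci={"m": ci_m, "sigma": ci_s, "lam": ci_l},
        posterior_sd={"m": sd_m, "sigma": sd_s, "lam": sd_l},
        flags=flags,
    )


# --------------------------------------------------------------------------
# phase-resolved refitting
# --------------------------------------------------------------------------

@dataclass
class ThresholdProfile:
    """Respiration-phase-resolved threshold estimates.

    ``window_centres`` are the 60 window centres (step pi/30);
    ``z_thresholds`` are per-window thresholds z-scored across defined
    windows; ``n_trials`` counts trials per window (each trial contributes
    to window-width / step = 6 windows).
    """

    window_centres: np.ndarray
    thresholds: np.ndarray
    z_thresholds: np.ndarray
    n_trials: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.z_thresholds)


def phase_window_centres(step: float = np.pi / 30) -> np.ndarray:
    n = int(round(2 * np.pi / step))
    return wrap_angle(-np.pi + step * np.arange(n))


def phase_resolved_thresholds(trials: pd.DataFrame, overall_fit: PsychFit,
                              step: float = np.pi / 30,
                              half_width: float = np.pi / 10,
                              min_trials: int = 10,
                              prior_scale: float = 2.0) -> ThresholdProfile:
    """Moving-window refit of the psychometric function across the
    respiratory cycle.

    Window centres advance in increments of ``step`` (pi/30 -> 60 windows);
    each window spans ``centre +/- half_width`` (pi/10), wrapping around the
    circle. Each window is refit with Gaussian priors on threshold and
    width centred on the overall fit (SD = ``prior_scale`` x the overall
    posterior SD), then thresholds are z-scored across defined windows.

    ``trials`` needs columns ``contrast``, ``hit`` and ``phase_rad``.
    """
    centres = phase_window_centres(step)
    phases = trials["phase_rad"].to_numpy(float)
    ok = np.isfinite(phases)
    membership = np.zeros((centres.size, phases.size), dtype=bool)
    membership[:, ok] = moving_window_membership(phases[ok], centres, half_width)

    priors = {
        "m": (overall_fit.m, max(prior_scale * overall_fit.posterior_sd.get("m", 0.05), 1e-3)),
        "sigma": (overall_fit.sigma, max(prior_scale * overall_fit.posterior_sd.get("sigma", 0.05), 1e-3)),
    }
    contrasts = trials["contrast"].to_numpy(float)
    hits = trials["hit"].to_numpy(float)
    grids = _default_grids(contrasts)

    thresholds = np.full(centres.size, np.nan)
    n_per = np.zeros(centres.size, int)
    for k in range(centres.size):
        sel = membership[k]
        n_per[k] = int(sel.sum())
        if n_per[k] < min_trials:
            logger.info("phase window %d: only %d trials, skipped", k, n_per[k])
            continue
        fit = fit_psychometric(contrasts[sel], hits[sel], gamma=overall_fit.gamma,
                               priors=priors, grids=grids)
        thresholds[k] = fit.m

    defined = np.isfinite(thresholds)
    z = np.full_like(thresholds, np.nan)
    if defined.sum() >= 2:
        mu = thresholds[defined].mean()
        sd = thresholds[defined].std()
        if sd > 0:
            z[defined] = (thresholds[defined] - mu) / sd
        else:
            z[defined] = 0.0
    return ThresholdProfile(window_centres=centres, thresholds=thresholds,
                            z_thresholds=z, n_trials=n_per)


def group_profile_test(profiles: list[ThresholdProfile], q: float = 0.05):
    """Group-level test of the phase-resolved threshold modulation.

    Per window, a two-sided one-sample t-test of the z-scored thresholds
    against 0 across participants; Benjamini-Hochberg FDR across windows.

    Returns (group mean curve, p-values, FDR significance mask).
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 participants")
    Z = np.vstack([p.z_thresholds for p in profiles])
    mean_curve = np.nanmean(Z, axis=0)
    n_win = Z.shape[1]
    pvals = np.ones(n_win)
    for k in range(n_win):
        col = Z[:, k]
        col = col[np.isfinite(col)]
        if col.size >= 2 and col.std() > 0:
            pvals[k] = stats.ttest_1samp(col, 0.0).pvalue
    sig = fdr_bh(pvals, q=q)
    return mean_curve, pvals, sig
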