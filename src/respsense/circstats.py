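"""Circular statistics used across the behavioural, pupil, spectral and
connectivity analyses.

Angles are radians on the circle; the package-wide respiratory convention
(trough = -pi, peak = 0) means "inspiration" is the (-pi, 0) half-cycle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


def wrap_angle(theta) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    theta = np.asarray(theta, float)
    wrapped = -((-theta + np.pi) % (2 * np.pi) - np.pi)
    return wrapped


def circ_mean(angles) -> float:
    a = np.asarray(angles, float)
    return float(np.angle(np.exp(1j * a).mean()))


def resultant_length(angles) -> float:
    a = np.asarray(angles, float)
    return float(np.abs(np.exp(1j * a).mean()))


# --------------------------------------------------------------------------
# circular-linear association
# --------------------------------------------------------------------------

def circ_linear_corr(angles, x) -> tuple[float, float]:
    """Circular-linear correlation of a linear variable with an angle.

    rho^2 is the R^2 of regressing x on (sin, cos) of the angle, computed
    through the pairwise correlations

        rho = sqrt((r_cx^2 + r_sx^2 - 2 r_cx r_sx r_cs) / (1 - r_cs^2))

    with r_cx = corr(cos t, x), r_sx = corr(sin t, x),
    r_cs = corr(sin t, cos t). The p-value uses the chi^2_2 approximation
    of n * rho^2.
    """
    a = np.asarray(angles, float)
    x = np.asarray(x, float)
    if a.size != x.size or a.size < 4:
        raise ValueError("need n >= 4 paired observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("x contains non-finite values")
    if np.std(x) == 0:
        raise ValueError("circular-linear correlation undefined for constant x")
    s, c = np.sin(a), np.cos(a)
    r_cx = np.corrcoef(c, x)[0, 1]
    r_sx = np.corrcoef(s, x)[0, 1]
    r_cs = np.corrcoef(s, c)[0, 1]
    rho2 = (r_cx**2 + r_sx**2 - 2 * r_cx * r_sx * r_cs) / (1 - r_cs**2)
    rho = float(np.sqrt(np.clip(rho2, 0.0, 1.0)))
    p = float(stats.chi2.sf(a.size * rho**2, df=2))
    return rho, p


# --------------------------------------------------------------------------
# tests of non-uniformity
# --------------------------------------------------------------------------

def rayleigh_test(angles) -> tuple[float, float]:
    """Rayleigh test for a unimodal departure from circular uniformity.

    Returns ``z = n * Rbar^2`` and the standard finite-n corrected p-value.
    """
    a = np.asarray(angles, float)
    n = a.size
    if n < 2:
        raise ValueError("need n >= 2 angles")
    rbar = resultant_length(a)
    z = n * rbar**2
    # Zar's finite-n correction
    p = math.exp(math.sqrt(1 + 4 * n + 4 * (n**2 - (rbar * n) ** 2)) - (1 + 2 * n))
    return float(z), float(min(max(p, 0.0), 1.0))


def hodges_ajne(angles) -> tuple[int, float]:
    """Hodges-Ajne omnibus test against circular uniformity.

    The statistic m is the minimum number of observations in any closed
    half-circle. Small m indicates clustering. The p-value is exact,
    ``p = (n - 2m) * C(n, m) * 2^(1-n)``, for n <= 50 and uses the normal
    approximation above that.
    """
    a = wrap_angle(np.asarray(angles, float))
    n = a.size
    if n < 4:
        raise ValueError("need n >= 4 angles")
    # half circles bounded at each data direction; points within float
    # noise of the far boundary count as outside so antipodal grids are
    # handled deterministically
    counts = np.array([
        np.sum(np.mod(a - t, 2 * np.pi) < np.pi - 1e-9) for t in a
    ])
    m = int(min(counts.min(), (n - counts).min()))
    if n - 2 * m <= 0:
        p = 1.0  # weakest possible clustering
    elif n <= 50:
        p = (n - 2 * m) * math.comb(n, m) * 2.0 ** (1 - n)
    else:
        A = math.pi * math.sqrt(n) / (2 * (n - 2 * m))
        p = math.sqrt(2 * math.pi) / A * math.exp(-(math.pi**2) / (8 * A**2))
    return m, float(min(p, 1.0))


# --------------------------------------------------------------------------
# sine/cosine phase regression
# --------------------------------------------------------------------------

@dataclass
class PhaseRegression:
    """Least-squares fit of a response to ``b0 + b_sin sin t + b_cos cos t``.

    ``amplitude`` and ``preferred_phase`` re-express the sine/cosine pair as
    a single cosine ``amplitude * cos(t - preferred_phase)``.
    """

    b0: float
    b_sin: float
    b_cos: float

    @property
    def amplitude(self) -> float:
        return float(np.hypot(self.b_sin, self.b_cos))

    @property
    def preferred_phase(self) -> float:
        return float(np.arctan2(self.b_sin, self.b_cos))

    def predict(self, angles) -> np.ndarray:
        a = np.asarray(angles, float)
        return self.b0 + self.b_sin * np.sin(a) + self.b_cos * np.cos(a)


def phase_regression(angles, y) -> PhaseRegression:
    """OLS of ``y`` on [1, sin(angle), cos(angle)]."""
    a = np.asarray(angles, float)
    y = np.asarray(y, float)
    if a.size != y.size or a.size < 4:
        raise ValueError("need n >= 4 paired observations")
    X = np.column_stack([np.ones_like(a), np.sin(a), np.cos(a)])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design (angles do not span the circle)")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return PhaseRegression(b0=float(beta[0]), b_sin=float(beta[1]), b_cos=float(beta[2]))


# --------------------------------------------------------------------------
# phase binning
# --------------------------------------------------------------------------

def bin_by_phase(angles, n_bins: int) -> np.ndarray:
    """Assign each angle to one of ``n_bins`` equal, non-overlapping bins
    partitioning (-pi, pi]. Intervals are right-closed, so an angle exactly
    on an edge belongs to the bin ending there."""
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    a = wrap_angle(angles)
    width = 2 * np.pi / n_bins
    # right-closed: bin k is (-pi + k*width, -pi + (k+1)*width]; the small
    # offset keeps angles within float noise of an edge on its closed side
    idx = np.ceil((a + np.pi) / width - 1e-9).astype(int) - 1
    return np.clip(idx, 0, n_bins - 1)


def phase_bin_centres(n_bins: int) -> np.ndarray:
    width = 2 * np.pi / n_bins
    return -np.pi + width * (np.arange(n_bins) + 0.5)


def moving_window_membership(angles, centres, half_width: float) -> np.ndarray:
    """Boolean (n_centres, n_angles) membership for overlapping circular
    windows ``centre +/- half_width``."""
    a = wrap_angle(angles)[None, :]
    c = np.asarray(centres, float)[:, None]
    d = np.abs(wrap_angle(a - c))
    return d <= half_width + 1e-12


# --------------------------------------------------------------------------
# paired circular difference test
# --------------------------------------------------------------------------

def circ_diff_test(angles_a, angles_b, n_perm: int = 10_000,
                   seed: int | None = None) -> tuple[float, float]:
    """Test whether the mean paired circular difference departs from zero.

    Differences ``d_i = wrap(a_i - b_i)`` are tested against a mean
    direction of 0 with a sign-flip permutation: under the null of no
    systematic shift, d and -d are exchangeable. The statistic is the
    absolute mean sine of the differences — the component of the mean
    resultant orthogonal to the null direction, which a pure rotation of
    the differences toward either side increases.

    Returns (observed statistic, permutation p-value).
    """
    a = np.asarray(angles_a, float)
    b = np.asarray(angles_b, float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    d = wrap_angle(a - b)
    n = d.size

    def stat(dd):
        return np.abs(np.mean(np.sin(dd), axis=-1))

    observed = float(stat(d))
    rng = np.random.default_rng(seed)
    if n < 5:
        warnings.warn("fewer than 5 pairs; enumerating all sign flips")
        signs = np.array(np.meshgrid(*([[-1, 1]] * n))).T.reshape(-1, n)
    else:
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    null = stat(signs * d[None, :])
    p = float((1 + np.sum(null >= observed - 1e-15)) / (1 + null.size))
    return observed, p
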