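"""Nonparametric blockwise spectral Granger causality and the directed
asymmetry index (DAI).

The chain is: multitaper cross-spectral density of two 3-component ROI
blocks -> Wilson spectral matrix factorisation S(f) = H(f) Sigma H(f)* ->
Geweke blockwise Granger causality per direction -> DAI,

    DAI(f) = (mGC(A->B) - mGC(B->A)) / (mGC(A->B) + mGC(B->A)),

which is antisymmetric in the block labels and bounded in [-1, 1]. The
factorisation is performed without fitting an autoregressive model: Wilson's
iteration updates a causal (minimum-phase) spectral factor until the
reconstruction matches the estimated CSD.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import dpss

from .circstats import bin_by_phase, phase_bin_centres, phase_regression
from .epochs import RoiEpochs
from .spectral import PRESTIM_WINDOW, n_tapers_for

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# ROI block components
# --------------------------------------------------------------------------

def roi_block_components(roi_data: np.ndarray, n_components: int = 3) -> np.ndarray:
    """Top principal components of one ROI's trial-based time series.

    PCA is computed across trials concatenated in time, so the same spatial
    weights apply to every trial. Input (trials, channels, times); output
    (trials, n_components, times). If the data have rank below
    ``n_components``, fewer components are returned with a warning.
    """
    X = np.asarray(roi_data, float)
    n_tr, n_ch, n_t = X.shape
    flat = X.transpose(1, 0, 2).reshape(n_ch, n_tr * n_t)
    flat = flat - flat.mean(axis=1, keepdims=True)
    U, s, _ = np.linalg.svd(flat, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    k = min(n_components, rank)
    if k < n_components:
        warnings.warn(f"ROI rank {rank} < {n_components}; returning {k} components")
    comp = (U[:, :k].T @ flat).reshape(k, n_tr, n_t).transpose(1, 0, 2)
    return comp


# --------------------------------------------------------------------------
# cross-spectral density
# --------------------------------------------------------------------------

@dataclass
class CrossSpectralDensity:
    """Trial-averaged CSD on a uniform frequency grid from 0 to Nyquist.

    ``S`` is (n_freqs, n_channels, n_channels), Hermitian at every
    frequency. The uniform grid (including 0 and Nyquist) is what the
    Wilson factorisation operates on.
    """

    S: np.ndarray
    freqs: np.ndarray
    fs: float
    n_trials: int
    n_tapers: int

    def crop_mask(self, fmax: float) -> np.ndarray:
        return self.freqs <= fmax + 1e-9


def csd_multitaper(data: np.ndarray, fs: float, smoothing_hz: float = 2.0,
                   nfft: int | None = None) -> CrossSpectralDensity:
    """DPSS multitaper cross-spectral density of epoched data.

    Parameters
    ----------
    data : ndarray, (n_trials, n_channels, n_times)
        Epoched block data (e.g. 3 + 3 ROI components), already cropped to
        the analysis window.
    smoothing_hz : float
        One-sided spectral smoothing; taper count floor(2 NW) - 1.
    nfft : int, optional
        FFT length (even); defaults to the next power of two >= n_times.
    """
    data = np.asarray(data, float)
    n_tr, n_ch, n_t = data.shape
    K = n_tapers_for(smoothing_hz, n_t, fs)
    if K < 1:
        raise ValueError(
            f"smoothing {smoothing_hz} Hz too small for a {n_t / fs:.3g} s window; "
            f"need at least {fs / n_t:.3g} Hz")
    if nfft is None:
        nfft = 1 << int(np.ceil(np.log2(n_t)))
    if nfft % 2:
        raise ValueError("nfft must be even")
    tapers, eigvals = dpss(n_t, smoothing_hz * n_t / fs, Kmax=K,
                           return_ratios=True)
    d = data - data.mean(axis=-1, keepdims=True)
    # (trials, tapers, channels, freqs)
    X = np.fft.rfft(d[:, None, :, :] * tapers[None, :, None, :], n=nfft, axis=-1)
    w = eigvals / eigvals.sum()
    S = np.einsum("tkif,tkjf,k->fij", X, np.conj(X), w) / (n_tr * fs)
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    return CrossSpectralDensity(S=S, freqs=freqs, fs=fs, n_trials=n_tr,
                                n_tapers=K)


def coherence(csd: CrossSpectralDensity) -> np.ndarray:
    """Magnitude-squared coherence from the CSD."""
    P = np.real(np.einsum("fii->fi", csd.S))
    return np.abs(csd.S) ** 2 / (P[:, :, None] * P[:, None, :])


# --------------------------------------------------------------------------
# Wilson spectral matrix factorisation
# --------------------------------------------------------------------------

def _plus_operator(g: np.ndarray) -> np.ndarray:
    """Causal part of a two-sided spectral matrix function.

    Zeroes negative lags, keeps positive lags, and takes the triangular
    half (with half diagonal) of lag zero so the lag-0 factor stays lower
    triangular through the iteration.
    """
    nfft = g.shape[0]
    G = np.fft.ifft(g, axis=0)
    # split the Hermitian lag-0 term as L + L^H with L lower triangular:
    # strict lower part in full, half the diagonal
    G[0] = np.tril(G[0], -1) + 0.5 * np.diag(np.diag(G[0]))
    G[nfft // 2 + 1:] = 0.0
    return np.fft.fft(G, axis=0)


def wilson_factorize(csd: CrossSpectralDensity, tol: float = 1e-8,
                     max_iter: int = 100, diag_load: float = 1e-8):
    """Wilson's iterative factorisation S(f) = H(f) Sigma H(f)*.

    The spectral factor is initialised from the Cholesky factor of the
    frequency-averaged spectrum (the lag-0 covariance) and updated with the
    causal-projection iteration until the relative change of the factor
    falls below ``tol``. A small diagonal loading (``diag_load`` x mean
    power) keeps the CSD positive definite under finite trial counts.

    Returns
    -------
    H : ndarray, (n_freqs, n, n)
        Minimum-phase transfer function on the one-sided grid, normalised
        so that H at lag 0 corresponds to a lower-triangular factor.
    Sigma : ndarray, (n, n)
        Innovation (noise) covariance.

    Raises
    ------
    RuntimeError
        If the iteration does not converge within ``max_iter``; the final
        relative residual is reported.
    """
    S = np.asarray(csd.S, complex)
    n_f, n, _ = S.shape
    nfft = 2 * (n_f - 1)
    mean_pow = float(np.mean(np.real(np.einsum("fii->fi", S))))
    S = S + diag_load * mean_pow * np.eye(n)[None]

    Sfull = np.empty((nfft, n, n), complex)
    Sfull[:n_f] = S
    Sfull[n_f:] = np.conj(S[1:-1][::-1])  # S(-f) = conj(S(f)) for real data

    gam0 = np.real(np.fft.ifft(Sfull, axis=0)[0])
    try:
        L = np.linalg.cholesky(gam0)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(gam0 + 1e-6 * np.trace(gam0) / n * np.eye(n))
    psi = np.broadcast_to(L, (nfft, n, n)).astype(complex).copy()

    I = np.eye(n)
    resid = np.inf
    prev_resid = np.inf
    stall = 0
    s_norm = max(np.linalg.norm(Sfull), 1e-300)
    for _ in range(max_iter):
        psi_inv = np.linalg.inv(psi)
        g = psi_inv @ Sfull @ np.conj(psi_inv.transpose(0, 2, 1)) + I
        gp = _plus_operator(g)
        psi_new = psi @ gp
        step = np.linalg.norm(psi_new - psi) / np.linalg.norm(psi)
        psi = psi_new
        recon = psi @ np.conj(psi.transpose(0, 2, 1))
        resid = np.linalg.norm(recon - Sfull) / s_norm
        if resid < tol or step < 1e-12:
            break
        # the causal-lag truncation of the finite frequency grid puts a
        # floor under the residual; stop once it no longer improves
        stall = stall + 1 if resid > 0.999 * prev_resid else 0
        if stall >= 10:
            break
        prev_resid = min(prev_resid, resid)
    if resid > 1e-3:
        raise RuntimeError(
            f"Wilson factorisation did not converge in {max_iter} iterations "
            f"(relative residual {resid:.3g})")

    A0 = np.real(np.fft.ifft(psi, axis=0)[0])
    Sigma = A0 @ A0.T
    H = psi[:n_f] @ np.linalg.inv(A0)
    return H, Sigma


# --------------------------------------------------------------------------
# blockwise Granger causality and DAI
# --------------------------------------------------------------------------

@dataclass
class GCSpectra:
    """Frequency-resolved directed influence between two channel blocks."""

    freqs: np.ndarray
    f_ab: np.ndarray  # A -> B
    f_ba: np.ndarray  # B -> A
    label_a: str = "A"
    label_b: str = "B"


def _block_gc_one_direction(S, H, Sigma, src, dst):
    """Geweke spectral GC from block ``src`` to block ``dst``."""
    S_dd = S[np.ix_(range(S.shape[0]), dst, dst)]
    H_ds = H[np.ix_(range(H.shape[0]), dst, src)]
    Sig_ss = Sigma[np.ix_(src, src)]
    Sig_sd = Sigma[np.ix_(src, dst)]
    Sig_dd = Sigma[np.ix_(dst, dst)]
    # innovation covariance of src conditional on dst
    try:
        cond = Sig_ss - Sig_sd @ np.linalg.solve(Sig_dd, Sig_sd.T)
    except np.linalg.LinAlgError:
        warnings.warn("singular conditional covariance; regularising")
        ridge = 1e-10 * np.trace(Sig_dd) / len(dst) * np.eye(len(dst))
        cond = Sig_ss - Sig_sd @ np.linalg.solve(Sig_dd + ridge, Sig_sd.T)
    intrinsic = S_dd - H_ds @ cond[None] @ np.conj(H_ds.transpose(0, 2, 1))
    sign_n, logdet_num = np.linalg.slogdet(S_dd)
    sign_d, logdet_den = np.linalg.slogdet(intrinsic)
    gc = np.where((sign_n.real > 0) & (sign_d.real > 0),
                  np.real(logdet_num - logdet_den), 0.0)
    return np.clip(gc, 0.0, None)


def block_gc(csd: CrossSpectralDensity, H: np.ndarray, Sigma: np.ndarray,
             block_a, block_b, fmax: float | None = None,
             label_a: str = "A", label_b: str = "B") -> GCSpectra:
    """Blockwise spectral Granger causality in both directions.

    ``block_a``/``block_b`` are channel index lists (e.g. [0,1,2] and
    [3,4,5] for two 3-component ROI blocks).
    """
    a = list(block_a)
    b = list(block_b)
    S = csd.S + 0.0
    f_ab = _block_gc_one_direction(S, H, Sigma, a, b)
    f_ba = _block_gc_one_direction(S, H, Sigma, b, a)
    freqs = csd.freqs
    if fmax is not None:
        m = csd.crop_mask(fmax)
        freqs, f_ab, f_ba = freqs[m], f_ab[m], f_ba[m]
    return GCSpectra(freqs=freqs, f_ab=f_ab, f_ba=f_ba,
                     label_a=label_a, label_b=label_b)


def dai(gc: GCSpectra, floor: float = 1e-15) -> np.ndarray:
    """Directed asymmetry index of a GC spectrum pair.

    ``(gc_ab - gc_ba) / (gc_ab + gc_ba)`` elementwise; frequencies where the
    denominator falls below ``floor`` (including both directions zero) are
    returned as NaN rather than propagating division artefacts.
    """
    num = gc.f_ab - gc.f_ba
    den = gc.f_ab + gc.f_ba
    out = np.full_like(den, np.nan)
    ok = den > floor
    out[ok] = num[ok] / den[ok]
    return out


# --------------------------------------------------------------------------
# respiration-phase-resolved GC
# --------------------------------------------------------------------------

@dataclass
class PhaseResolvedGC:
    """GC per respiration-phase bin: (n_freqs, n_bins) per direction."""

    freqs: np.ndarray
    bin_centres: np.ndarray
    gc_ab: np.ndarray
    gc_ba: np.ndarray
    n_per_bin: np.ndarray
    label_a: str = "A"
    label_b: str = "B"


def phase_resolved_gc(epochs: RoiEpochs, phases, roi_a: str, roi_b: str,
                      n_bins: int = 30, min_trials: int = 15,
                      smoothing_hz: float = 2.0, fmax: float = 150.0,
                      window: tuple = PRESTIM_WINDOW,
                      n_components: int = 3, nfft: int | None = None,
                      tol: float = 1e-8, max_iter: int = 100) -> PhaseResolvedGC:
    """Full CSD -> factorisation -> block-GC chain per respiration-phase bin.

    Trials are assigned to ``n_bins`` non-overlapping bins of respiratory
    phase at target onset; within each bin the two ROIs' principal
    components (computed once across all trials) are cross-spectrally
    decomposed, factorised, and reduced to directional GC spectra. Bins
    with fewer than ``min_trials`` trials are skipped and reported as NaN.
    """
    phases = np.asarray(phases, float)
    if phases.size != epochs.n_trials:
        raise ValueError("need one phase per trial")
    ep = epochs.crop(*window)
    comp_a = roi_block_components(ep.roi_data(roi_a), n_components)
    comp_b = roi_block_components(ep.roi_data(roi_b), n_components)
    block = np.concatenate([comp_a, comp_b], axis=1)
    ia = list(range(comp_a.shape[1]))
    ib = list(range(comp_a.shape[1], block.shape[1]))

    centres = phase_bin_centres(n_bins)
    ok = np.isfinite(phases)
    assign = np.full(phases.size, -1, int)
    assign[ok] = bin_by_phase(phases[ok], n_bins)

    gc_ab = gc_ba = None
    n_per = np.zeros(n_bins, int)
    freqs = None
    for k in range(n_bins):
        sel = assign == k
        n_per[k] = int(sel.sum())
        if n_per[k] < min_trials:
            logger.warning("phase bin %d: %d trials < %d, skipped",
                           k, n_per[k], min_trials)
            continue
        csd = csd_multitaper(block[sel], ep.fs, smoothing_hz, nfft=nfft)
        H, Sigma = wilson_factorize(csd, tol=tol, max_iter=max_iter)
        gc = block_gc(csd, H, Sigma, ia, ib, fmax=fmax,
                      label_a=roi_a, label_b=roi_b)
        if gc_ab is None:
            freqs = gc.freqs
            gc_ab = np.full((freqs.size, n_bins), np.nan)
            gc_ba = np.full((freqs.size, n_bins), np.nan)
        gc_ab[:, k] = gc.f_ab
        gc_ba[:, k] = gc.f_ba
    if gc_ab is None:
        raise ValueError("no phase bin reached the minimum trial count")
    return PhaseResolvedGC(freqs=freqs, bin_centres=centres, gc_ab=gc_ab,
                           gc_ba=gc_ba, n_per_bin=n_per,
                           label_a=roi_a, label_b=roi_b)


def gc_phase_regression(prgc: PhaseResolvedGC, fmax: float = 40.0):
    """First-level sine/cosine regression of phase-resolved GC, and the DAI
    of the resulting modulation magnitudes.

    Per frequency and direction, GC across bins is regressed on
    [1, sin, cos] of the bin centre; the modulation magnitude is
    sqrt(b_sin^2 + b_cos^2). Because raw sine/cosine weights are signed,
    the DAI is applied to the two directions' nonnegative modulation
    magnitudes. Statistics are restricted to frequencies up to ``fmax``.

    Returns
    -------
    freqs : ndarray
    modulation : ndarray, (n_freqs, 2)
        Modulation magnitude for A->B (column 0) and B->A (column 1).
    dai_mod : ndarray, (n_freqs,)
        DAI of the modulation magnitudes.
    """
    m = prgc.freqs <= fmax + 1e-9
    freqs = prgc.freqs[m]
    mods = np.full((freqs.size, 2), np.nan)
    for col, gc_dir in enumerate((prgc.gc_ab[m], prgc.gc_ba[m])):
        for i in range(freqs.size):
            row = gc_dir[i]
            ok = np.isfinite(row)
            if ok.sum() < 4:
                continue
            fit = phase_regression(prgc.bin_centres[ok], row[ok])
            mods[i, col] = fit.amplitude
    den = mods[:, 0] + mods[:, 1]
    dai_mod = np.full(freqs.size, np.nan)
    okd = np.isfinite(den) & (den > 1e-15)
    dai_mod[okd] = (mods[okd, 0] - mods[okd, 1]) / den[okd]
    return freqs, mods, dai_mod
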