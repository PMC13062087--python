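"""Independent reference implementations used as oracles in tests.

Everything here is deliberately written from the defining formulas, without
reusing package internals, so that agreement is informative.
"""

import math

import numpy as np
from scipy.stats import norm


# --------------------------------------------------------------------------
# brute-force grid Bayes for the staircase
# --------------------------------------------------------------------------

def brute_force_quest_posterior(grid, prior, history, beta, delta, gamma,
                                target_p):
    """Direct product-of-likelihoods posterior over the threshold grid.

    ``history`` is a list of (log10-contrast, hit) pairs. The psychometric
    model is anchored so a stimulus at the threshold yields ``target_p``.
    """
    shift = norm.ppf((target_p - gamma) / (1.0 - gamma - delta))
    post = np.array(prior, float)
    for x, hit in history:
        p = gamma + (1 - gamma - delta) * norm.cdf(beta * (x - grid) + shift)
        post = post * (p if hit else (1.0 - p))
    return post / post.sum()


# --------------------------------------------------------------------------
# circular statistics
# --------------------------------------------------------------------------

def direct_circ_linear_rho(angles, x):
    """Literal evaluation of the circular-linear correlation formula."""
    s = np.sin(angles)
    c = np.cos(angles)

    def corr(u, v):
        u = u - np.mean(u)
        v = v - np.mean(v)
        return np.sum(u * v) / np.sqrt(np.sum(u * u) * np.sum(v * v))

    rcx, rsx, rcs = corr(c, x), corr(s, x), corr(s, c)
    return math.sqrt((rcx**2 + rsx**2 - 2 * rcx * rsx * rcs) / (1 - rcs**2))


def hodges_ajne_brute(angles, n_rot=20001):
    """Hodges-Ajne statistic by scanning a dense grid of half-circle
    boundaries, with the classical exact p-value."""
    a = np.mod(np.asarray(angles, float), 2 * np.pi)
    n = a.size
    best = n
    for t in np.linspace(0, 2 * np.pi, n_rot, endpoint=False):
        cnt = int(np.sum(np.mod(a - t, 2 * np.pi) < np.pi))
        best = min(best, cnt, n - cnt)
    p = (n - 2 * best) * math.comb(n, best) / 2.0 ** (n - 1)
    return best, min(p, 1.0)


# --------------------------------------------------------------------------
# FDR
# --------------------------------------------------------------------------

def fdr_bh_brute(pvals, q=0.05):
    """Largest k with p_(k) <= k q / m, rejecting the k smallest p-values."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    mask = np.zeros(m, bool)
    mask[order[:k_star]] = True
    return mask


# --------------------------------------------------------------------------
# parametric VAR spectra and Geweke block GC
# --------------------------------------------------------------------------

def var_transfer_and_spectrum(A_list, Sigma, freqs, fs):
    """Analytic transfer function and spectral matrix of a stable VAR."""
    n = Sigma.shape[0]
    S = np.zeros((len(freqs), n, n), complex)
    H = np.zeros((len(freqs), n, n), complex)
    for i, f in enumerate(freqs):
        z = np.exp(-2j * np.pi * f / fs)
        Af = np.eye(n) - sum(A * z ** (k + 1) for k, A in enumerate(A_list))
        Hf = np.linalg.inv(Af)
        H[i] = Hf
        S[i] = Hf @ Sigma @ Hf.conj().T
    return H, S


def parametric_block_gc(A_list, Sigma, src, dst, freqs, fs):
    """Geweke block GC from the true VAR coefficients (det-ratio form)."""
    H, S = var_transfer_and_spectrum(A_list, Sigma, freqs, fs)
    src = list(src)
    dst = list(dst)
    Sig_ss = Sigma[np.ix_(src, src)]
    Sig_sd = Sigma[np.ix_(src, dst)]
    Sig_dd = Sigma[np.ix_(dst, dst)]
    cond = Sig_ss - Sig_sd @ np.linalg.inv(Sig_dd) @ Sig_sd.T
    gc = np.zeros(len(freqs))
    for i in range(len(freqs)):
        S_dd = S[i][np.ix_(dst, dst)]
        H_ds = H[i][np.ix_(dst, src)]
        intrinsic = S_dd - H_ds @ cond @ H_ds.conj().T
        gc[i] = np.real(np.log(np.linalg.det(S_dd))
                        - np.log(np.linalg.det(intrinsic)))
    return np.clip(gc, 0.0, None)
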