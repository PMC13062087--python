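"""Group-level inference: cluster-based permutation statistics, FDR,
mutual-information model comparison, and brain-behaviour correlation with
cluster correction.

The cluster-permutation procedure follows the standard nonparametric
recipe for neurophysiological data: point-wise two-tailed t-tests are
thresholded at p = 0.05, adjacent suprathreshold points of equal sign are
grouped into clusters, each cluster is summarised by the sum of absolute
t-values, and the summary is compared against a label-permutation null in
which t-values are recomputed and clusters redetected for every
permutation. Clusters exceeding the 97.5th percentile of the permutation
distribution of the maximum cluster statistic are deemed significant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse, stats
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# cluster permutation
# --------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Clusters over the tested dimensions with permutation p-values."""

    t_obs: np.ndarray
    threshold: float
    clusters: list = field(default_factory=list)  # boolean masks, t_obs shape
    cluster_stats: np.ndarray = field(default_factory=lambda: np.empty(0))
    pvals: np.ndarray = field(default_factory=lambda: np.empty(0))
    sig_mask: np.ndarray | None = None
    null_percentile_975: float = np.nan

    @property
    def significant(self) -> list:
        return [c for c, s in zip(self.clusters, self.cluster_stats)
                if s > self.null_percentile_975]


def _find_clusters(tvals: np.ndarray, threshold: float, adjacency=None):
    """Clusters of adjacent suprathreshold points, separately per sign."""
    masks, stats_ = [], []
    for sign in (1.0, -1.0):
        supra = sign * tvals > threshold
        if not supra.any():
            continue
        if adjacency is None:
            labels, n = ndimage.label(supra)
            for lab in range(1, n + 1):
                m = labels == lab
                masks.append(m)
                stats_.append(np.abs(tvals[m]).sum())
        else:
            idx = np.flatnonzero(supra.ravel())
            sub = sparse.csr_matrix(adjacency)[idx][:, idx]
            n_comp, comp = connected_components(sub, directed=False)
            for lab in range(n_comp):
                m = np.zeros(tvals.size, bool)
                m[idx[comp == lab]] = True
                m = m.reshape(tvals.shape)
                masks.append(m)
                stats_.append(np.abs(tvals[m]).sum())
    return masks, np.asarray(stats_)


def _one_sample_t(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(np.isfinite(t), t, 0.0)


def cluster_perm_test(data_a: np.ndarray, data_b: np.ndarray | None = None,
                      adjacency=None, n_perm: int = 5000, alpha: float = 0.05,
                      seed: int | None = None) -> ClusterResult:
    """Paired / one-sample cluster-based permutation test.

    Parameters
    ----------
    data_a : ndarray, shape (n_units, \\*dims)
        Per-participant maps (power, GC, DAI, regression coefficients ...).
    data_b : ndarray, optional
        Paired condition; if given the test runs on ``data_a - data_b``.
    adjacency : sparse matrix, optional
        Adjacency over the flattened tested dimensions. Default: grid
        adjacency (immediate neighbours along each axis).
    n_perm : int
        Number of sign-flip permutations (exchangeability of the paired
        difference / the sign of the effect under the null).
    alpha : float
        Point-wise two-tailed threshold for cluster formation.
    """
    X = np.asarray(data_a, float)
    if data_b is not None:
        X = X - np.asarray(data_b, float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 units (participants)")
    if n_perm < 2 / alpha:
        warnings.warn("n_perm too small to resolve the requested alpha")
    dims = X.shape[1:]
    Xf = X.reshape(n, -1)

    t_crit = stats.t.ppf(1 - alpha / 2, df=n - 1)
    t_obs = _one_sample_t(Xf).reshape(dims)
    masks, cstats = _find_clusters(t_obs, t_crit, adjacency)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    sumsq = (Xf**2).sum(axis=0)
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        m = signs[i] @ Xf / n
        var = (sumsq / n - m**2) * (n / (n - 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = m / np.sqrt(var / n)
        t_perm = np.where(np.isfinite(t_perm), t_perm, 0.0).reshape(dims)
        _, s = _find_clusters(t_perm, t_crit, adjacency)
        null_max[i] = s.max() if s.size else 0.0

    pvals = np.array([(1 + np.sum(null_max >= s)) / (1 + n_perm) for s in cstats])
    pct = float(np.percentile(null_max, 97.5)) if n_perm else np.nan
    sig = np.zeros(dims, bool)
    for m, s in zip(masks, cstats):
        if s > pct:
            sig |= m
    return ClusterResult(t_obs=t_obs, threshold=float(t_crit), clusters=masks,
                         cluster_stats=cstats, pvals=pvals, sig_mask=sig,
                         null_percentile_975=pct)


# --------------------------------------------------------------------------
# FDR
# --------------------------------------------------------------------------

def fdr_bh(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level ``q``."""
    p = np.asarray(pvals, float)
    mask = np.zeros(p.shape, bool)
    ok = np.isfinite(p)
    if ok.any():
        mask[ok] = multipletests(p[ok], alpha=q, method="fdr_bh")[0]
    return mask


# --------------------------------------------------------------------------
# Gaussian-copula mutual information
# --------------------------------------------------------------------------

def copnorm(x: np.ndarray) -> np.ndarray:
    """Copula-normalise columns: rank-transform to standard-normal scores.

    Makes Gaussian MI estimates invariant to monotone transforms of each
    continuous variable.
    """
    x = np.atleast_2d(np.asarray(x, float))
    if x.shape[0] == 1:
        x = x.T
    ranks = np.argsort(np.argsort(x, axis=0), axis=0) + 1
    return stats.norm.ppf(ranks / (x.shape[0] + 1))


def _gauss_entropy(C: np.ndarray) -> float:
    C = np.atleast_2d(C)
    d = C.shape[0]
    sign, logdet = np.linalg.slogdet(C + 1e-12 * np.eye(d))
    return 0.5 * (d * np.log(2 * np.pi * np.e) + logdet) / np.log(2)


def mi_discrete_target(X: np.ndarray, y: np.ndarray) -> float:
    """Gaussian-model MI (bits) between predictors X and a discrete target.

    ``I = H(X) - sum_y p(y) H(X | y)`` with Gaussian entropies computed
    from class-conditional covariances. Continuous columns should be
    copula-normalised first.
    """
    X = np.atleast_2d(X)
    if X.shape[0] < X.shape[1]:
        X = X.T
    h_total = _gauss_entropy(np.cov(X, rowvar=False, ddof=1))
    classes, counts = np.unique(y, return_counts=True)
    h_cond = 0.0
    for cls, cnt in zip(classes, counts):
        if cnt < X.shape[1] + 2:
            continue
        h_cond += (cnt / y.size) * _gauss_entropy(
            np.cov(X[y == cls], rowvar=False, ddof=1))
    return float(h_total - h_cond)


def _prepare_predictors(df, cols):
    """Copula-normalise continuous columns, centre binary ones, drop
    constants with a warning."""
    out = []
    for c in cols:
        v = np.asarray(df[c], float)
        if np.unique(v).size <= 1:
            warnings.warn(f"constant predictor {c!r} dropped")
            continue
        if np.unique(v).size == 2:
            out.append(v - v.mean())
        else:
            out.append(copnorm(v)[:, 0])
    if not out:
        raise ValueError("no usable predictors")
    return np.column_stack(out)


def mi_model_compare(participants, base: list, added: list,
                     outcome: str = "hit", n_shuffle: int = 50,
                     seed: int | None = None):
    """Does adding predictors improve the MI with single-trial outcome?

    For each participant's trial table, computes bias-corrected
    ``MI(outcome; base)`` and ``MI(outcome; base + added)`` with the
    Gaussian-copula estimator; the bias term is the mean MI over
    ``n_shuffle`` outcome permutations, and corrected MI is floored at 0.
    Returns (delta_mi per participant, t statistic, two-sided p) for the
    group-level one-sample t-test of delta MI against zero.
    """
    rng = np.random.default_rng(seed)
    deltas = []
    for df in participants:
        if len(df) < 100:
            raise ValueError("need at least 100 trials per participant")
        y = np.asarray(df[outcome], int)

        def corrected_mi(cols):
            X = _prepare_predictors(df, cols)
            mi = mi_discrete_target(X, y)
            bias = np.mean([mi_discrete_target(X, rng.permutation(y))
                            for _ in range(n_shuffle)])
            return max(mi - bias, 0.0)

        deltas.append(corrected_mi(list(base) + list(added)) - corrected_mi(base))
    deltas = np.asarray(deltas)
    res = stats.ttest_1samp(deltas, 0.0)
    return deltas, float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# brain-behaviour correlation with cluster correction
# --------------------------------------------------------------------------

def _corr_and_t(C: np.ndarray, b: np.ndarray, method: str):
    """Per-column correlation of C (n_subj, n_points) with b, as t-values."""
    n_pts = C.shape[1]
    r = np.zeros(n_pts)
    for j in range(n_pts):
        col = C[:, j]
        ok = np.isfinite(col) & np.isfinite(b)
        if ok.sum() < 4 or np.std(col[ok]) == 0:
            r[j] = np.nan
            continue
        if method == "spearman":
            r[j] = stats.spearmanr(col[ok], b[ok]).statistic
        else:
            r[j] = stats.pearsonr(col[ok], b[ok]).statistic
    n = np.sum(np.isfinite(b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    return r, np.where(np.isfinite(t), t, 0.0), int(n)


def coeff_threshold_correlation(coeffs: np.ndarray, behaviour: np.ndarray,
                                method: str = "spearman", n_perm: int = 5000,
                                alpha: float = 0.05,
                                seed: int | None = None) -> ClusterResult:
    """Correlate per-participant coefficient spectra with a behavioural
    scalar, cluster-corrected over frequency.

    ``coeffs`` is (n_participants, n_freqs) — e.g. phase-modulation
    magnitudes of power or GC regressions; ``behaviour`` is one scalar per
    participant (e.g. psychometric threshold, or a condition difference).
    The null is generated by permuting the participant pairing.
    """
    C = np.asarray(coeffs, float)
    b = np.asarray(behaviour, float)
    if C.shape[0] < 10:
        raise ValueError("need at least 10 participants")
    n_bad = int(np.sum(~np.isfinite(C)))
    if n_bad:
        logger.info("pairwise-deleting %d missing coefficient values", n_bad)
    const_cols = np.nanstd(C, axis=0) == 0
    if const_cols.any():
        logger.warning("%d constant coefficient columns excluded", const_cols.sum())

    r_obs, t_obs, n_eff = _corr_and_t(C, b, method)
    t_crit = stats.t.ppf(1 - alpha / 2, df=n_eff - 2)
    masks, cstats = _find_clusters(t_obs, t_crit)

    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        _, t_perm, _ = _corr_and_t(C, rng.permutation(b), method)
        _, s = _find_clusters(t_perm, t_crit)
        null_max[i] = s.max() if s.size else 0.0

    pvals = np.array([(1 + np.sum(null_max >= s)) / (1 + n_perm) for s in cstats])
    pct = float(np.percentile(null_max, 97.5))
    sig = np.zeros(t_obs.shape, bool)
    for m, s in zip(masks, cstats):
        if s > pct:
            sig |= m
    res = ClusterResult(t_obs=t_obs, threshold=float(t_crit), clusters=masks,
                        cluster_stats=cstats, pvals=pvals, sig_mask=sig,
                        null_percentile_975=pct)
    res.r_obs = r_obs
    return res
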