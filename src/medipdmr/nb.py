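"""Negative-binomial GLM machinery for count-based differential testing.

The model for peak *i*, sample *j* is

    K_ij ~ NB(mu_ij, alpha_i),   Var = mu + alpha * mu^2
    log mu_ij = log sf_j + x_j' beta_i

with per-sample size factors sf_j (median-of-ratios), per-peak dispersion
alpha_i (gamma-Poisson overdispersion), and a log-link GLM fitted by Fisher
scoring, vectorised across peaks.  Wald tests use the observed information
matrix at the optimum.  Deliberate simplifications relative to the larger
frameworks in this space: no count-outlier handling, no fold-change
shrinkage, and a fixed (equal-weight, log-space) shrinkage of per-peak
dispersions toward a 1/mu trend.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

__all__ = [
    "size_factors",
    "fit_nb_glm",
    "estimate_dispersion",
    "wald_pvalues",
    "bh_adjust",
    "independent_filter",
    "ttest_groups",
]

MIN_DISPERSION = 1e-8


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios normalisation factors, one per sample (column).

    Ratios are taken to the per-peak geometric mean over peaks where every
    sample has a positive count; the returned factors are rescaled so their
    geometric mean is 1.
    """
    counts = np.asarray(counts, dtype=float)
    allpos = (counts > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no peak has positive counts in every sample; "
            "cannot form the geometric-mean reference"
        )
    sub = counts[allpos]
    geo = np.exp(np.mean(np.log(sub), axis=1, keepdims=True))
    sf = np.median(sub / geo, axis=0)
    return sf / np.exp(np.mean(np.log(sf)))


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha) -> np.ndarray:
    """NB2 log-likelihood summed over samples; vectorised over leading axes."""
    alpha = np.asarray(alpha, dtype=float)
    a = np.maximum(alpha, MIN_DISPERSION)
    r = 1.0 / a
    ll = (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1.0)
        + y * np.log(a * mu / (1.0 + a * mu))
        - r * np.log1p(a * mu)
    )
    return ll.sum(axis=-1)


def fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    offsets: np.ndarray | None = None,
    alpha: float | np.ndarray = 0.0,
    max_iter: int = 100,
    tol: float = 1e-10,
):
    """Fit log-link NB GLMs by Fisher scoring, vectorised across peaks.

    Parameters
    ----------
    y : (n_peaks, n_samples) or (n_samples,) counts
    X : (n_samples, p) full-rank design matrix
    offsets : (n_samples,) log size factors, default 0
    alpha : scalar or per-peak NB dispersion; 0 gives Poisson

    Returns
    -------
    beta : (n_peaks, p) coefficients on the natural-log scale
    se : (n_peaks, p) standard errors from the observed information matrix
    converged : (n_peaks,) bool
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    X = np.asarray(X, dtype=float)
    n_peaks, n = y.shape
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank-deficient")
    if offsets is None:
        offsets = np.zeros(n)
    offsets = np.asarray(offsets, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (n_peaks,)).copy()
    alpha = np.maximum(alpha, 0.0)

    # start from a log-mean intercept, zero slopes
    beta = np.zeros((n_peaks, p))
    beta[:, 0] = np.log(np.maximum(y.mean(axis=1), 0.5)) - offsets.mean()
    converged = np.zeros(n_peaks, dtype=bool)
    a = alpha[:, None]

    for _ in range(max_iter):
        eta = offsets[None, :] + beta @ X.T
        mu = np.exp(np.clip(eta, -500, 500))
        # Fisher (expected-information) working weights for NB log link
        w = mu / (1.0 + a * mu)
        score = np.einsum("ij,jk->ik", (y - mu) / (1.0 + a * mu), X)
        info = np.einsum("ij,jk,jl->ikl", w, X, X)
        try:
            step = np.linalg.solve(info, score[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            info = info + 1e-8 * np.eye(p)[None]
            step = np.linalg.solve(info, score[:, :, None])[:, :, 0]
        step = np.clip(step, -10, 10)
        beta = beta + step
        done = np.max(np.abs(step), axis=1) < tol
        converged |= done
        if done.all():
            break

    eta = offsets[None, :] + beta @ X.T
    mu = np.exp(np.clip(eta, -500, 500))
    # observed information: w_obs = mu (1 + alpha y) / (1 + alpha mu)^2
    w_obs = mu * (1.0 + a * y) / (1.0 + a * mu) ** 2
    info = np.einsum("ij,jk,jl->ikl", w_obs, X, X)
    with np.errstate(invalid="ignore"):
        cov = np.linalg.inv(info + 1e-12 * np.eye(p)[None])
        se = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0))
    return beta, se, converged


def estimate_dispersion(
    counts: np.ndarray,
    sf: np.ndarray,
    X: np.ndarray,
    grid: np.ndarray | None = None,
):
    """Per-peak NB dispersions: raw profile-ML, 1/mu trend, shrunken final.

    raw_i maximises the NB likelihood over a log-spaced alpha grid with the
    peak's fitted means held at their (alpha-specific) GLM fit; the trend
    alpha(mu) = a0 + a1/mu is a non-negative least-squares fit of raw
    dispersions on inverse normalised means; the final value is the
    equal-weight log-space average (geometric mean) of raw and trend,
    floored at 1e-8.

    Returns dict with keys 'raw', 'trend', 'final' (each (n_peaks,)) and
    the trend coefficients '(a0, a1)'.
    """
    counts = np.asarray(counts, dtype=float)
    n_peaks, n = counts.shape
    if n - X.shape[1] < 2:
        raise ValueError("need at least 2 residual degrees of freedom")
    if grid is None:
        grid = np.concatenate([[MIN_DISPERSION], np.geomspace(1e-4, 10.0, 61)])
    offsets = np.log(sf)

    # profile likelihood over the grid; refit means at a few anchor alphas
    # (the NB mean fit varies slowly with alpha, so anchors suffice)
    anchors = np.array([MIN_DISPERSION, 0.01, 0.1, 1.0])
    ll = np.full((n_peaks, grid.size), -np.inf)
    anchor_idx = np.abs(np.log10(grid[None, :] + 1e-300) - np.log10(anchors[:, None])).argmin(axis=0)
    for k, a0 in enumerate(anchors):
        cols = np.where(anchor_idx == k)[0]
        if cols.size == 0:
            continue
        beta, _, _ = fit_nb_glm(counts, X, offsets, alpha=a0)
        mu = np.exp(np.clip(offsets[None, :] + beta @ X.T, -500, 500))
        for g in cols:
            ll[:, g] = _nb_loglik(counts, mu, grid[g])
    raw = grid[np.argmax(ll, axis=1)]

    norm = counts / sf[None, :]
    base_mean = norm.mean(axis=1)
    ok = base_mean > 0
    # non-negative LS of raw on [1, 1/mu]
    A = np.column_stack([np.ones(ok.sum()), 1.0 / base_mean[ok]])
    from scipy.optimize import nnls

    coef, _ = nnls(A, raw[ok])
    a0_t, a1_t = float(coef[0]), float(coef[1])
    with np.errstate(divide="ignore"):
        trend = a0_t + a1_t / np.maximum(base_mean, 1e-300)
    trend = np.maximum(trend, MIN_DISPERSION)
    raw_f = np.maximum(raw, MIN_DISPERSION)
    final = np.exp(0.5 * (np.log(raw_f) + np.log(trend)))
    final = np.maximum(final, MIN_DISPERSION)
    return {"raw": raw, "trend": trend, "final": final, "coef": (a0_t, a1_t)}


def wald_pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Two-sided normal-approximation Wald p-values, p = 2 (1 - Phi(|z|))."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    z = np.abs(beta / se)
    return 2.0 * stats.norm.sf(z)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def independent_filter(
    base_mean: np.ndarray,
    pvalues: np.ndarray,
    alpha_fdr: float = 0.05,
    quantiles: np.ndarray | None = None,
):
    """Rejection-maximising independent filtering on the mean-count statistic.

    Scans baseMean-quantile thresholds; for each, BH-adjusts only the
    surviving records and counts rejections at ``alpha_fdr``.  Returns
    ``(threshold, padj)`` where filtered-out records have padj = NaN.  Ties
    in the rejection count go to the smallest threshold (most records kept).
    """
    base_mean = np.asarray(base_mean, dtype=float)
    pvalues = np.asarray(pvalues, dtype=float)
    if base_mean.size == 0:
        return 0.0, np.array([])
    if quantiles is None:
        quantiles = np.arange(0.0, 0.951, 0.01)
    best_q = None
    best_rej = -1
    best_padj = None
    best_thresh = 0.0
    for q in quantiles:
        thresh = np.quantile(base_mean, q) if q > 0 else -np.inf
        keep = base_mean >= thresh
        if not keep.any():
            continue
        padj = np.full(base_mean.size, np.nan)
        padj[keep] = bh_adjust(pvalues[keep])
        rej = int((padj[keep] < alpha_fdr).sum())
        if rej > best_rej:
            best_rej, best_q, best_padj = rej, q, padj
            best_thresh = 0.0 if q == 0 else float(thresh)
    return best_thresh, best_padj


def ttest_groups(a, b):
    """Pooled-variance two-sample Student t-test (two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)
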