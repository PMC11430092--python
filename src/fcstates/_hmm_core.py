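"""Numerical core for full-covariance Gaussian HMM estimation.

Scaled forward-backward recursions and Viterbi decoding are compiled
with numba (the T x K^2 inner loops dominate otherwise); emission
log-likelihoods and the M-step run on BLAS through numpy.  Everything
here operates on plain arrays; model bookkeeping lives in
:mod:`fcstates.hmm`.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.linalg import cholesky, solve_triangular

_LOG2PI = float(np.log(2.0 * np.pi))


def gaussian_log_likelihood(
    X: np.ndarray, means: np.ndarray, covariances: np.ndarray
) -> np.ndarray:
    """Per-sample, per-state Gaussian log density (T x K).

    Uses the whitening form y = (x - mu) L^{-T} with an explicitly
    inverted (small, d x d) Cholesky factor so the T-long dimension
    only enters one GEMM per state.
    """
    t, d = X.shape
    k = means.shape[0]
    out = np.empty((t, k))
    eye = np.eye(d)
    for j in range(k):
        L = cholesky(covariances[j], lower=True, check_finite=False)
        linv = solve_triangular(L, eye, lower=True, check_finite=False)
        y = X @ linv.T - means[j] @ linv.T
        logdet = 2.0 * np.log(np.diag(L)).sum()
        np.square(y, out=y)
        out[:, j] = y.sum(axis=1)
        out[:, j] *= -0.5
        out[:, j] += -0.5 * (d * _LOG2PI + logdet)
    return out


@njit(cache=True)
def _forward_backward(logb, startprob, transmat):
    """Scaled forward-backward.

    Returns (log_likelihood, gamma, xi_sum) where gamma is the T x K
    posterior state probability and xi_sum the K x K expected
    transition counts.
    """
    T, K = logb.shape
    # stabilize emissions per sample
    shift = np.empty(T)
    b = np.empty((T, K))
    for t in range(T):
        m = logb[t, 0]
        for j in range(1, K):
            if logb[t, j] > m:
                m = logb[t, j]
        shift[t] = m
        for j in range(K):
            b[t, j] = np.exp(logb[t, j] - m)

    alpha = np.empty((T, K))
    c = np.empty(T)
    s = 0.0
    for j in range(K):
        alpha[0, j] = startprob[j] * b[0, j]
        s += alpha[0, j]
    c[0] = s
    for j in range(K):
        alpha[0, j] /= s
    for t in range(1, T):
        s = 0.0
        for j in range(K):
            a = 0.0
            for i in range(K):
                a += alpha[t - 1, i] * transmat[i, j]
            a *= b[t, j]
            alpha[t, j] = a
            s += a
        c[t] = s
        for j in range(K):
            alpha[t, j] /= s

    beta = np.ones(K)
    gamma = np.empty((T, K))
    xi_sum = np.zeros((K, K))
    for j in range(K):
        gamma[T - 1, j] = alpha[T - 1, j]
    for t in range(T - 2, -1, -1):
        bb = np.empty(K)
        for j in range(K):
            bb[j] = b[t + 1, j] * beta[j] / c[t + 1]
        for i in range(K):
            for j in range(K):
                xi_sum[i, j] += alpha[t, i] * transmat[i, j] * bb[j]
        newbeta = np.empty(K)
        g = 0.0
        for i in range(K):
            v = 0.0
            for j in range(K):
                v += transmat[i, j] * bb[j]
            newbeta[i] = v
            gamma[t, i] = alpha[t, i] * v
            g += gamma[t, i]
        for i in range(K):
            gamma[t, i] /= g
            beta[i] = newbeta[i]

    ll = 0.0
    for t in range(T):
        ll += np.log(c[t]) + shift[t]
    return ll, gamma, xi_sum


@njit(cache=True)
def _viterbi(logb, log_start, log_trans):
    """Most probable joint state path (max-sum recursion)."""
    T, K = logb.shape
    delta = np.empty((T, K))
    psi = np.zeros((T, K), dtype=np.int64)
    for j in range(K):
        delta[0, j] = log_start[j] + logb[0, j]
    for t in range(1, T):
        for j in range(K):
            best = delta[t - 1, 0] + log_trans[0, j]
            arg = 0
            for i in range(1, K):
                v = delta[t - 1, i] + log_trans[i, j]
                if v > best:
                    best = v
                    arg = i
            delta[t, j] = best + logb[t, j]
            psi[t, j] = arg
    path = np.empty(T, dtype=np.int64)
    best = delta[T - 1, 0]
    arg = 0
    for j in range(1, K):
        if delta[T - 1, j] > best:
            best = delta[T - 1, j]
            arg = j
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best


def forward_backward(
    logb: np.ndarray, startprob: np.ndarray, transmat: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    ll, gamma, xi = _forward_backward(
        np.ascontiguousarray(logb, dtype=np.float64),
        np.ascontiguousarray(startprob, dtype=np.float64),
        np.ascontiguousarray(transmat, dtype=np.float64),
    )
    return float(ll), gamma, xi


def viterbi_path(
    logb: np.ndarray, startprob: np.ndarray, transmat: np.ndarray
) -> tuple[np.ndarray, float]:
    """Viterbi path and its joint log-probability."""
    tiny = 1e-300
    path, score = _viterbi(
        np.ascontiguousarray(logb, dtype=np.float64),
        np.log(np.maximum(startprob, tiny)),
        np.log(np.maximum(transmat, tiny)),
    )
    return np.asarray(path), float(score)


def em_step(
    X: np.ndarray,
    startprob: np.ndarray,
    transmat: np.ndarray,
    means: np.ndarray,
    covariances: np.ndarray,
    cov_floor: float,
    lengths: list[int] | None = None,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One EM iteration; returns (lnL, start', trans', means', covs').

    ``lengths`` splits X into independent sequences (per-subject
    segments of a concatenated fit); posteriors are accumulated across
    segments.  ``cov_floor`` is added to every covariance diagonal,
    guaranteeing the documented variance floor.
    """
    t, d = X.shape
    k = means.shape[0]
    logb = gaussian_log_likelihood(X, means, covariances)
    if lengths is None:
        segments = [(0, t)]
    else:
        bounds = np.concatenate([[0], np.cumsum(lengths)])
        if bounds[-1] != t:
            raise ValueError("lengths do not sum to the number of samples")
        segments = list(zip(bounds[:-1], bounds[1:]))
    ll_total = 0.0
    gamma = np.empty((t, k))
    xi = np.zeros((k, k))
    start_acc = np.zeros(k)
    for s, e in segments:
        ll, g, x = forward_backward(logb[s:e], startprob, transmat)
        ll_total += ll
        gamma[s:e] = g
        xi += x
        start_acc += g[0]
    new_start = start_acc / start_acc.sum()
    row = xi.sum(axis=1, keepdims=True)
    new_trans = np.where(row > 0, xi / np.maximum(row, 1e-300), transmat)
    nk = gamma.sum(axis=0)
    new_means = (gamma.T @ X) / nk[:, None]
    new_covs = np.empty((k, d, d))
    eye = np.eye(d)
    for j in range(k):
        xw = X * gamma[:, j : j + 1]
        s2 = (xw.T @ X) / nk[j]
        mu = new_means[j]
        new_covs[j] = s2 - np.outer(mu, mu) + cov_floor * eye
    return ll_total, new_start, new_trans, new_means, new_covs
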