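"""Independent test oracles: truncated-CME (finite-state-projection)
stationary solvers and explicit thinning convolutions.  These never touch
the generating-function code paths they are used to check."""

from __future__ import annotations

import numpy as np
from scipy import sparse, stats
from scipy.sparse.linalg import spsolve


def _stationary(Q) -> np.ndarray:
    """Stationary distribution of a (column-)generator via a normalized solve."""
    n = Q.shape[0]
    A = sparse.lil_matrix(Q) if not sparse.issparse(Q) else Q.tolil()
    A[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    pi = spsolve(A.tocsc(), b)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _add_rate(Q, i, j, rate):
    """Transition i -> j; diagonal keeps columns summing to zero (FSP censoring)."""
    Q[j, i] += rate
    Q[i, i] -= rate


def constitutive_cme(K: float, gamma: float, n: int) -> np.ndarray:
    Q = sparse.lil_matrix((n, n))
    for x in range(n):
        if x + 1 < n:
            _add_rate(Q, x, x + 1, K)
        if x > 0:
            _add_rate(Q, x, x - 1, gamma * x)
    return _stationary(Q)


def telegraph_cme(kon, koff, kinit, beta, gamma=None, nN=32, nM=1):
    """Telegraph stationary law; returns the joint (nN,) or (nN, nM) marginal
    over molecule counts (gene state summed out)."""
    two = gamma is not None
    nM = nM if two else 1
    dim = 2 * nN * nM

    def idx(s, xn, xm=0):
        return (s * nN + xn) * nM + xm

    Q = sparse.lil_matrix((dim, dim))
    for s in range(2):
        for xn in range(nN):
            for xm in range(nM):
                i = idx(s, xn, xm)
                _add_rate(Q, i, idx(1 - s, xn, xm), kon if s == 0 else koff)
                if s == 1 and xn + 1 < nN:
                    _add_rate(Q, i, idx(s, xn + 1, xm), kinit)
                if two:
                    if xn > 0 and xm + 1 < nM:
                        _add_rate(Q, i, idx(s, xn - 1, xm + 1), beta * xn)
                    if xm > 0:
                        _add_rate(Q, i, idx(s, xn, xm - 1), gamma * xm)
                else:
                    if xn > 0:
                        _add_rate(Q, i, idx(s, xn - 1, xm), beta * xn)
    pi = _stationary(Q).reshape(2, nN, nM)
    marg = pi.sum(axis=0)
    return marg[:, 0] if not two else marg


def bursty_cme(alpha, b, beta, gamma=None, nN=40, nM=1):
    """Bursty (geometric, 0-based, mean b) stationary law on a truncated grid."""
    two = gamma is not None
    nM = nM if two else 1
    dim = nN * nM
    pgeo = 1.0 / (1.0 + b)
    burst = np.array([pgeo * (1 - pgeo) ** k for k in range(nN)])

    def idx(xn, xm=0):
        return xn * nM + xm

    Q = sparse.lil_matrix((dim, dim))
    for xn in range(nN):
        for xm in range(nM):
            i = idx(xn, xm)
            for k in range(1, nN - xn):
                _add_rate(Q, i, idx(xn + k, xm), alpha * burst[k])
            if two:
                if xn > 0 and xm + 1 < nM:
                    _add_rate(Q, i, idx(xn - 1, xm + 1), beta * xn)
                if xm > 0:
                    _add_rate(Q, i, idx(xn, xm - 1), gamma * xm)
            else:
                if xn > 0:
                    _add_rate(Q, i, idx(xn - 1, xm), beta * xn)
    pi = _stationary(Q).reshape(nN, nM)
    return pi[:, 0] if not two else pi


def autocatalytic_cme(alpha, q, gamma, b=None, n=80):
    """Constitutive-or-bursty production with autocatalysis X -> 2X."""
    Q = sparse.lil_matrix((n, n))
    if b is None:
        for x in range(n):
            if x + 1 < n:
                _add_rate(Q, x, x + 1, alpha)
    else:
        pgeo = 1.0 / (1.0 + b)
        burst = np.array([pgeo * (1 - pgeo) ** k for k in range(n)])
        for x in range(n):
            for k in range(1, n - x):
                _add_rate(Q, x, x + k, alpha * burst[k])
    for x in range(n):
        if x + 1 < n and x > 0:
            _add_rate(Q, x, x + 1, q * x)
        if x > 0:
            _add_rate(Q, x, x - 1, gamma * x)
    return _stationary(Q)


def thin_pmf_1d(pmf: np.ndarray, p: float) -> np.ndarray:
    """Explicit binomial-thinning convolution of a 1-D PMF."""
    n = len(pmf)
    out = np.zeros(n)
    for x in range(n):
        if pmf[x] == 0:
            continue
        out[: x + 1] += pmf[x] * stats.binom.pmf(np.arange(x + 1), x, p)
    return out


def thin_pmf_2d(pmf: np.ndarray, pN: float, pM: float) -> np.ndarray:
    """Axis-wise binomial thinning of a joint PMF."""
    out = np.apply_along_axis(thin_pmf_1d, 0, pmf, pN)
    return np.apply_along_axis(thin_pmf_1d, 1, out, pM)


def ssa_autocatalytic(alpha, q, gamma, b, t_end, n_samples, seed) -> np.ndarray:
    """SSA draws from the bursty autocatalytic network at time t_end."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_samples, dtype=np.int64)
    for i in range(n_samples):
        x, t = 0, 0.0
        while True:
            total = alpha + (q + gamma) * x
            t += rng.exponential(1.0 / total)
            if t >= t_end:
                break
            r = rng.uniform() * total
            if r < alpha:
                x += rng.geometric(1.0 / (1.0 + b)) - 1
            elif r < alpha + q * x:
                x += 1
            else:
                x -= 1
        out[i] = x
    return out
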