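"""Coordinate-descent graphical-lasso kernel (numba-compiled).

Solves, for a correlation matrix S and penalty lam >= 0,

    maximize_K  log det K - tr(S K) - lam * sum_{i != j} |K_ij|

by the block coordinate-descent algorithm on the covariance estimate W:
each column update is an L1-penalized quadratic subproblem solved by inner
coordinate descent. The diagonal is not penalized (W_jj = S_jj throughout),
the convention of the regularized-network toolchain this pipeline mirrors.
The kernel is written for repeated warm-started calls along a penalty path
and inside bootstrap loops, where per-call overhead dominates.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _lasso_cd(W11, s12, beta, lam, tol, max_iter):
    p1 = s12.shape[0]
    for _ in range(max_iter):
        dmax = 0.0
        for k in range(p1):
            g = s12[k]
            for m in range(p1):
                if m != k:
                    g -= W11[k, m] * beta[m]
            old = beta[k]
            if g > lam:
                beta[k] = (g - lam) / W11[k, k]
            elif g < -lam:
                beta[k] = (g + lam) / W11[k, k]
            else:
                beta[k] = 0.0
            d = abs(beta[k] - old)
            if d > dmax:
                dmax = d
        if dmax < tol:
            break
    return beta


@njit(cache=True)
def glasso_cd(S, lam, W, B, tol, max_iter, inner_tol, inner_max_iter):
    """One graphical-lasso solve; W and B carry warm-start state.

    Returns (K, W, B, converged). W is the working covariance estimate,
    B the p x p matrix whose column j holds the regression coefficients of
    node j on the others (zeros on the diagonal).
    """
    p = S.shape[0]
    s_off = 0.0
    for i in range(p):
        for j in range(p):
            if i != j:
                s_off += abs(S[i, j])
    thr = tol * s_off / (p * (p - 1)) if s_off > 0 else tol
    idx = np.empty(p - 1, np.int64)
    converged = False
    for _ in range(max_iter):
        dmax = 0.0
        for j in range(p):
            c = 0
            for m in range(p):
                if m != j:
                    idx[c] = m
                    c += 1
            W11 = np.empty((p - 1, p - 1))
            for a in range(p - 1):
                for b in range(p - 1):
                    W11[a, b] = W[idx[a], idx[b]]
            s12 = np.empty(p - 1)
            beta = np.empty(p - 1)
            for a in range(p - 1):
                s12[a] = S[idx[a], j]
                beta[a] = B[idx[a], j]
            beta = _lasso_cd(W11, s12, beta, lam, inner_tol, inner_max_iter)
            for a in range(p - 1):
                B[idx[a], j] = beta[a]
            w12 = W11 @ beta
            for a in range(p - 1):
                d = abs(W[idx[a], j] - w12[a])
                if d > dmax:
                    dmax = d
                W[idx[a], j] = w12[a]
                W[j, idx[a]] = w12[a]
        if dmax < thr:
            converged = True
            break
    K = np.zeros((p, p))
    for j in range(p):
        wb = 0.0
        for m in range(p):
            if m != j:
                wb += W[j, m] * B[m, j]
        kjj = 1.0 / (W[j, j] - wb)
        K[j, j] = kjj
        for m in range(p):
            if m != j:
                K[m, j] = -B[m, j] * kjj
    for i in range(p):
        for j in range(i + 1, p):
            v = 0.5 * (K[i, j] + K[j, i])
            K[i, j] = v
            K[j, i] = v
    return K, W, B, converged
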