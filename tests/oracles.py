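"""Independent reference implementations used only by the test suite.

These deliberately use different algorithms from the package: an ADMM
solver for the graphical lasso, and exhaustive path enumeration for
betweenness, so that agreement is evidence of correctness rather than of
shared code.
"""

from __future__ import annotations

import itertools

import numpy as np


def glasso_admm(S, lam, rho=1.0, max_iter=50_000, tol=1e-10):
    """ADMM solution of max logdet K - tr(SK) - lam * ||K||_1,offdiag."""
    p = S.shape[0]
    Z = np.eye(p)
    U = np.zeros((p, p))
    off = ~np.eye(p, dtype=bool)
    for _ in range(max_iter):
        M = rho * (Z - U) - S
        ew, ev = np.linalg.eigh((M + M.T) / 2)
        kw = (ew + np.sqrt(ew**2 + 4 * rho)) / (2 * rho)
        K = (ev * kw) @ ev.T
        Zold = Z.copy()
        A = K + U
        Z = A.copy()
        Z[off] = np.sign(A[off]) * np.maximum(np.abs(A[off]) - lam / rho, 0)
        U = U + K - Z
        if (
            np.linalg.norm(K - Z) < tol
            and rho * np.linalg.norm(Z - Zold) < tol
        ):
            break
    return (Z + Z.T) / 2


def glasso_objective(S, K, lam):
    sign, ld = np.linalg.slogdet(K)
    off = ~np.eye(K.shape[0], dtype=bool)
    return ld - np.trace(S @ K) - lam * np.abs(K[off]).sum()


def brute_force_bridge_betweenness(W, labels, tol=1e-9):
    """Bridge betweenness by exhaustive enumeration of simple paths.

    Only feasible for small graphs (p <= ~7). For every cross-community
    pair, all simple paths are enumerated, the shortest length found, and
    each intermediate node credited with the fraction of minimum-length
    paths through it.
    """
    W = np.asarray(W, dtype=float)
    p = W.shape[0]
    labels = np.asarray(labels)
    scores = np.zeros(p)
    nodes = range(p)
    for s in nodes:
        for t in nodes:
            if t <= s or labels[s] == labels[t]:
                continue
            best = np.inf
            paths = []
            for k in range(0, p - 1):  # number of intermediates
                for mid in itertools.permutations(
                    [v for v in nodes if v not in (s, t)], k
                ):
                    path = (s, *mid, t)
                    length = 0.0
                    ok = True
                    for a, b in zip(path, path[1:]):
                        if W[a, b] == 0:
                            ok = False
                            break
                        length += 1.0 / abs(W[a, b])
                    if not ok:
                        continue
                    if length < best - tol:
                        best = length
                        paths = [path]
                    elif abs(length - best) <= tol * max(1.0, best):
                        paths.append(path)
            if not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    scores[v] += 1.0 / len(paths)
    return scores
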