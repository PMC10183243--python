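"""Sparse Gaussian graphical model estimation with EBIC selection.

The network is the matrix of partial correlations implied by an
L1-penalized precision-matrix estimate (graphical lasso, off-diagonal
penalty only). The penalty is chosen on a descending log-spaced path by the
Extended Bayesian Information Criterion

    EBIC(K) = -2 l(K) + E log n + 4 E gamma log p,

where l = (n/2)(log det K - tr(R K)) is the Gaussian profile
log-likelihood up to constants, E the number of edges (nonzero
upper-triangle off-diagonals) and gamma the extra-penalty hyperparameter
(default 0.50). Ties are broken toward the sparser model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ._solver import glasso_cd
from .data import CommunityMap, ValidationError
from .transform import CorrelationMatrix

logger = logging.getLogger(__name__)

DEFAULT_GAMMA = 0.50
DEFAULT_N_LAMBDA = 100
DEFAULT_LAMBDA_MIN_RATIO = 0.01

_EDGE_EPS = 1e-10  # numerical-zero threshold when counting edges


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class PrecisionEstimate:
    """A single graphical-lasso solution along the penalty path."""

    K: np.ndarray
    lam: float
    loglik: float
    n_edges: int


@dataclass(frozen=True)
class GGMNetwork:
    """Partial-correlation network with its selection metadata."""

    W: np.ndarray
    item_ids: tuple[str, ...]
    lam: float
    ebic: float
    gamma: float
    n_edges: int

    @property
    def p(self) -> int:
        return self.W.shape[0]

    def edge_list(self) -> list[tuple[str, str, float]]:
        p = self.p
        out = []
        for i in range(p):
            for j in range(i + 1, p):
                w = self.W[i, j]
                if abs(w) > _EDGE_EPS:
                    out.append((self.item_ids[i], self.item_ids[j], float(w)))
        return out

    def to_edge_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.edge_list(), columns=["item_a", "item_b", "weight"]
        ).to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "item_ids": list(self.item_ids),
            "lambda": self.lam,
            "ebic": self.ebic,
            "gamma": self.gamma,
            "n_edges": self.n_edges,
            "weights": self.W.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_graphml(self, path: str | Path, cm: CommunityMap | None = None) -> None:
        import networkx as nx

        g = self.to_networkx(cm)
        nx.write_graphml(g, path)

    def to_networkx(self, cm: CommunityMap | None = None):
        import networkx as nx

        g = nx.Graph()
        labels = cm.labels_for(self.item_ids) if cm is not None else None
        for idx, item in enumerate(self.item_ids):
            attrs = {"community": str(labels[idx])} if labels is not None else {}
            g.add_node(item, **attrs)
        for a, b, w in self.edge_list():
            g.add_edge(a, b, weight=w, length=1.0 / abs(w))
        return g


def partial_correlations(K: np.ndarray) -> np.ndarray:
    """Edge weights w_ij = -K_ij / sqrt(K_ii K_jj), zero diagonal."""
    K = np.asarray(K, dtype=float)
    d = np.diag(K)
    if np.any(d <= 0):
        raise ValidationError("precision matrix has nonpositive diagonal")
    denom = np.sqrt(np.outer(d, d))
    W = -K / denom
    np.fill_diagonal(W, 0.0)
    return (W + W.T) / 2.0


def _count_edges(K: np.ndarray) -> int:
    off = K[np.triu_indices_from(K, k=1)]
    return int(np.sum(np.abs(off) > _EDGE_EPS))


def _profile_loglik(K: np.ndarray, R: np.ndarray, n: int) -> float:
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        raise ValidationError("precision estimate is not positive definite")
    return 0.5 * n * (logdet - float(np.sum(R * K)))


def _repair_psd(r: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Clip negative eigenvalues of a borderline correlation matrix."""
    w, v = np.linalg.eigh(r)
    if w[0] >= eps:
        return r
    logger.warning(
        "correlation matrix min eigenvalue %.3g < 0; clipping at %.1g", w[0], eps
    )
    r2 = (v * np.maximum(w, eps)) @ v.T
    d = np.sqrt(np.diag(r2))
    r2 = r2 / np.outer(d, d)
    return (r2 + r2.T) / 2.0


def lambda_grid(
    r: np.ndarray,
    n_lambda: int = DEFAULT_N_LAMBDA,
    min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
) -> np.ndarray:
    """Descending log-spaced penalty grid from lambda_max = max off-diag |r|."""
    off = np.abs(r - np.diag(np.diag(r)))
    lam_max = float(off.max())
    if lam_max <= 0:
        return np.array([0.0])
    return np.geomspace(lam_max, min_ratio * lam_max, n_lambda)


def glasso_path(
    r: CorrelationMatrix | np.ndarray,
    lambdas: Sequence[float],
    *,
    n: int | None = None,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> list[PrecisionEstimate]:
    """Solve the graphical lasso at each penalty, warm-starting down the path.

    ``lambdas`` should be descending; the log-likelihood stored on each
    estimate uses ``n`` (taken from the CorrelationMatrix when available,
    else 1, in which case only relative comparisons at fixed n make sense).
    A zero penalty returns the unpenalized MLE, the inverse correlation
    matrix.
    """
    if isinstance(r, CorrelationMatrix):
        R, n = r.r, r.n
    else:
        R = np.asarray(r, dtype=float)
        n = n or 1
    lambdas = np.asarray(list(lambdas), dtype=float)
    if np.any(lambdas < 0):
        raise ValidationError("penalties must be nonnegative")
    R = _repair_psd(R)
    p = R.shape[0]
    W = R.copy()
    B = np.zeros((p, p))
    out: list[PrecisionEstimate] = []
    for lam in lambdas:
        if lam < 1e-12:
            try:
                K = np.linalg.inv(R)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(
                    "lambda = 0 requires an invertible correlation matrix"
                ) from exc
            K = (K + K.T) / 2.0
        else:
            K, W, B, converged = glasso_cd(
                R, float(lam), W, B, tol, max_iter, tol * 1e-2, 10_000
            )
            if not converged:
                raise ConvergenceError(
                    f"graphical lasso did not converge at lambda = {lam:.4g}"
                )
        out.append(
            PrecisionEstimate(
                K=K,
                lam=float(lam),
                loglik=_profile_loglik(K, R, n),
                n_edges=_count_edges(K),
            )
        )
    return out


def ebic_score(
    est: PrecisionEstimate,
    r: CorrelationMatrix | np.ndarray,
    n: int,
    gamma: float = DEFAULT_GAMMA,
) -> float:
    """EBIC of one path estimate; gamma = 0 reduces to the ordinary BIC."""
    if gamma < 0:
        raise ValidationError("gamma must be nonnegative")
    R = r.r if isinstance(r, CorrelationMatrix) else np.asarray(r, dtype=float)
    p = R.shape[0]
    ll = _profile_loglik(est.K, R, n)
    E = est.n_edges
    return -2.0 * ll + E * np.log(n) + 4.0 * E * gamma * np.log(p)


def select_network(
    r: CorrelationMatrix,
    n: int | None = None,
    gamma: float = DEFAULT_GAMMA,
    *,
    n_lambda: int = DEFAULT_N_LAMBDA,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
    tol: float = 1e-4,
) -> GGMNetwork:
    """Estimate the partial-correlation network with EBIC model selection.

    The penalty path has ``n_lambda`` log-spaced values from lambda_max
    down to ``lambda_min_ratio * lambda_max``; the EBIC-minimizing model is
    returned, ties resolved toward the sparser (larger-penalty) model.
    """
    n = n or r.n
    lambdas = lambda_grid(r.r, n_lambda, lambda_min_ratio)
    path = glasso_path(r, lambdas, n=n, tol=tol)
    scores = np.array([ebic_score(est, r, n, gamma) for est in path])
    # path is in descending lambda, so the first argmin is the sparsest tie
    best = int(np.argmin(scores))
    est = path[best]
    W = partial_correlations(est.K)
    # enforce an identical sparsity pattern (guards symmetrization dust)
    W[np.abs(est.K - np.diag(np.diag(est.K))) <= _EDGE_EPS] = 0.0
    np.fill_diagonal(W, 0.0)
    return GGMNetwork(
        W=W,
        item_ids=r.item_ids,
        lam=est.lam,
        ebic=float(scores[best]),
        gamma=gamma,
        n_edges=est.n_edges,
    )
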