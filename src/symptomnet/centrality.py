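"""Node centrality and bridge statistics on the estimated network.

Strength is the sum of absolute edge weights at a node; bridge strength
restricts that sum to edges crossing community boundaries, so that
strength = within_strength + bridge_strength exactly. Bridge betweenness
counts how often a node lies on shortest paths between nodes of *different*
communities, with edge lengths 1/|w| (stronger associations are shorter)
and fractional credit split over tied shortest paths. Indices are reported
raw and as z-scores standardized over the p nodes.
"""

from __future__ import annotations

import heapq
import warnings

import numpy as np
import pandas as pd

from .data import CommunityMap, ValidationError
from .ggm import GGMNetwork

_TIE_TOL = 1e-9


def _weights(W: GGMNetwork | np.ndarray) -> np.ndarray:
    W = W.W if isinstance(W, GGMNetwork) else np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValidationError("weight matrix must be square")
    return W


def strength(W: GGMNetwork | np.ndarray) -> np.ndarray:
    """s_i = sum_j |w_ij|."""
    A = np.abs(_weights(W))
    np.fill_diagonal(A, 0.0)
    return A.sum(axis=1)


def _cross_mask(item_ids, cm: CommunityMap) -> np.ndarray:
    labels = cm.labels_for(item_ids)
    return labels[:, None] != labels[None, :]


def bridge_strength(
    W: GGMNetwork | np.ndarray,
    cm: CommunityMap,
    item_ids=None,
) -> np.ndarray:
    """b_i = sum over j in other communities of |w_ij|."""
    if isinstance(W, GGMNetwork):
        item_ids = W.item_ids
    A = np.abs(_weights(W))
    np.fill_diagonal(A, 0.0)
    return (A * _cross_mask(item_ids, cm)).sum(axis=1)


def within_strength(
    W: GGMNetwork | np.ndarray,
    cm: CommunityMap,
    item_ids=None,
) -> np.ndarray:
    """Strength restricted to same-community edges."""
    if isinstance(W, GGMNetwork):
        item_ids = W.item_ids
    A = np.abs(_weights(W))
    np.fill_diagonal(A, 0.0)
    return (A * ~_cross_mask(item_ids, cm)).sum(axis=1)


def _dijkstra_counts(lengths: list[list[tuple[int, float]]], s: int, p: int):
    """Single-source shortest-path lengths and path counts with tie tolerance."""
    dist = np.full(p, np.inf)
    sigma = np.zeros(p)
    dist[s] = 0.0
    sigma[s] = 1.0
    done = np.zeros(p, dtype=bool)
    heap: list[tuple[float, int]] = [(0.0, s)]
    while heap:
        d, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        for v, length in lengths[u]:
            nd = d + length
            if nd < dist[v] - _TIE_TOL:
                dist[v] = nd
                sigma[v] = sigma[u]
                heapq.heappush(heap, (nd, v))
            elif abs(nd - dist[v]) <= _TIE_TOL * max(1.0, dist[v]):
                sigma[v] += sigma[u]
    return dist, sigma


def bridge_betweenness(
    W: GGMNetwork | np.ndarray,
    cm: CommunityMap,
    item_ids=None,
) -> np.ndarray:
    """Fractional shortest-path counts between cross-community pairs.

    For every unordered pair (A, C) with different communities, each
    intermediate node B accumulates the fraction of shortest A-C paths
    passing through it; disconnected pairs contribute nothing.
    """
    if isinstance(W, GGMNetwork):
        item_ids = W.item_ids
    A = _weights(W)
    p = A.shape[0]
    labels = cm.labels_for(item_ids)

    lengths: list[list[tuple[int, float]]] = [[] for _ in range(p)]
    for i in range(p):
        for j in range(p):
            if i != j and abs(A[i, j]) > 0:
                lengths[i].append((j, 1.0 / abs(A[i, j])))

    D = np.empty((p, p))
    SIG = np.empty((p, p))
    for s in range(p):
        D[s], SIG[s] = _dijkstra_counts(lengths, s, p)

    scores = np.zeros(p)
    for s in range(p):
        for t in range(s + 1, p):
            if labels[s] == labels[t] or not np.isfinite(D[s, t]):
                continue
            dst = D[s, t]
            for b in range(p):
                if b == s or b == t:
                    continue
                through = D[s, b] + D[b, t]
                if np.isfinite(through) and abs(through - dst) <= _TIE_TOL * max(
                    1.0, dst
                ):
                    scores[b] += SIG[s, b] * SIG[b, t] / SIG[s, t]
    return scores


def bridge_closeness(
    W: GGMNetwork | np.ndarray,
    cm: CommunityMap,
    item_ids=None,
) -> np.ndarray:
    """Inverse mean shortest-path distance to all other-community nodes.

    Provided for completeness; excluded from default reports because this
    family of indices is rarely stable under case-dropping.
    """
    if isinstance(W, GGMNetwork):
        item_ids = W.item_ids
    A = _weights(W)
    p = A.shape[0]
    labels = cm.labels_for(item_ids)
    lengths: list[list[tuple[int, float]]] = [[] for _ in range(p)]
    for i in range(p):
        for j in range(p):
            if i != j and abs(A[i, j]) > 0:
                lengths[i].append((j, 1.0 / abs(A[i, j])))
    out = np.zeros(p)
    for i in range(p):
        dist, _ = _dijkstra_counts(lengths, i, p)
        other = labels != labels[i]
        d = dist[other]
        out[i] = 0.0 if np.any(~np.isfinite(d)) or d.size == 0 else d.size / d.sum()
    return out


def zstandardize(values: np.ndarray) -> np.ndarray:
    """(x - mean) / sample SD; all zeros (with a warning) if SD = 0."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("z-standardization needs at least 2 nodes")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("constant index vector; z-scores set to 0", stacklevel=2)
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def node_metrics(net: GGMNetwork, cm: CommunityMap) -> pd.DataFrame:
    """Per-node centrality table (raw and z-standardized)."""
    s = strength(net)
    b = bridge_strength(net, cm)
    w = within_strength(net, cm)
    bb = bridge_betweenness(net, cm)
    return pd.DataFrame(
        {
            "node": list(net.item_ids),
            "community": cm.labels_for(net.item_ids),
            "strength": s,
            "strength_z": zstandardize(s),
            "bridge_strength": b,
            "bridge_strength_z": zstandardize(b),
            "within_strength": w,
            "bridge_betweenness": bb,
            "bridge_betweenness_z": zstandardize(bb),
        }
    )
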