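"""Nodewise predictability: variance of each node explained by the rest.

Each (transformed) item is regressed on all other items with an L1-penalized
linear model; the penalty is selected by EBIC with gamma = 0.25, the
convention of the nodewise mixed-graphical-model literature this index
comes from. Predictability is R^2 against the intercept-only model, clipped
to [0, 1]. Because estimation is penalized, R^2 is conservative: a node
with no detectable neighbours gets (near) zero, not overfit noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path

from .data import ValidationError
from .transform import TransformedMatrix

PREDICTABILITY_GAMMA = 0.25
_N_ALPHA = 100
_ALPHA_MIN_RATIO = 0.01


@dataclass(frozen=True)
class PredictabilityTable:
    """Per-node R^2 and its mean."""

    table: pd.DataFrame  # columns: node, r2
    mean_r2: float

    def r2(self) -> np.ndarray:
        return self.table["r2"].to_numpy()


def _ebic_lasso_r2(y: np.ndarray, X: np.ndarray, gamma: float) -> float:
    """R^2 of the EBIC-selected lasso fit of y on X (both centered)."""
    n, q = X.shape
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    tss = float(yc @ yc)
    if tss <= 0:
        raise ValidationError("degenerate (constant) response column")
    alpha_max = np.max(np.abs(Xc.T @ yc)) / n
    if alpha_max <= 0:
        return 0.0
    alphas = np.geomspace(alpha_max, _ALPHA_MIN_RATIO * alpha_max, _N_ALPHA)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duality-gap chatter at tiny alphas
        _, coefs, _ = lasso_path(Xc, yc, alphas=alphas)
    resid = yc[:, None] - Xc @ coefs
    rss = np.einsum("ij,ij->j", resid, resid)
    rss = np.maximum(rss, 1e-12 * tss)
    k = np.count_nonzero(coefs, axis=0)
    ebic = n * np.log(rss / n) + k * np.log(n) + 2.0 * gamma * k * np.log(q)
    best = int(np.argmin(ebic))  # alphas descend, so first argmin = sparsest
    # unpenalized refit on the selected support: R^2 should measure the
    # variance the selected neighbours explain, free of shrinkage bias
    support = np.flatnonzero(coefs[:, best])
    if support.size == 0:
        return 0.0
    if support.size < n:
        beta, *_ = np.linalg.lstsq(Xc[:, support], yc, rcond=None)
        rss_refit = float(np.sum((yc - Xc[:, support] @ beta) ** 2))
    else:  # saturated fallback: keep the penalized residual
        rss_refit = float(rss[best])
    r2 = 1.0 - rss_refit / tss
    return float(np.clip(r2, 0.0, 1.0))


def node_predictability(
    z: TransformedMatrix | np.ndarray,
    gamma: float = PREDICTABILITY_GAMMA,
    item_ids=None,
) -> PredictabilityTable:
    """Per-node share of variance explained by all other nodes."""
    if isinstance(z, TransformedMatrix):
        Z, item_ids = z.z, z.item_ids
    else:
        Z = np.asarray(z, dtype=float)
        if item_ids is None:
            item_ids = tuple(f"v{j}" for j in range(Z.shape[1]))
    n, p = Z.shape
    if n <= p:
        warnings.warn(
            f"n = {n} <= p = {p}: nodewise regressions are weakly determined",
            stacklevel=2,
        )
    if np.any(Z.std(axis=0) == 0):
        raise ValidationError("degenerate (constant) column in input")
    r2 = np.empty(p)
    for i in range(p):
        mask = np.arange(p) != i
        r2[i] = _ebic_lasso_r2(Z[:, i], Z[:, mask], gamma)
    table = pd.DataFrame({"node": list(item_ids), "r2": r2})
    return PredictabilityTable(table, float(r2.mean()))
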