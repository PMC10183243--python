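"""Nonparanormal (Gaussian-copula) transformation and correlations.

Ordinal item scores are mapped column-wise through a Winsorized empirical
CDF and the standard-normal quantile function. The transform is rank-based,
so any strictly increasing recoding of a column leaves the result (and all
downstream correlations) unchanged; ties share a value via average ranks.
The Winsorization bound delta_n = 1 / (4 n^{1/4} sqrt(pi log n)) keeps the
transformed values finite and is the standard truncation rate for this
estimator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import ItemResponseMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TransformedMatrix:
    """Columns of the input mapped to the standard-normal scale."""

    z: np.ndarray
    item_ids: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.z.shape[0]

    @property
    def p(self) -> int:
        return self.z.shape[1]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pearson correlations of the transformed columns."""

    r: np.ndarray
    item_ids: tuple[str, ...]
    n: int

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValidationError("correlation matrix must be square")
        object.__setattr__(self, "r", r)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.r, index=list(self.item_ids),
                     columns=list(self.item_ids)).to_csv(path)


def winsorization_bound(n: int) -> float:
    """Truncation level delta_n for the shrunken empirical CDF."""
    return 1.0 / (4.0 * n**0.25 * np.sqrt(np.pi * np.log(n)))


def npn_transform(x: ItemResponseMatrix | np.ndarray,
                  item_ids: tuple[str, ...] | None = None) -> TransformedMatrix:
    """Apply the nonparanormal transformation column by column.

    Average ranks are converted to the shrunken empirical CDF rank/(n+1),
    Winsorized at [delta_n, 1 - delta_n], and mapped through the normal
    quantile function. Requires n >= 3 and at least two distinct values per
    column (a constant item carries no copula information).
    """
    if isinstance(x, ItemResponseMatrix):
        values, item_ids = x.values, x.item_ids
    else:
        values = np.asarray(x, dtype=float)
        if item_ids is None:
            item_ids = tuple(f"v{j}" for j in range(values.shape[1]))
    n, p = values.shape
    if n < 3:
        raise ValidationError("nonparanormal transform needs n >= 3")
    z = np.empty((n, p), dtype=float)
    delta = winsorization_bound(n)
    for j in range(p):
        col = values[:, j]
        if np.all(col == col[0]):
            raise ValidationError(
                f"item {item_ids[j]!r} is constant; cannot transform"
            )
        u = stats.rankdata(col, method="average") / (n + 1.0)
        z[:, j] = stats.norm.ppf(np.clip(u, delta, 1.0 - delta))
    return TransformedMatrix(z, tuple(item_ids))


def correlation_matrix(z: TransformedMatrix) -> CorrelationMatrix:
    """Pearson product-moment correlations of the transformed columns."""
    if z.n < z.p:
        warnings.warn(
            f"n = {z.n} < p = {z.p}: correlation matrix is rank-deficient",
            stacklevel=2,
        )
    sd = z.z.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValidationError(
            f"zero-variance transformed column(s): "
            f"{[z.item_ids[j] for j in dead]}"
        )
    r = np.corrcoef(z.z, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r, z.item_ids, z.n)
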