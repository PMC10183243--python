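"""Case-dropping bootstrap stability of node indices (CS-coefficient).

Robustness of a node index (strength, bridge strength, predictability) is
assessed by repeatedly re-running the whole estimation pipeline on random
subsamples with a growing fraction of respondents removed, and correlating
the subsample index vector with the full-sample one. The CS-coefficient is
the largest drop proportion at which, with the required probability
(default 95%), that correlation stays at or above the threshold (default
0.7). Values below 0.25 indicate insufficient stability; above 0.50 is
preferred.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .centrality import bridge_strength, strength
from .data import CommunityMap, ItemResponseMatrix, ValidationError
from .ggm import DEFAULT_GAMMA, GGMNetwork, select_network
from .predictability import node_predictability
from .transform import correlation_matrix, npn_transform

DEFAULT_DROP_GRID: tuple[float, ...] = tuple(
    np.round(np.arange(0.05, 0.751, 0.05), 2)
)
DEFAULT_B = 1000
DEFAULT_COR_THRESHOLD = 0.7
DEFAULT_CONFIDENCE = 0.95

INDEX_NAMES = ("strength", "bridge_strength", "predictability")


@dataclass(frozen=True)
class StabilityResult:
    """Bootstrap correlations per drop proportion for one node index."""

    index: str
    proportions: tuple[float, ...]
    correlations: np.ndarray  # shape (len(proportions), B)
    seed: int

    @property
    def B(self) -> int:
        return self.correlations.shape[1]

    def mean_correlations(self) -> np.ndarray:
        return np.nanmean(self.correlations, axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pi, prop in enumerate(self.proportions):
            for b in range(self.B):
                rows.append((self.index, prop, b, self.correlations[pi, b]))
        return pd.DataFrame(
            rows, columns=["index", "proportion", "replicate", "correlation"]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _pipeline_network(
    values: np.ndarray,
    item_ids,
    gamma: float,
    n_lambda: int,
) -> GGMNetwork:
    z = npn_transform(values, tuple(item_ids))
    r = correlation_matrix(z)
    return select_network(r, gamma=gamma, n_lambda=n_lambda)


def _index_fn(
    index: str,
    item_ids,
    cm: CommunityMap | None,
    gamma: float,
    n_lambda: int,
) -> Callable[[np.ndarray], np.ndarray]:
    if index == "strength":
        return lambda v: strength(_pipeline_network(v, item_ids, gamma, n_lambda))
    if index == "bridge_strength":
        if cm is None:
            raise ValidationError("bridge_strength stability needs a CommunityMap")
        return lambda v: bridge_strength(
            _pipeline_network(v, item_ids, gamma, n_lambda), cm
        )
    if index == "predictability":
        return lambda v: node_predictability(
            npn_transform(v, tuple(item_ids))
        ).r2()
    raise ValidationError(f"unknown index {index!r}; choose from {INDEX_NAMES}")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    # a constant vector (e.g. an empty subsample network) carries no rank
    # information about the index: record complete instability, not NaN
    if np.array_equal(a, b):
        return 1.0
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def case_drop_bootstrap(
    x: ItemResponseMatrix,
    index: str = "strength",
    *,
    cm: CommunityMap | None = None,
    proportions: Sequence[float] = DEFAULT_DROP_GRID,
    B: int = DEFAULT_B,
    seed: int = 0,
    gamma: float = DEFAULT_GAMMA,
    n_lambda: int = 100,
) -> StabilityResult:
    """Correlate subsample node-index vectors with the full-sample vector.

    For every drop proportion, ``B`` uniform without-replacement subsamples
    are drawn and the complete pipeline (nonparanormal transform ->
    correlations -> EBIC graphical lasso -> index) is re-run on each. The
    RNG stream is derived per (proportion, replicate) from the master seed,
    so results do not depend on execution order. Subsamples whose index
    vector is constant (typically an empty network) are recorded as
    correlation 0, counting fully against stability.
    """
    proportions = tuple(float(p) for p in proportions)
    n, p = x.n, x.p
    for prop in proportions:
        if not 0.0 <= prop < 1.0:
            raise ValidationError(f"drop proportion {prop} outside [0, 1)")
        if round(n * (1.0 - prop)) < p + 5:
            raise ValidationError(
                f"drop proportion {prop} leaves fewer than p + 5 = {p + 5} cases"
            )
    fn = _index_fn(index, x.item_ids, cm, gamma, n_lambda)
    full = fn(x.values)
    corrs = np.empty((len(proportions), B))
    for pi, prop in enumerate(proportions):
        m = int(round(n * (1.0 - prop)))
        for b in range(B):
            if m == n:
                corrs[pi, b] = 1.0
                continue
            rng = np.random.Generator(
                np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(pi, b)))
            )
            rows = np.sort(rng.choice(n, size=m, replace=False))
            corrs[pi, b] = _pearson(fn(x.values[rows]), full)
    return StabilityResult(index, proportions, corrs, seed)


def cs_coefficient(
    res: StabilityResult,
    cor_threshold: float = DEFAULT_COR_THRESHOLD,
    confidence: float = DEFAULT_CONFIDENCE,
) -> float:
    """Largest drop proportion retaining the correlation with the stated
    probability; 0 if no grid point qualifies."""
    if not res.proportions:
        raise ValidationError("empty drop-proportion grid")
    cs = 0.0
    for pi, prop in enumerate(res.proportions):
        c = res.correlations[pi]
        share = float(np.mean(np.nan_to_num(c, nan=-np.inf) >= cor_threshold))
        if share >= confidence and prop > cs:
            cs = prop
    return cs


def interpret_cs(cs: float) -> str:
    """Qualitative stability label for a CS-coefficient."""
    if not 0.0 <= cs <= 1.0:
        raise ValidationError("CS-coefficient must lie in [0, 1]")
    if cs < 0.25:
        return "insufficient"
    if cs <= 0.50:
        return "acceptable"
    return "preferred"
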