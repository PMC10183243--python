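"""Reading, validating and summarizing questionnaire response data.

The analysis input is a respondent x item matrix of ordinal scores on the
DASS-21 four-point scale (0 = "did not apply to me at all" ... 3 = "applied
to me very much"), together with a community map assigning each item to one
of the Stress / Anxiety / Depression subscales. Respondents with any
missing (or, by default, out-of-range) response are removed before analysis
(listwise deletion).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Items 1-7 form the Stress subscale, 8-14 Anxiety, 15-21 Depression.
DASS21_ITEMS: tuple[str, ...] = tuple(f"dass{i}" for i in range(1, 22))

DASS21_COMMUNITIES: dict[str, tuple[str, ...]] = {
    "Stress": tuple(f"dass{i}" for i in range(1, 8)),
    "Anxiety": tuple(f"dass{i}" for i in range(8, 15)),
    "Depression": tuple(f"dass{i}" for i in range(15, 22)),
}

SCALE_MIN, SCALE_MAX = 0, 3


class SchemaError(ValueError):
    """Input file does not match the expected layout."""


class ValidationError(ValueError):
    """Input values violate the instrument's constraints."""


@dataclass(frozen=True)
class ItemResponseMatrix:
    """Complete-case respondent x item matrix of ordinal scores.

    Attributes
    ----------
    values : (n, p) int array, every entry in {0, 1, 2, 3}
    item_ids : ordered item labels, length p
    n_dropped : respondents removed during ingestion (listwise deletion)
    """

    values: np.ndarray
    item_ids: tuple[str, ...]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValidationError("response matrix must be 2-dimensional")
        if v.shape[1] != len(self.item_ids):
            raise ValidationError("item_ids length must match column count")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValidationError("item_ids must be unique")
        if v.size and (np.any(v < SCALE_MIN) or np.any(v > SCALE_MAX)):
            raise ValidationError("scores must lie in [0, 3]")
        object.__setattr__(self, "values", v.astype(np.int64))
        object.__setattr__(self, "item_ids", tuple(self.item_ids))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.item_ids))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def ingestion_log(self) -> dict[str, int]:
        return {
            "n_read": self.n + self.n_dropped,
            "n_dropped": self.n_dropped,
            "n_retained": self.n,
        }


@dataclass(frozen=True)
class CommunityMap:
    """Item -> community assignment (communities are pre-assigned subscales)."""

    assignment: Mapping[str, str]
    communities: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        assignment = dict(self.assignment)
        communities = tuple(self.communities) or tuple(
            dict.fromkeys(assignment.values())
        )
        missing = set(assignment.values()) - set(communities)
        if missing:
            raise SchemaError(f"communities {sorted(missing)} not declared")
        object.__setattr__(self, "assignment", assignment)
        object.__setattr__(self, "communities", communities)

    def labels_for(self, item_ids: Sequence[str]) -> np.ndarray:
        """Community label per item, erroring on unassigned items."""
        missing = [i for i in item_ids if i not in self.assignment]
        if missing:
            raise SchemaError(f"items without community assignment: {missing}")
        return np.array([self.assignment[i] for i in item_ids])

    def members(self, community: str) -> tuple[str, ...]:
        return tuple(i for i, c in self.assignment.items() if c == community)


def dass21_community_map() -> CommunityMap:
    """The built-in DASS-21 preset: 3 subscales x 7 items."""
    assignment = {
        item: comm for comm, items in DASS21_COMMUNITIES.items() for item in items
    }
    return CommunityMap(assignment, tuple(DASS21_COMMUNITIES))


def load_community_map(path: str | Path | None = None) -> CommunityMap:
    """Load a community map from YAML/JSON ``{community: [item, ...]}``.

    ``path=None`` or the string ``"dass21"`` returns the built-in preset.
    Raises :class:`SchemaError` if an item is assigned twice.
    """
    if path is None or str(path) == "dass21":
        return dass21_community_map()
    raw = Path(path).read_text()
    try:
        spec = yaml.safe_load(raw)  # YAML is a JSON superset
    except yaml.YAMLError as exc:
        raise SchemaError(f"cannot parse community map {path}: {exc}") from exc
    if not isinstance(spec, dict):
        raise SchemaError("community map must be a mapping {community: [items]}")
    assignment: dict[str, str] = {}
    for comm, items in spec.items():
        for item in items:
            item = str(item)
            if item in assignment:
                raise SchemaError(f"item {item!r} assigned to more than one community")
            assignment[item] = str(comm)
    return CommunityMap(assignment, tuple(str(c) for c in spec))


def read_responses(
    path: str | Path,
    item_ids: Sequence[str] = DASS21_ITEMS,
    *,
    strict: bool = False,
) -> ItemResponseMatrix:
    """Read a CSV of item responses, applying listwise deletion.

    Rows with any missing value among the named items are dropped. Scores
    outside 0-3 (the instrument admits only four categories) are treated as
    invalid and the row is likewise dropped with a warning, unless
    ``strict=True`` in which case they raise :class:`ValidationError`.
    Non-integer scores always raise, naming the row and item.
    """
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    missing_cols = [c for c in item_ids if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing item columns: {missing_cols}")
    sub = df[list(item_ids)]

    numeric = sub.apply(pd.to_numeric, errors="coerce")
    finite = numeric.notna()
    frac = numeric.where(finite, 0.0) % 1
    non_integer = finite & (frac != 0)
    if non_integer.any().any():
        row = int(non_integer.any(axis=1).idxmax())
        item = non_integer.loc[row].idxmax()
        raise ValidationError(
            f"non-integer score at row {row}, item {item!r}: {sub.loc[row, item]!r}"
        )
    out_of_range = finite & ((numeric < SCALE_MIN) | (numeric > SCALE_MAX))
    if out_of_range.any().any():
        n_bad = int(out_of_range.any(axis=1).sum())
        if strict:
            row = int(out_of_range.any(axis=1).idxmax())
            item = out_of_range.loc[row].idxmax()
            raise ValidationError(
                f"out-of-range score at row {row}, item {item!r}: "
                f"{sub.loc[row, item]!r}"
            )
        logger.warning(
            "%d row(s) contain out-of-range scores; treated as missing "
            "and excluded (listwise deletion)",
            n_bad,
        )
    keep = (finite & ~out_of_range).all(axis=1)
    retained = numeric.loc[keep].to_numpy(dtype=np.int64)
    n_dropped = int(len(sub) - keep.sum())
    if n_dropped:
        logger.info(
            "listwise deletion: read %d rows, dropped %d, retained %d",
            len(sub), n_dropped, len(retained),
        )
    return ItemResponseMatrix(retained, tuple(item_ids), n_dropped=n_dropped)


def _round_half_away(value: Decimal, digits: int = 2) -> float:
    q = Decimal(1).scaleb(-digits)
    sign = -1 if value < 0 else 1
    return float(sign * abs(value).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SampleSummary:
    """Descriptive counts/percentages of the retained sample."""

    table: pd.DataFrame  # columns: variable, category, count, percent
    n: int

    def percent_of(self, variable: str, category: str) -> float:
        t = self.table
        row = t[(t.variable == variable) & (t.category == category)]
        if row.empty:
            raise KeyError((variable, category))
        return float(row.percent.iloc[0])


def summarize_sample(
    counts: Iterable[tuple[str, str, int]], n: int
) -> SampleSummary:
    """Tabulate (variable, category, count) rows as percentages of ``n``.

    Percentages are ``100 * count / n`` rounded half-away-from-zero to two
    decimals, matching the precision conventionally printed in descriptive
    sample tables.
    """
    if n <= 0:
        raise ValidationError("n must be positive")
    rows = []
    totals: dict[str, int] = {}
    for variable, category, count in counts:
        count = int(count)
        if count < 0:
            raise ValidationError(f"negative count for {variable}/{category}")
        totals[variable] = totals.get(variable, 0) + count
        if totals[variable] > n:
            raise ValidationError(
                f"counts for variable {variable!r} exceed n={n}"
            )
        pct = _round_half_away(Decimal(100 * count) / Decimal(n))
        rows.append((variable, category, count, pct))
    table = pd.DataFrame(rows, columns=["variable", "category", "count", "percent"])
    return SampleSummary(table, n)


def write_ingestion_log(matrix: ItemResponseMatrix, path: str | Path) -> None:
    Path(path).write_text(json.dumps(matrix.ingestion_log(), indent=2))
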