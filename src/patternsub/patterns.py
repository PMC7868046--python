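"""Missing-data pattern bookkeeping.

Indicator convention
--------------------
Throughout this package ``M[i, j] == 1`` means predictor ``j`` is
**missing** for record ``i`` and ``0`` means it is observed.  This is the
pattern-mixture-model convention and is the *reverse* of the
"1 = observed" convention used by some other software.  Pattern keys,
submodel dispatch and every report rely on it.

A *pattern key* is the tuple of indicator bits for one record, in the
fixed column order of the data table.  The fully observed pattern is the
all-zero key, which sorts first under the lexicographic ordering used
for all pattern tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence, Tuple

import numpy as np

PatternKey = Tuple[int, ...]

__all__ = [
    "DataTable",
    "PatternKey",
    "PatternInfo",
    "PatternTable",
    "compute_indicator_matrix",
    "enumerate_patterns",
    "assign_pattern",
    "key_to_string",
    "string_to_key",
]


@dataclass
class DataTable:
    """A response vector plus a predictor matrix with missing cells.

    Parameters
    ----------
    y : array of shape (n,)
        Observed responses.  Responses must be fully observed; a NaN here
        is an error (the methods in this package predict Y from partially
        observed X, they do not handle missing Y).
    X : array of shape (n, p)
        Predictors with ``numpy.nan`` marking missing cells.
    columns : sequence of str, optional
        Predictor names; defaults to ``x1..xp``.  Column order is fixed
        and determines pattern-key bit order.
    """

    y: np.ndarray
    X: np.ndarray
    columns: Sequence[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-d array")
        n, p = self.X.shape
        if n < 1 or p < 1:
            raise ValueError("need n >= 1 records and p >= 1 predictors")
        if self.y.shape[0] != n:
            raise ValueError(f"response length {self.y.shape[0]} != n rows {n}")
        if np.isnan(self.y).any():
            raise ValueError(
                "response contains missing values; all responses must be observed"
            )
        if self.columns is None:
            self.columns = [f"x{j + 1}" for j in range(p)]
        else:
            self.columns = list(self.columns)
            if len(self.columns) != p:
                raise ValueError("number of column names != number of predictors")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class PatternInfo:
    """One observed missingness pattern: its key, count and member rows."""

    key: PatternKey
    count: int
    rows: np.ndarray  # sorted row indices into the source table


@dataclass
class PatternTable:
    """Deterministically ordered table of the observed patterns.

    Patterns are sorted lexicographically by key, so the fully observed
    pattern (all zeros), when present, comes first.  Row-index sets
    partition ``0..n-1``.
    """

    patterns: list[PatternInfo]
    n: int

    def __iter__(self) -> Iterator[PatternInfo]:
        return iter(self.patterns)

    def __len__(self) -> int:
        return len(self.patterns)

    def keys(self) -> list[PatternKey]:
        return [info.key for info in self.patterns]

    def counts(self) -> dict[PatternKey, int]:
        return {info.key: info.count for info in self.patterns}

    def rows(self, key: PatternKey) -> np.ndarray:
        for info in self.patterns:
            if info.key == tuple(key):
                return info.rows
        raise KeyError(f"pattern {key!r} not observed")


def compute_indicator_matrix(data: DataTable) -> np.ndarray:
    """Return the n x p indicator matrix M with 1 marking missing cells."""
    if np.isnan(data.y).any():  # defensive: DataTable already rejects this
        raise ValueError("response contains missing values")
    return np.isnan(data.X).astype(np.int8)


def assign_pattern(record: Sequence[float] | np.ndarray, p: int | None = None) -> PatternKey:
    """Pattern key of one predictor row (bit j = 1 iff cell j is missing)."""
    arr = np.asarray(record, dtype=float).ravel()
    if p is not None and arr.shape[0] != p:
        raise ValueError(f"record has {arr.shape[0]} cells, expected {p}")
    return tuple(int(b) for b in np.isnan(arr))


def enumerate_patterns(M: np.ndarray) -> PatternTable:
    """Group rows of an indicator matrix into distinct patterns.

    Returns one entry per distinct row of ``M`` with the member row
    indices, in lexicographic key order.
    """
    M = np.asarray(M)
    if M.ndim != 2:
        raise ValueError("M must be 2-d")
    groups: dict[PatternKey, list[int]] = {}
    for i, row in enumerate(M):
        groups.setdefault(tuple(int(b) for b in row), []).append(i)
    infos = [
        PatternInfo(key=key, count=len(rows), rows=np.asarray(rows, dtype=np.intp))
        for key, rows in sorted(groups.items())
    ]
    return PatternTable(patterns=infos, n=M.shape[0])


def key_to_string(key: PatternKey) -> str:
    return "".join(str(int(b)) for b in key)


def string_to_key(s: str) -> PatternKey:
    return tuple(int(c) for c in s)
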