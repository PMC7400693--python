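"""Clonotype abundance vectors — the unit of all diversity/overlap math."""

from __future__ import annotations

from collections import Counter
from collections.abc import Mapping
from typing import Iterable

import numpy as np


class CountVector(Mapping):
    """An immutable map clonotype key -> positive integer cell count.

    Every diversity, overlap and clonal-architecture statistic consumes one
    of these. Invariants enforced at construction: all counts are positive
    integers and ``total`` equals their sum.
    """

    __slots__ = ("_counts", "_total")

    def __init__(self, counts: Mapping[str, int]):
        clean = {}
        for key, n in counts.items():
            n = int(n)
            if n <= 0:
                raise ValueError(
                    f"count for {key!r} must be a positive integer, got {n}")
            clean[str(key)] = n
        self._counts = clean
        self._total = sum(clean.values())

    @classmethod
    def from_keys(cls, keys: Iterable[str]) -> "CountVector":
        """Tally an iterable of clonotype keys (one entry per cell)."""
        return cls(Counter(str(k) for k in keys))

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, key):
        return self._counts[key]

    def __iter__(self):
        return iter(self._counts)

    def __len__(self):
        return len(self._counts)

    def __repr__(self):
        return f"CountVector({len(self)} clonotypes, {self.total} cells)"

    def __eq__(self, other):
        if isinstance(other, CountVector):
            return self._counts == other._counts
        return self._counts == dict(other)

    def __hash__(self):
        return hash(frozenset(self._counts.items()))

    # Derived quantities ---------------------------------------------------
    @property
    def total(self) -> int:
        """Number of cells (sum of counts)."""
        return self._total

    @property
    def richness(self) -> int:
        """Number of distinct clonotypes."""
        return len(self._counts)

    def values_array(self) -> np.ndarray:
        return np.asarray(list(self._counts.values()), dtype=np.int64)

    def proportions(self) -> np.ndarray:
        """Relative clone sizes (sum to 1)."""
        v = self.values_array()
        return v / v.sum()
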