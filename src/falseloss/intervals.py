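"""Interval algebra on genome coordinates.

All coordinates are 0-based half-open, the BED convention.  An
:class:`IntervalSet` stores, per sequence, a sorted and disjoint
``(n, 2)`` integer array of ``[start, end)`` rows; every operation
returns sets in the same canonical form, so results are directly
comparable and writable as BED.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, Mapping, Tuple

import numpy as np

__all__ = ["GenomicInterval", "IntervalSet"]


@dataclass(frozen=True)
class GenomicInterval:
    """A single 0-based half-open interval on a named sequence."""

    sequence: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.sequence}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


def _canonical(arr: np.ndarray) -> np.ndarray:
    """Sort and fuse touching/overlapping rows into disjoint form."""
    if len(arr) == 0:
        return np.empty((0, 2), dtype=np.int64)
    arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = [arr[0].copy()]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append(np.array([s, e], dtype=np.int64))
    return np.vstack(out)


class IntervalSet:
    """Per-sequence collection of sorted, disjoint half-open intervals."""

    def __init__(self, data: Mapping[str, np.ndarray] | None = None):
        self._data: Dict[str, np.ndarray] = {}
        if data:
            for name, arr in data.items():
                arr = _canonical(np.asarray(arr))
                if len(arr):
                    if arr[0, 0] < 0:
                        raise ValueError(f"negative coordinate on {name}")
                    self._data[name] = arr

    # ------------------------------------------------------------------
    # construction helpers
    # ------------------------------------------------------------------
    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval | Tuple[str, int, int]]) -> "IntervalSet":
        acc: Dict[str, list] = {}
        for iv in intervals:
            if isinstance(iv, GenomicInterval):
                name, s, e = iv.sequence, iv.start, iv.end
            else:
                name, s, e = iv
            acc.setdefault(name, []).append((s, e))
        return cls({k: np.array(v) for k, v in acc.items()})

    @classmethod
    def whole(cls, lengths: Mapping[str, int]) -> "IntervalSet":
        return cls({k: np.array([[0, v]]) for k, v in lengths.items() if v > 0})

    @classmethod
    def read_bed(cls, path: str | Path) -> "IntervalSet":
        acc: Dict[str, list] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                acc.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
        return cls({k: np.array(v) for k, v in acc.items()})

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name in sorted(self._data):
                for s, e in self._data[name]:
                    fh.write(f"{name}\t{s}\t{e}\n")

    # ------------------------------------------------------------------
    # basics
    # ------------------------------------------------------------------
    @property
    def sequences(self) -> Tuple[str, ...]:
        return tuple(sorted(self._data))

    def array(self, sequence: str) -> np.ndarray:
        return self._data.get(sequence, np.empty((0, 2), dtype=np.int64))

    def __iter__(self) -> Iterator[GenomicInterval]:
        for name in sorted(self._data):
            for s, e in self._data[name]:
                yield GenomicInterval(name, int(s), int(e))

    def __len__(self) -> int:
        return sum(len(a) for a in self._data.values())

    def __bool__(self) -> bool:
        return len(self) > 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if set(self._data) != set(other._data):
            return False
        return all(np.array_equal(self._data[k], other._data[k]) for k in self._data)

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals on {len(self._data)} sequences, {self.total_length} bp)"

    @property
    def total_length(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self._data.values()))

    def length_on(self, sequence: str) -> int:
        a = self.array(sequence)
        return int((a[:, 1] - a[:, 0]).sum()) if len(a) else 0

    # ------------------------------------------------------------------
    # set algebra
    # ------------------------------------------------------------------
    def merge(self, max_gap: int = 0) -> "IntervalSet":
        """Fuse intervals separated by at most ``max_gap`` bases.

        ``max_gap=0`` fuses only touching/overlapping intervals; with the
        25-kbp default used for false-duplication masking, intervals up to
        25 kbp apart become one.
        """
        if max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        out = {}
        for name, arr in self._data.items():
            padded = arr.copy()
            padded[:, 1] += max_gap
            fused = _canonical(padded)
            fused[:, 1] -= max_gap
            out[name] = fused
        return IntervalSet(out)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        out = {}
        for name in set(self._data) | set(other._data):
            out[name] = np.vstack([self.array(name), other.array(name)])
        return IntervalSet(out)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out: Dict[str, np.ndarray] = {}
        for name in set(self._data) & set(other._data):
            a, b = self._data[name], other._data[name]
            rows = []
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i, 0], b[j, 0])
                e = min(a[i, 1], b[j, 1])
                if s < e:
                    rows.append((s, e))
                if a[i, 1] < b[j, 1]:
                    i += 1
                else:
                    j += 1
            if rows:
                out[name] = np.array(rows)
        return IntervalSet(out)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Bases of ``self`` not covered by ``other``."""
        out: Dict[str, np.ndarray] = {}
        for name, a in self._data.items():
            b = other.array(name)
            if len(b) == 0:
                out[name] = a
                continue
            rows = []
            j = 0
            for s, e in a:
                cur = s
                while j < len(b) and b[j, 1] <= cur:
                    j += 1
                k = j
                while k < len(b) and b[k, 0] < e:
                    if b[k, 0] > cur:
                        rows.append((cur, b[k, 0]))
                    cur = max(cur, b[k, 1])
                    k += 1
                if cur < e:
                    rows.append((cur, e))
            if rows:
                out[name] = np.array(rows)
        return IntervalSet(out)

    def complement(self, lengths: Mapping[str, int]) -> "IntervalSet":
        missing = set(self._data) - set(lengths)
        if missing:
            raise ValueError(f"sequence {sorted(missing)[0]!r} absent from length table")
        for name, arr in self._data.items():
            if len(arr) and arr[-1, 1] > lengths[name]:
                raise ValueError(f"interval beyond end of {name}")
        return IntervalSet.whole(lengths).subtract(self)

    # ------------------------------------------------------------------
    # queries
    # ------------------------------------------------------------------
    def coverage_fraction(self, target: GenomicInterval) -> float:
        """|target ∩ self| / |target| for a single interval."""
        if len(target) == 0:
            raise ValueError("zero-length target interval")
        return self.overlap_length(target) / len(target)

    def overlap_length(self, target: GenomicInterval) -> int:
        a = self.array(target.sequence)
        if len(a) == 0:
            return 0
        lo = np.searchsorted(a[:, 1], target.start, side="right")
        hi = np.searchsorted(a[:, 0], target.end, side="left")
        if lo >= hi:
            return 0
        sub = a[lo:hi]
        return int(np.sum(np.minimum(sub[:, 1], target.end) - np.maximum(sub[:, 0], target.start)))

    def contains_point(self, sequence: str, pos: int) -> bool:
        a = self.array(sequence)
        if len(a) == 0:
            return False
        i = np.searchsorted(a[:, 0], pos, side="right") - 1
        return i >= 0 and pos < a[i, 1]

    def mask(self, sequence: str, length: int) -> np.ndarray:
        """Boolean per-base membership array for one sequence."""
        m = np.zeros(length, dtype=bool)
        for s, e in self.array(sequence):
            m[s:e] = True
        return m

    @classmethod
    def from_mask(cls, sequence: str, m: np.ndarray) -> "IntervalSet":
        m = np.asarray(m, dtype=bool)
        if not m.any():
            return cls()
        d = np.diff(m.astype(np.int8))
        starts = list(np.where(d == 1)[0] + 1)
        ends = list(np.where(d == -1)[0] + 1)
        if m[0]:
            starts.insert(0, 0)
        if m[-1]:
            ends.append(len(m))
        return cls({sequence: np.column_stack([starts, ends])})
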