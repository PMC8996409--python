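"""Genome layout and interval-set algebra.

All coordinates are 0-based, half-open (BED convention). An
:class:`IntervalSet` is the universal currency of the package: a
per-chromosome, sorted collection of non-overlapping, non-adjacent segments
on a fixed :class:`GenomeLayout`. LADs, i-LADs, change categories, peaks and
sub-domains are all IntervalSets, and every downstream quantity (coverage in
mb, overlap bp, O/E ratios) is defined through the base-exact set operations
implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "Interval",
    "IntervalSet",
    "merge",
    "set_op",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
]


class BedParseError(ValueError):
    """Raised when a BED/bedGraph line cannot be interpreted."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths (bp).

    The layout is user-supplied (e.g. a subset of hg38 chromosomes, or a
    synthetic genome); all intervals elsewhere must lie within
    ``[0, length)`` of a declared chromosome.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        if any(length <= 0 for length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        object.__setattr__(
            self, "_index", dict(zip(self.chrom_names, self.chrom_lengths))
        )

    @classmethod
    def from_dict(cls, sizes: Mapping[str, int]) -> "GenomeLayout":
        return cls(tuple(sizes.keys()), tuple(int(v) for v in sizes.values()))

    def length(self, chrom: str) -> int:
        try:
            return self._index[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome layout") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._index

    @property
    def total_bp(self) -> int:
        return int(sum(self.chrom_lengths))


class Interval(NamedTuple):
    """A single genomic segment, 0-based half-open."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _validate_interval(chrom: str, start: int, end: int, layout: GenomeLayout) -> None:
    if chrom not in layout:
        raise KeyError(f"chromosome {chrom!r} not in genome layout")
    if not (0 <= start < end <= layout.length(chrom)):
        raise ValueError(
            f"invalid interval {chrom}:{start}-{end} "
            f"(chromosome length {layout.length(chrom)})"
        )


def _merge_pairs(pairs: np.ndarray, gap_bp: int = 0) -> np.ndarray:
    """Sort (n, 2) start/end pairs and fuse overlapping or book-ended runs.

    Two segments merge when ``next.start <= prev.end + gap_bp``.
    """
    if pairs.size == 0:
        return pairs.reshape(0, 2)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    pairs = pairs[order]
    out_s: list[int] = [int(pairs[0, 0])]
    out_e: list[int] = [int(pairs[0, 1])]
    for s, e in pairs[1:]:
        if s <= out_e[-1] + gap_bp:
            if e > out_e[-1]:
                out_e[-1] = int(e)
        else:
            out_s.append(int(s))
            out_e.append(int(e))
    return np.column_stack([out_s, out_e]).astype(np.int64)


class IntervalSet:
    """Normalized set of genomic segments on a :class:`GenomeLayout`.

    Invariants: per chromosome, segments are sorted by start, pairwise
    disjoint, and never book-ended (``prev.end < next.start``). Construction
    through any public path normalizes input segments.
    """

    __slots__ = ("layout", "_segs")

    def __init__(
        self,
        layout: GenomeLayout,
        segments: Mapping[str, np.ndarray] | None = None,
        *,
        _normalized: bool = False,
    ) -> None:
        self.layout = layout
        segs: dict[str, np.ndarray] = {}
        if segments:
            for chrom, arr in segments.items():
                arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
                if arr.size == 0:
                    continue
                if not _normalized:
                    for s, e in arr:
                        _validate_interval(chrom, int(s), int(e), layout)
                    arr = _merge_pairs(arr)
                segs[chrom] = arr
        self._segs = segs

    # ------------------------------------------------------------------ #
    # construction

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[tuple[str, int, int] | Interval], layout: GenomeLayout
    ) -> "IntervalSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        return cls(layout, {c: np.array(v) for c, v in by_chrom.items()})

    @classmethod
    def empty(cls, layout: GenomeLayout) -> "IntervalSet":
        return cls(layout)

    @classmethod
    def whole_genome(cls, layout: GenomeLayout) -> "IntervalSet":
        segs = {
            c: np.array([[0, layout.length(c)]], dtype=np.int64)
            for c in layout.chrom_names
        }
        return cls(layout, segs, _normalized=True)

    # ------------------------------------------------------------------ #
    # introspection

    def segments_on(self, chrom: str) -> np.ndarray:
        """(n, 2) int64 array of start/end pairs on one chromosome."""
        return self._segs.get(chrom, np.empty((0, 2), dtype=np.int64))

    def __iter__(self) -> Iterator[Interval]:
        for chrom in self.layout.chrom_names:
            for s, e in self.segments_on(chrom):
                yield Interval(chrom, int(s), int(e))

    @property
    def total_bp(self) -> int:
        return int(
            sum((arr[:, 1] - arr[:, 0]).sum() for arr in self._segs.values())
        )

    @property
    def total_mb(self) -> float:
        return self.total_bp / 1e6

    @property
    def n_segments(self) -> int:
        return int(sum(len(arr) for arr in self._segs.values()))

    def segment_lengths(self) -> np.ndarray:
        if not self._segs:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(
            [arr[:, 1] - arr[:, 0] for arr in self._segs.values()]
        )

    def __bool__(self) -> bool:
        return bool(self._segs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if self.layout != other.layout:
            return False
        chroms = set(self._segs) | set(other._segs)
        return all(
            np.array_equal(self.segments_on(c), other.segments_on(c)) for c in chroms
        )

    def __repr__(self) -> str:
        return (
            f"IntervalSet({self.n_segments} segments, {self.total_bp} bp "
            f"on {len(self.layout.chrom_names)} chromosomes)"
        )

    # ------------------------------------------------------------------ #
    # set algebra (base-exact)

    def _check_layout(self, other: "IntervalSet") -> None:
        if self.layout != other.layout:
            raise ValueError("interval sets are on different genome layouts")

    def union(self, other: "IntervalSet") -> "IntervalSet":
        self._check_layout(other)
        segs: dict[str, np.ndarray] = {}
        for chrom in set(self._segs) | set(other._segs):
            merged = _merge_pairs(
                np.concatenate([self.segments_on(chrom), other.segments_on(chrom)])
            )
            segs[chrom] = merged
        return IntervalSet(self.layout, segs, _normalized=True)

    def complement(self) -> "IntervalSet":
        """Bases of the genome not covered by this set (e.g. i-LADs)."""
        segs: dict[str, np.ndarray] = {}
        for chrom in self.layout.chrom_names:
            length = self.layout.length(chrom)
            arr = self.segments_on(chrom)
            if arr.size == 0:
                segs[chrom] = np.array([[0, length]], dtype=np.int64)
                continue
            bounds = np.concatenate([[0], arr.ravel(), [length]])
            pairs = bounds.reshape(-1, 2)
            keep = pairs[:, 0] < pairs[:, 1]
            if keep.any():
                segs[chrom] = pairs[keep].astype(np.int64)
        return IntervalSet(self.layout, segs, _normalized=True)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        self._check_layout(other)
        segs: dict[str, np.ndarray] = {}
        for chrom in set(self._segs) & set(other._segs):
            a = self.segments_on(chrom)
            b = other.segments_on(chrom)
            # sweep both sorted lists
            out: list[tuple[int, int]] = []
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i, 0], b[j, 0])
                e = min(a[i, 1], b[j, 1])
                if s < e:
                    out.append((int(s), int(e)))
                if a[i, 1] <= b[j, 1]:
                    i += 1
                else:
                    j += 1
            if out:
                segs[chrom] = np.array(out, dtype=np.int64)
        return IntervalSet(self.layout, segs, _normalized=True)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        self._check_layout(other)
        return self.intersect(other.complement())

    def overlap_bp(self, other: "IntervalSet") -> int:
        """Total bp of the base-exact intersection (symmetric)."""
        return self.intersect(other).total_bp

    def contains_point(self, chrom: str, pos: int) -> bool:
        arr = self.segments_on(chrom)
        if arr.size == 0:
            return False
        idx = int(np.searchsorted(arr[:, 0], pos, side="right")) - 1
        return idx >= 0 and pos < arr[idx, 1]

    def overlaps_interval(self, chrom: str, start: int, end: int) -> bool:
        """True iff any segment overlaps [start, end) by >= 1 bp."""
        arr = self.segments_on(chrom)
        if arr.size == 0:
            return False
        idx = int(np.searchsorted(arr[:, 0], end, side="left"))
        return idx > 0 and arr[idx - 1, 1] > start

    # ------------------------------------------------------------------ #
    # I/O

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(i.chrom, i.start, i.end) for i in self]
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def write_bed(self, path: str | Path, name: str | None = None) -> None:
        write_bed(self, path, name=name)


def merge(
    intervals: Iterable[tuple[str, int, int] | Interval],
    layout: GenomeLayout,
    gap_bp: int = 0,
) -> IntervalSet:
    """Normalize raw intervals into an :class:`IntervalSet`.

    ``gap_bp`` > 0 additionally fuses segments separated by at most that
    many bases (default 0: only overlapping/book-ended segments fuse).
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        _validate_interval(chrom, int(start), int(end), layout)
        by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    segs = {
        c: _merge_pairs(np.array(v, dtype=np.int64), gap_bp=gap_bp)
        for c, v in by_chrom.items()
    }
    return IntervalSet(layout, segs, _normalized=True)


_SET_OPS = {
    "union": IntervalSet.union,
    "intersect": IntervalSet.intersect,
    "subtract": IntervalSet.subtract,
}


def set_op(a: IntervalSet, b: IntervalSet, op: str) -> IntervalSet:
    """Dispatch union/intersect/subtract by name."""
    try:
        fn = _SET_OPS[op]
    except KeyError:
        raise ValueError(
            f"unknown set operation {op!r}; expected one of {sorted(_SET_OPS)}"
        ) from None
    return fn(a, b)


def read_bed(path: str | Path, layout: GenomeLayout) -> IntervalSet:
    """Read a BED3+ file into a normalized IntervalSet.

    Extra columns are ignored; ``track``/``browser``/``#`` lines are
    skipped. Records on undeclared chromosomes or with invalid coordinates
    raise with the offending line number.
    """
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated BED
                fields = line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            if chrom not in layout:
                raise BedParseError(
                    f"{path}:{lineno}: chromosome {chrom!r} not in genome layout"
                )
            if not (0 <= start < end <= layout.length(chrom)):
                raise BedParseError(
                    f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}"
                )
            intervals.append((chrom, start, end))
    return IntervalSet.from_intervals(intervals, layout)


def write_bed(iset: IntervalSet, path: str | Path, name: str | None = None) -> None:
    """Write BED3 (or BED4 when ``name`` is given) with a trailing newline."""
    with open(path, "w") as fh:
        for iv in iset:
            if name is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Read a two-column chrom-sizes TSV into a GenomeLayout."""
    names: list[str] = []
    lengths: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 2 columns")
            names.append(fields[0])
            lengths.append(int(fields[1]))
    return GenomeLayout(tuple(names), tuple(lengths))


def write_chrom_sizes(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in zip(layout.chrom_names, layout.chrom_lengths):
            fh.write(f"{name}\t{length}\n")
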