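"""Genomic interval algebra and BED I/O.

Intervals are 0-based half-open throughout, matching BED's native
convention. A :class:`RegionSet` is always normalized: sorted by
(contig, start) and pairwise non-overlapping.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from typing import Iterable, Iterator, NamedTuple, Optional, TextIO

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "BedFormatError",
    "read_bed",
    "write_bed",
    "merge",
    "restrict",
    "genes_to_regions",
]


class BedFormatError(ValueError):
    def __init__(self, message: str, line_number: Optional[int] = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class GenomicInterval(NamedTuple):
    """contig + [start, end) span; start >= 0, end > start."""

    contig: str
    start: int
    end: int

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def __len__(self) -> int:  # number of bases
        return self.end - self.start


def _check(iv: GenomicInterval, line_number: Optional[int] = None) -> GenomicInterval:
    if iv.start < 0:
        raise BedFormatError(f"negative start in {iv}", line_number)
    if iv.end <= iv.start:
        raise BedFormatError(f"end <= start in {iv}", line_number)
    return iv


class RegionSet:
    """Sorted, non-overlapping collection of :class:`GenomicInterval`.

    Construction normalizes via :func:`merge` (gap 0, abutting intervals
    joined), so the union of bases is preserved but the representation is
    minimal and deterministic.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), gap: int = 0):
        self.intervals: list[GenomicInterval] = _merge_sorted(
            sorted(_check(iv) for iv in intervals), gap
        )
        # per-contig start/end arrays for bisect lookups
        self._by_contig: dict[str, tuple[list[int], list[int]]] = {}
        for iv in self.intervals:
            starts, ends = self._by_contig.setdefault(iv.contig, ([], []))
            starts.append(iv.start)
            ends.append(iv.end)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __eq__(self, other) -> bool:
        return isinstance(other, RegionSet) and self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"RegionSet({self.intervals!r})"

    def total_bases(self) -> int:
        return sum(iv.end - iv.start for iv in self.intervals)

    def contains_point(self, contig: str, pos: int) -> bool:
        """Is 0-based position ``pos`` inside the region union?"""
        entry = self._by_contig.get(contig)
        if entry is None:
            return False
        starts, ends = entry
        i = bisect_right(starts, pos) - 1
        return i >= 0 and pos < ends[i]

    def overlaps_interval(self, iv: GenomicInterval) -> bool:
        """Does ``iv`` share at least one base with the region union?"""
        entry = self._by_contig.get(iv.contig)
        if entry is None:
            return False
        starts, ends = entry
        i = bisect_right(starts, iv.end - 1) - 1
        return i >= 0 and iv.start < ends[i]


def _merge_sorted(ivs: list[GenomicInterval], gap: int) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and iv.contig == out[-1].contig and iv.start - out[-1].end <= gap:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.contig, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def merge(intervals: Iterable[GenomicInterval], gap: int = 0) -> RegionSet:
    """Minimal normalized set whose union equals the input union.

    Intervals on the same contig separated by at most ``gap`` bases are
    joined; ``gap=0`` joins overlapping and abutting intervals. Idempotent
    and order-insensitive.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    return RegionSet(intervals, gap=gap)


def restrict(
    intervals: Iterable[GenomicInterval], regions: RegionSet
) -> list[GenomicInterval]:
    """Keep exactly the intervals sharing >=1 base with the region union."""
    return [iv for iv in intervals if regions.overlaps_interval(iv)]


def read_bed(stream: TextIO) -> RegionSet:
    """Read a BED (>=3 columns) into a normalized RegionSet.

    ``track``/``browser``/``#`` lines are skipped; extra columns ignored.
    """
    return RegionSet(iv for iv, _name in _iter_bed(stream))


def _iter_bed(stream: TextIO) -> Iterator[tuple[GenomicInterval, Optional[str]]]:
    for n, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(("track", "browser", "#")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise BedFormatError("expected >=3 tab-separated columns", n)
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise BedFormatError(f"non-integer coordinates in {line!r}", n)
        iv = _check(GenomicInterval(fields[0], start, end), n)
        yield iv, (fields[3] if len(fields) > 3 else None)


def write_bed(regions: Iterable[GenomicInterval], stream: TextIO) -> int:
    """Write 3-column BED; coordinates emitted exactly as stored."""
    n = 0
    for iv in regions:
        stream.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")
        n += 1
    return n


def genes_to_regions(
    gene_names: Iterable[str], annotation: TextIO
) -> tuple[RegionSet, list[str]]:
    """Resolve gene symbols to regions via a user-supplied annotation BED.

    The annotation's 4th column is the gene symbol; matching is
    case-insensitive exact. Returns the union of matching intervals plus
    the list of names with no match (also emitted as a UserWarning).
    """
    wanted: dict[str, str] = {}
    for name in gene_names:
        wanted.setdefault(name.upper(), name)
    hits: list[GenomicInterval] = []
    seen: set[str] = set()
    for iv, name in _iter_bed(annotation):
        if name is not None and name.upper() in wanted:
            hits.append(iv)
            seen.add(name.upper())
    missing = [orig for key, orig in wanted.items() if key not in seen]
    if missing:
        warnings.warn(
            f"no annotation rows matched gene name(s): {', '.join(sorted(missing))}",
            UserWarning,
            stacklevel=2,
        )
    return RegionSet(hits), missing
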