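"""Computational-subtraction microbe screen.

Reads are first aligned to the host (human) reference; reads that fail
to map are aligned to a database of microbial genomes. This module
consumes the two alignment passes and produces:

* the host / microbial / unknown read-class partition (a read is human
  if its primary host-pass record is mapped; microbial if non-host and
  primary-mapped to at least one database genome; unknown otherwise);
* per-genome evidence: read count, genome length, and breadth of
  coverage — the number of bases covered by at least one aligned read,
  computed from M/=/X aligned segments only (deleted/skipped bases
  inside an alignment are not covered);
* the ranked top-N report with a log10 read-count column.

Mates of a pair are classified independently: each (read, segment) is
its own unit.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, TextIO, Union

from .regions import GenomicInterval, merge
from .sam import AlignmentRecord

__all__ = [
    "GenomeHit",
    "ScreenSummary",
    "subtract_host",
    "summarize_hits",
    "classify_reads",
    "top_hits",
    "read_length_table",
]

ReadKey = tuple[str, int]  # (query_name, segment)


@dataclass
class GenomeHit:
    """Per-genome screen statistics."""

    genome_id: str
    genome_length: int
    read_count: int
    covered_bases: int

    @property
    def breadth_fraction(self) -> float:
        return self.covered_bases / self.genome_length

    def __post_init__(self):
        if self.covered_bases > self.genome_length:
            raise ValueError(
                f"covered_bases {self.covered_bases} exceeds genome length "
                f"{self.genome_length} for {self.genome_id}"
            )
        if self.read_count == 0 and self.covered_bases != 0:
            raise ValueError("zero reads cannot cover bases")


@dataclass
class ScreenSummary:
    n_total: int
    n_human: int
    n_microbial: int
    n_unknown: int
    hits: list[GenomeHit] = field(default_factory=list)

    def __post_init__(self):
        if self.n_human + self.n_microbial + self.n_unknown != self.n_total:
            raise ValueError("read-class partition does not sum to the total")

    @property
    def proportions(self) -> dict[str, float]:
        if self.n_total == 0:
            return {"human": 0.0, "microbial": 0.0, "unknown": 0.0}
        return {
            "human": self.n_human / self.n_total,
            "microbial": self.n_microbial / self.n_total,
            "unknown": self.n_unknown / self.n_total,
        }


def subtract_host(
    records: Iterable[AlignmentRecord],
) -> tuple[set[ReadKey], set[ReadKey]]:
    """Partition the host-pass reads into (host, non-host) key sets.

    Only primary records carry the verdict; a (read, segment) is host iff
    its primary record is mapped to the host reference.
    """
    host: set[ReadKey] = set()
    nonhost: set[ReadKey] = set()
    for rec in records:
        if not rec.is_primary:
            continue
        key = (rec.query_name, rec.segment)
        (nonhost if rec.is_unmapped else host).add(key)
    return host, nonhost


def aligned_segments(rec: AlignmentRecord) -> list[GenomicInterval]:
    """Reference intervals actually covered by read bases (M/=/X runs)."""
    if rec.is_unmapped or rec.pos is None or rec.cigar is None:
        return []
    out: list[GenomicInterval] = []
    cursor = rec.pos
    for length, op in rec.cigar:
        if op in "M=X":
            out.append(GenomicInterval(rec.contig, cursor, cursor + length))
            cursor += length
        elif op in "DN":
            cursor += length
    return out


def summarize_hits(
    records: Iterable[AlignmentRecord],
    genome_lengths: Mapping[str, int],
    count_secondary: bool = False,
) -> list[GenomeHit]:
    """Per-genome read counts and breadth from the microbe-pass alignments.

    read_count is the number of distinct (read, segment) whose *primary*
    alignment maps to the genome; with ``count_secondary`` every genome a
    read aligns to is credited instead. Breadth always uses primary
    alignments only. Genomes with zero reads are omitted; an alignment to
    a contig absent from the length table is an error naming the contig.
    """
    reads_per_genome: dict[str, set[ReadKey]] = {}
    segs_per_genome: dict[str, list[GenomicInterval]] = {}
    for rec in records:
        if rec.is_unmapped or rec.contig is None:
            continue
        if rec.contig not in genome_lengths:
            raise KeyError(
                f"genome {rec.contig!r} missing from the length table"
            )
        if rec.is_primary or count_secondary:
            reads_per_genome.setdefault(rec.contig, set()).add(
                (rec.query_name, rec.segment)
            )
        if rec.is_primary:
            segs_per_genome.setdefault(rec.contig, []).extend(aligned_segments(rec))
    hits = []
    for genome, keys in sorted(reads_per_genome.items()):
        covered = merge(segs_per_genome.get(genome, [])).total_bases()
        hits.append(
            GenomeHit(
                genome_id=genome,
                genome_length=genome_lengths[genome],
                read_count=len(keys),
                covered_bases=covered,
            )
        )
    return hits


def classify_reads(
    host: set[ReadKey],
    nonhost: set[ReadKey],
    microbe_records: Iterable[AlignmentRecord],
    genome_lengths: Mapping[str, int],
    count_secondary: bool = False,
) -> ScreenSummary:
    """Build the full screen summary from both alignment passes.

    The host/microbial/unknown partition is exact over the read universe
    host ∪ nonhost; a read claimed by both passes as host and microbial
    indicates inconsistent inputs and raises ``ValueError``.
    """
    microbe_records = list(microbe_records)
    hits = summarize_hits(microbe_records, genome_lengths, count_secondary)
    microbial_keys = {
        (rec.query_name, rec.segment)
        for rec in microbe_records
        if rec.is_primary and not rec.is_unmapped
    }
    clash = microbial_keys & host
    if clash:
        name = sorted(clash)[0]
        raise ValueError(
            f"read {name[0]!r} is claimed by both the host and microbial sets"
        )
    n_total = len(host) + len(nonhost)
    n_microbial = len(microbial_keys & nonhost)
    n_unknown = len(nonhost) - n_microbial
    return ScreenSummary(
        n_total=n_total,
        n_human=len(host),
        n_microbial=n_microbial,
        n_unknown=n_unknown,
        hits=rank_hits(hits),
    )


def rank_hits(hits: Iterable[GenomeHit]) -> list[GenomeHit]:
    """Read-count descending, genome_id ascending on ties."""
    return sorted(hits, key=lambda h: (-h.read_count, h.genome_id))


def top_hits(hits: Iterable[GenomeHit], n: int = 20) -> list[GenomeHit]:
    """First ``n`` genomes by read count (ties by genome_id)."""
    return rank_hits(hits)[:n]


def log10_reads(hit: GenomeHit) -> float:
    """log10 read count for the ranked-hits plot column."""
    return math.log10(hit.read_count)


def read_length_table(path_or_stream: Union[str, os.PathLike, TextIO]) -> dict[str, int]:
    """Load a genome length table: 2-column TSV or a .fai index (the
    first two columns are the same in both dialects)."""
    if hasattr(path_or_stream, "read"):
        lines = path_or_stream.read().splitlines()
    else:
        with open(path_or_stream) as fh:
            lines = fh.read().splitlines()
    table: dict[str, int] = {}
    for n, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"length table line {n}: expected >=2 columns")
        try:
            table[fields[0]] = int(fields[1])
        except ValueError:
            raise ValueError(f"length table line {n}: non-integer length")
    return table
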