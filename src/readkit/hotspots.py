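"""Indel hotspot extraction: the intensive-mode targeting step.

A single CIGAR walk over all mapped reads collects every reference locus
where an insertion or deletion is evidenced by at least ``min_reads``
reads. The loci are padded and merged into a small BED target set so a
slow, assembly-based indel caller can be pointed at just those windows
instead of the whole genome.

Coordinate conventions:

* a deletion of length L starting at reference cursor c contributes the
  full span [c, c+L);
* an insertion (which lives between two reference bases) is anchored to
  the single reference base immediately after the insertion point,
  [c, c+1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .regions import GenomicInterval, RegionSet, merge
from .sam import AlignmentRecord

__all__ = ["HotspotConfig", "indel_loci", "collect_hotspots"]


@dataclass(frozen=True)
class HotspotConfig:
    """Tunables for hotspot collection.

    padding
        bases added on each side of an evidenced locus before merging
        (default 10: enough flanking context for local-reassembly
        callers).
    min_reads
        per-base evidence threshold; 1 keeps every locus seen on the
        CIGAR of at least one read.
    include_duplicates
        count duplicate-flagged reads as evidence (off by default —
        downstream callers ignore duplicates, so should the targeting).
    include_N_ops
        treat N (reference skip) spans as deletion evidence; off for DNA
        data, where N is a spliced-alignment artifact.
    """

    padding: int = 10
    min_reads: int = 1
    include_duplicates: bool = False
    include_N_ops: bool = False

    def __post_init__(self):
        if self.padding < 0:
            raise ValueError("padding must be >= 0")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")


def indel_loci(
    record: AlignmentRecord, include_N_ops: bool = False
) -> list[GenomicInterval]:
    """Reference intervals evidencing an indel on this record's CIGAR.

    Walks the CIGAR with a reference cursor from the record's 0-based
    position: M/=/X/D/N advance the cursor, S/H/P/I do not. Each D of
    length L emits [cursor, cursor+L); each I emits the one-base anchor
    [cursor, cursor+1).
    """
    if record.cigar is None or record.is_unmapped or record.pos is None:
        raise ValueError(
            f"record {record.query_name!r} has no usable CIGAR/position"
        )
    out: list[GenomicInterval] = []
    cursor = record.pos
    contig = record.contig
    assert contig is not None
    for length, op in record.cigar:
        if op == "D" or (op == "N" and include_N_ops):
            out.append(GenomicInterval(contig, cursor, cursor + length))
            cursor += length
        elif op == "I":
            out.append(GenomicInterval(contig, cursor, cursor + 1))
        elif op in "M=XN":
            cursor += length
        # S, H, P: no reference movement
    return out


def collect_hotspots(
    records: Iterable[AlignmentRecord],
    config: HotspotConfig = HotspotConfig(),
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> RegionSet:
    """Accumulate per-base indel evidence and emit padded target regions.

    Secondary/supplementary records are always skipped; duplicates are
    skipped unless configured otherwise. Bases with evidence from at
    least ``min_reads`` distinct reads are expanded by ``padding`` on
    each side (clamped at 0 and at the contig length when known) and
    merged into a normalized region set.
    """
    counts: dict[str, dict[int, int]] = {}
    for rec in records:
        if rec.is_unmapped or not rec.is_primary:
            continue
        if rec.is_duplicate and not config.include_duplicates:
            continue
        if rec.cigar is None:
            continue
        # de-duplicate bases within one read so adjacent ops cannot
        # double-count a single read's evidence
        bases: set[tuple[str, int]] = set()
        for iv in indel_loci(rec, include_N_ops=config.include_N_ops):
            for b in range(iv.start, iv.end):
                bases.add((iv.contig, b))
        for contig, b in bases:
            per = counts.setdefault(contig, {})
            per[b] = per.get(b, 0) + 1

    hot: list[GenomicInterval] = []
    for contig, per in counts.items():
        limit = contig_lengths.get(contig) if contig_lengths else None
        for b, n in per.items():
            if n >= config.min_reads:
                start = max(0, b - config.padding)
                end = b + 1 + config.padding
                if limit is not None:
                    end = min(end, limit)
                if end > start:
                    hot.append(GenomicInterval(contig, start, end))
    return merge(hot, gap=0)
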