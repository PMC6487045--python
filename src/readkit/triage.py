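"""Alignment refinement triage: pick out soft-clipped and unmapped reads.

A first-pass aligner optimised for speed tends to soft-clip or fail to
place reads spanning indels and divergent loci. The refinement step
selects those records, strips their alignment so a more sensitive
aligner can replace it, and later merges the refined records back into a
single coordinate-sorted set. Only the selection and merge are computed
here — the realignment itself is an external aligner's job, handed off
as unaligned records (or FASTQ).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .sam import FLAG_REVERSE, FLAG_UNMAPPED, AlignmentRecord, revcomp

__all__ = ["TriageResult", "needs_realignment", "triage", "merge_refined", "to_fastq"]


@dataclass
class TriageResult:
    """Partition of the input records; every record lands in exactly one
    of ``retained`` / ``to_realign``."""

    retained: list[AlignmentRecord] = field(default_factory=list)
    to_realign: list[AlignmentRecord] = field(default_factory=list)
    counts: dict[str, int] = field(
        default_factory=lambda: {
            "retained": 0,
            "to_realign_softclip": 0,
            "to_realign_unmapped": 0,
        }
    )


def needs_realignment(
    record: AlignmentRecord, min_clip: int = 1
) -> tuple[bool, Optional[str]]:
    """Should this record be re-examined by the sensitive aligner?

    True with reason ``"unmapped"`` when the unmapped flag is set; true
    with reason ``"softclip"`` when any S op is >= ``min_clip`` bases.
    Hard clips never trigger — the clipped bases are not in the record.
    """
    if record.is_unmapped:
        return True, "unmapped"
    if record.cigar:
        for length, op in record.cigar:
            if op == "S" and length >= min_clip:
                return True, "softclip"
    return False, None


def _strip_alignment(record: AlignmentRecord) -> AlignmentRecord:
    """Emit a record as an unaligned read in original orientation."""
    seq, quals = record.seq, record.quals
    if record.is_reverse:
        if seq is not None:
            seq = revcomp(seq)
        if quals is not None:
            quals = quals[::-1]
    flag = (record.flag | FLAG_UNMAPPED) & ~FLAG_REVERSE
    return record.copy(
        flag=flag,
        contig=None,
        pos=None,
        mapq=0,
        cigar=None,
        rnext="*",
        pnext=0,
        tlen=0,
        seq=seq,
        quals=quals,
    )


def triage(
    records: Iterable[AlignmentRecord], min_clip: int = 1
) -> TriageResult:
    """Partition records into retained vs to-realign, order-preserving.

    Secondary/supplementary and duplicate-flagged records pass through to
    ``retained`` untouched — they are not eligible evidence for
    realignment. Selected records are emitted with alignment fields
    cleared and sequence restored to original (forward) orientation.
    """
    result = TriageResult()
    for rec in records:
        if not rec.is_primary or rec.is_duplicate:
            result.retained.append(rec)
            result.counts["retained"] += 1
            continue
        hit, reason = needs_realignment(rec, min_clip)
        if hit:
            result.to_realign.append(_strip_alignment(rec))
            result.counts[f"to_realign_{reason}"] += 1
        else:
            result.retained.append(rec)
            result.counts["retained"] += 1
    return result


def _sort_key(rec: AlignmentRecord):
    # mapped first by (contig, pos, name); unmapped block trails
    if rec.is_unmapped or rec.contig is None or rec.pos is None:
        return (1, "", 0, rec.query_name, rec.segment)
    return (0, rec.contig, rec.pos, rec.query_name, rec.segment)


def merge_refined(
    retained: Iterable[AlignmentRecord], realigned: Iterable[AlignmentRecord]
) -> list[AlignmentRecord]:
    """Merge retained and realigned records into one coordinate-sorted set.

    Each (query_name, segment) may appear as a primary record in only one
    of the two inputs; a duplicate claim raises ``ValueError`` naming the
    read. Unmapped records sort after all mapped ones.
    """
    retained = list(retained)
    realigned = list(realigned)
    seen = {
        (rec.query_name, rec.segment) for rec in retained if rec.is_primary
    }
    if len(seen) < sum(1 for rec in retained if rec.is_primary):
        raise ValueError("duplicate primary (query_name, segment) within retained set")
    for rec in realigned:
        if rec.is_primary and (rec.query_name, rec.segment) in seen:
            raise ValueError(
                f"read {rec.query_name!r} (segment {rec.segment}) is primary "
                "in both the retained and realigned inputs"
            )
    return sorted(retained + realigned, key=_sort_key)


def to_fastq(records: Iterable[AlignmentRecord]) -> str:
    """Render unaligned records as FASTQ for the external realigner."""
    chunks = []
    for rec in records:
        name = rec.query_name
        if rec.segment:
            name = f"{name}/{rec.segment}"
        seq = rec.seq or ""
        quals = rec.quals if rec.quals is not None else "I" * len(seq)
        chunks.append(f"@{name}\n{seq}\n+\n{quals}\n")
    return "".join(chunks)
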