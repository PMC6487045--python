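"""Shared helpers: record builders and brute-force oracles.

The oracles here deliberately re-derive results by per-base simulation
(bitmaps, cursor walks) so the fast implementations are checked against
an independent code path.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from readkit.regions import GenomicInterval
from readkit.sam import AlignmentRecord, CigarOp, parse_cigar, query_span

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=75,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def mk_read(
    name: str,
    contig: str | None = "chr1",
    pos: int | None = 0,
    cigar: str | None = "100M",
    flag: int = 0,
) -> AlignmentRecord:
    """Build an alignment record with a sequence matching the CIGAR."""
    ops = parse_cigar(cigar) if cigar else None
    seq = "A" * query_span(ops) if ops else ("A" * 50 if flag & 0x4 else None)
    return AlignmentRecord(
        query_name=name,
        flag=flag,
        contig=contig,
        pos=pos,
        mapq=60 if not flag & 0x4 else 0,
        cigar=ops,
        seq=seq,
        quals="I" * len(seq) if seq else None,
    )


def bitmap_union(intervals, contig_len: int) -> np.ndarray:
    """Boolean per-base union of intervals on a single contig."""
    mask = np.zeros(contig_len, dtype=bool)
    for iv in intervals:
        mask[iv.start : min(iv.end, contig_len)] = True
    return mask


def runs_to_intervals(mask: np.ndarray, contig: str) -> list[GenomicInterval]:
    """Maximal True runs of a bitmap as intervals."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append(GenomicInterval(contig, start, i))
            start = None
    if start is not None:
        out.append(GenomicInterval(contig, start, len(mask)))
    return out


def pileup_indel_evidence(records, contig_len: int, include_dups: bool = False):
    """Independent per-base indel evidence counter for a single contig.

    Walks each read's CIGAR with its own cursor and increments an integer
    array — no sharing with the implementation under test.
    """
    counts = np.zeros(contig_len, dtype=int)
    for rec in records:
        if rec.is_unmapped or not rec.is_primary or rec.cigar is None:
            continue
        if rec.is_duplicate and not include_dups:
            continue
        touched = np.zeros(contig_len, dtype=bool)
        cursor = rec.pos
        for length, op in rec.cigar:
            if op == "D":
                touched[cursor : cursor + length] = True
                cursor += length
            elif op == "I":
                if cursor < contig_len:
                    touched[cursor] = True
            elif op in "M=XN":
                cursor += length
        counts += touched
    return counts


def oracle_hotspots(
    records, contig: str, contig_len: int, min_reads: int, padding: int
) -> list[GenomicInterval]:
    """Brute-force hotspot regions: threshold the pileup, pad via bitmap."""
    counts = pileup_indel_evidence(records, contig_len)
    hot = counts >= min_reads
    padded = np.zeros_like(hot)
    for i in np.flatnonzero(hot):
        padded[max(0, i - padding) : min(contig_len, i + padding + 1)] = True
    return runs_to_intervals(padded, contig)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_mapped_reads(rng, contig: str, contig_len: int, n: int):
    """Random reads with mixed M/I/D/S CIGARs fitting inside the contig."""
    reads = []
    for i in range(n):
        ops: list[CigarOp] = []
        if rng.random() < 0.3:
            ops.append(CigarOp(int(rng.integers(1, 15)), "S"))
        ops.append(CigarOp(int(rng.integers(10, 40)), "M"))
        for _ in range(int(rng.integers(0, 3))):
            kind = "ID"[int(rng.integers(0, 2))]
            ops.append(CigarOp(int(rng.integers(1, 8)), kind))
            ops.append(CigarOp(int(rng.integers(10, 40)), "M"))
        if rng.random() < 0.3:
            ops.append(CigarOp(int(rng.integers(1, 15)), "S"))
        span = sum(l for l, op in ops if op in "MDN=X")
        if span >= contig_len:
            continue
        pos = int(rng.integers(0, contig_len - span))
        qlen = sum(l for l, op in ops if op in "MIS=X")
        reads.append(
            AlignmentRecord(
                query_name=f"rand{i:04d}",
                flag=0,
                contig=contig,
                pos=pos,
                mapq=60,
                cigar=ops,
                seq="A" * qlen,
                quals="I" * qlen,
            )
        )
    return reads
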