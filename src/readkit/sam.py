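"""SAM records, CIGAR arithmetic and streaming text I/O.

All internal coordinates are 0-based half-open; SAM's 1-based POS is
converted at the I/O boundary. Records are processed streaming, single
pass — no index is ever assumed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, NamedTuple, Optional, TextIO

__all__ = [
    "CigarOp",
    "AlignmentRecord",
    "SamFormatError",
    "parse_cigar",
    "format_cigar",
    "reference_span",
    "query_span",
    "read_sam",
    "write_sam",
    "revcomp",
]

CIGAR_OPS = "MIDNSHP=X"
#: ops that consume reference bases
REF_CONSUMING = frozenset("MDN=X")
#: ops that consume query (read) bases
QUERY_CONSUMING = frozenset("MIS=X")

FLAG_PAIRED = 0x1
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100
FLAG_DUP = 0x400
FLAG_SUPPLEMENTARY = 0x800

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class SamFormatError(ValueError):
    """Malformed SAM content; carries the 1-based line number when known."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class CigarOp(NamedTuple):
    """A single CIGAR operation: a length and one of the nine SAM op codes."""

    length: int
    op: str


_CIGAR_TOKEN = re.compile(r"(\d+)([A-Za-z=])")


def parse_cigar(text: str) -> list[CigarOp]:
    """Parse a CIGAR string into an ordered op list.

    ``"*"`` (the SAM missing-CIGAR sentinel) yields the empty list.
    Zero-length or unknown ops raise :class:`SamFormatError` naming the
    offending token.
    """
    if text == "*":
        return []
    ops: list[CigarOp] = []
    pos = 0
    for m in _CIGAR_TOKEN.finditer(text):
        if m.start() != pos:
            raise SamFormatError(f"malformed CIGAR near {text[pos:]!r}")
        length, code = int(m.group(1)), m.group(2)
        if length == 0:
            raise SamFormatError(f"zero-length CIGAR op {m.group(0)!r}")
        if code not in CIGAR_OPS:
            raise SamFormatError(f"unknown CIGAR op code in {m.group(0)!r}")
        ops.append(CigarOp(length, code))
        pos = m.end()
    if pos != len(text) or not ops:
        raise SamFormatError(f"malformed CIGAR near {text[pos:]!r}")
    return ops


def format_cigar(ops: Iterable[CigarOp]) -> str:
    """Inverse of :func:`parse_cigar`; the empty list renders as ``"*"``."""
    ops = list(ops)
    if not ops:
        return "*"
    return "".join(f"{length}{op}" for length, op in ops)


def reference_span(ops: Iterable[CigarOp]) -> int:
    """Number of reference bases consumed (M/D/N/=/X); 0 for the empty list."""
    return sum(length for length, op in ops if op in REF_CONSUMING)


def query_span(ops: Iterable[CigarOp]) -> int:
    """Number of query bases consumed (M/I/S/=/X); 0 for the empty list."""
    return sum(length for length, op in ops if op in QUERY_CONSUMING)


@dataclass
class AlignmentRecord:
    """One SAM alignment line.

    ``pos`` is 0-based (converted from SAM's 1-based POS at the I/O
    boundary) and ``None`` when POS is 0. ``contig``/``cigar``/``seq``/
    ``quals`` are ``None`` when the column holds ``*``. The remaining
    mandatory columns and any optional tags are carried through verbatim
    so that write∘read is the identity.
    """

    query_name: str
    flag: int
    contig: Optional[str] = None
    pos: Optional[int] = None
    mapq: int = 0
    cigar: Optional[list[CigarOp]] = None
    rnext: str = "*"
    pnext: int = 0
    tlen: int = 0
    seq: Optional[str] = None
    quals: Optional[str] = None
    tags: list[str] = field(default_factory=list)

    # -- flag accessors -------------------------------------------------
    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FLAG_PAIRED)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FLAG_SECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & FLAG_SUPPLEMENTARY)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flag & FLAG_DUP)

    @property
    def is_primary(self) -> bool:
        return not (self.is_secondary or self.is_supplementary)

    @property
    def segment(self) -> int:
        """Read-pair segment: 1 for read1, 2 for read2, 0 for unpaired."""
        if self.flag & FLAG_READ1:
            return 1
        if self.flag & FLAG_READ2:
            return 2
        return 0

    @property
    def effective_cigar(self) -> list[CigarOp]:
        """CIGAR for reference arithmetic: empty when unmapped or absent."""
        if self.is_unmapped or self.cigar is None:
            return []
        return self.cigar

    def reference_end(self) -> Optional[int]:
        """0-based exclusive end on the reference, or None when unmapped."""
        if self.pos is None or self.is_unmapped:
            return None
        return self.pos + reference_span(self.effective_cigar)

    def validate(self, line_number: Optional[int] = None) -> None:
        """Check the SEQ/CIGAR length consistency the SAM format requires."""
        if self.cigar and self.seq is not None:
            qlen = query_span(self.cigar)
            if qlen != len(self.seq):
                raise SamFormatError(
                    f"CIGAR query length {qlen} != SEQ length {len(self.seq)} "
                    f"for read {self.query_name!r}",
                    line_number,
                )

    def copy(self, **changes) -> "AlignmentRecord":
        rec = replace(self, **changes)
        rec.tags = list(rec.tags)
        if rec.cigar is not None:
            rec.cigar = list(rec.cigar)
        return rec


def _parse_record(line: str, line_number: int) -> AlignmentRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 11:
        raise SamFormatError(
            f"expected >=11 tab-separated fields, got {len(fields)}", line_number
        )
    try:
        flag = int(fields[1])
        pos1 = int(fields[3])
        mapq = int(fields[4])
        pnext = int(fields[7])
        tlen = int(fields[8])
    except ValueError as exc:
        raise SamFormatError(f"non-integer mandatory field ({exc})", line_number)
    try:
        cigar = parse_cigar(fields[5]) or None
    except SamFormatError as exc:
        raise SamFormatError(str(exc), line_number) from exc
    rec = AlignmentRecord(
        query_name=fields[0],
        flag=flag,
        contig=None if fields[2] == "*" else fields[2],
        pos=None if pos1 == 0 else pos1 - 1,
        mapq=mapq,
        cigar=cigar,
        rnext=fields[6],
        pnext=pnext,
        tlen=tlen,
        seq=None if fields[9] == "*" else fields[9],
        quals=None if fields[10] == "*" else fields[10],
        tags=fields[11:],
    )
    rec.validate(line_number)
    return rec


def format_record(rec: AlignmentRecord) -> str:
    """Render a record back to one SAM line (no trailing newline)."""
    fields = [
        rec.query_name,
        str(rec.flag),
        rec.contig if rec.contig is not None else "*",
        str(rec.pos + 1 if rec.pos is not None else 0),
        str(rec.mapq),
        format_cigar(rec.cigar) if rec.cigar else "*",
        rec.rnext,
        str(rec.pnext),
        str(rec.tlen),
        rec.seq if rec.seq is not None else "*",
        rec.quals if rec.quals is not None else "*",
        *rec.tags,
    ]
    return "\t".join(fields)


def read_sam(stream: TextIO) -> tuple[list[str], Iterator[AlignmentRecord]]:
    """Read SAM text: returns (header lines, lazy record iterator).

    Header lines are preserved verbatim (without trailing newlines) so a
    subsequent :func:`write_sam` round-trips byte-exactly. Records are
    yielded in file order, one pass.
    """
    header: list[str] = []
    first_record: Optional[tuple[int, str]] = None
    line_number = 0
    for line in stream:
        line_number += 1
        if line.startswith("@"):
            header.append(line.rstrip("\n"))
        elif line.strip():
            first_record = (line_number, line)
            break

    def records() -> Iterator[AlignmentRecord]:
        if first_record is not None:
            yield _parse_record(first_record[1], first_record[0])
            n = first_record[0]
            for line in stream:
                n += 1
                if line.strip():
                    yield _parse_record(line, n)

    return header, records()


def write_sam(
    header: Iterable[str], records: Iterable[AlignmentRecord], stream: TextIO
) -> int:
    """Write header lines then records; returns the record count."""
    for line in header:
        stream.write(line.rstrip("\n") + "\n")
    n = 0
    for rec in records:
        stream.write(format_record(rec) + "\n")
        n += 1
    return n
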