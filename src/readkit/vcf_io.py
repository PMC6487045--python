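"""VCF records and I/O.

Reading goes through :mod:`pysam` (htslib) and is converted to the small
:class:`VariantRecord` model the filtering/evaluation code consumes.
Writing is a plain-text VCF v4.2 formatter, so filter tags added by this
package (``lowGQ``/``lowDP``) can be declared and emitted directly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, TextIO, Union

import pysam

__all__ = ["SampleCall", "VariantRecord", "read_vcf", "write_vcf"]


@dataclass
class SampleCall:
    """Per-sample genotype fields: GT allele indices (None for '.'),
    phasing, genotype quality and depth."""

    gt: Optional[tuple[Optional[int], ...]] = None
    phased: bool = False
    gq: Optional[int] = None
    dp: Optional[int] = None

    def gt_string(self) -> str:
        if self.gt is None:
            return "./."
        sep = "|" if self.phased else "/"
        return sep.join("." if a is None else str(a) for a in self.gt)

    def unphased_gt(self) -> Optional[tuple[int, ...]]:
        """Sorted allele indices, or None when any allele is missing."""
        if self.gt is None or any(a is None for a in self.gt):
            return None
        return tuple(sorted(a for a in self.gt if a is not None))


@dataclass
class VariantRecord:
    """One VCF site. ``pos`` is 1-based, as printed in the file."""

    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    id: str = "."
    qual: Optional[float] = None
    filters: tuple[str, ...] = ()
    info: str = "."
    samples: dict[str, SampleCall] = field(default_factory=dict)

    @property
    def pos0(self) -> int:
        """0-based position."""
        return self.pos - 1

    def sample(self, name: Optional[str] = None) -> SampleCall:
        """Named sample's call, or the first sample when name is None."""
        if not self.samples:
            raise ValueError("record carries no sample fields")
        if name is None:
            return next(iter(self.samples.values()))
        try:
            return self.samples[name]
        except KeyError:
            raise ValueError(f"unknown sample name {name!r}") from None

    def copy(self, **changes) -> "VariantRecord":
        rec = replace(self, **changes)
        rec.samples = {k: replace(v) for k, v in rec.samples.items()}
        return rec


def _convert(rec: pysam.VariantRecord, sample_names: Sequence[str]) -> VariantRecord:
    samples: dict[str, SampleCall] = {}
    for name in sample_names:
        s = rec.samples[name]
        gt = s.get("GT")
        gt_tuple = None if gt is None or all(a is None for a in gt) else tuple(gt)
        gq = s.get("GQ")
        dp = s.get("DP")
        samples[name] = SampleCall(
            gt=gt_tuple,
            phased=bool(getattr(s, "phased", False)),
            gq=None if gq is None else int(gq),
            dp=None if dp is None else int(dp),
        )
    filters = tuple(rec.filter.keys())
    return VariantRecord(
        contig=rec.chrom,
        pos=rec.pos,
        ref=rec.ref,
        alts=tuple(rec.alts or ()),
        id=rec.id or ".",
        qual=rec.qual,
        filters=filters,
        samples=samples,
    )


def read_vcf(path: Union[str, os.PathLike]) -> tuple[list[str], list[VariantRecord]]:
    """Read a VCF file: returns (sample names, records)."""
    with pysam.VariantFile(os.fspath(path)) as vf:
        sample_names = list(vf.header.samples)
        records = [_convert(rec, sample_names) for rec in vf]
    return sample_names, records


_HEADER_TEMPLATE = [
    "##fileformat=VCFv4.2",
    '##FILTER=<ID=lowGQ,Description="Genotype quality below the hard-filter threshold">',
    '##FILTER=<ID=lowDP,Description="Read depth below the hard-filter threshold">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
]


def write_vcf(
    records: Iterable[VariantRecord],
    stream: TextIO,
    sample_names: Sequence[str],
    contig_lengths: Optional[dict[str, int]] = None,
) -> int:
    """Write VCF v4.2 text with GT:GQ:DP sample columns."""
    for line in _HEADER_TEMPLATE:
        stream.write(line + "\n")
    for contig, length in (contig_lengths or {}).items():
        stream.write(f"##contig=<ID={contig},length={length}>\n")
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if sample_names:
        cols += ["FORMAT", *sample_names]
    stream.write("\t".join(cols) + "\n")
    n = 0
    for rec in records:
        qual = "." if rec.qual is None else f"{rec.qual:g}"
        filt = ";".join(rec.filters) if rec.filters else "."
        fields = [
            rec.contig,
            str(rec.pos),
            rec.id,
            rec.ref,
            ",".join(rec.alts) if rec.alts else ".",
            qual,
            filt,
            rec.info,
        ]
        if sample_names:
            fields.append("GT:GQ:DP")
            for name in sample_names:
                call = rec.samples.get(name, SampleCall())
                gq = "." if call.gq is None else str(call.gq)
                dp = "." if call.dp is None else str(call.dp)
                fields.append(f"{call.gt_string()}:{gq}:{dp}")
        stream.write("\t".join(fields) + "\n")
        n += 1
    return n
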