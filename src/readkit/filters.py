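"""Hard-filtering and classing of variant calls.

The filter rule is the literal "discard calls with genotype quality
smaller than 20 and depth smaller than 10": a call passes iff
GQ >= min_gq AND DP >= min_dp, so GQ=20/DP=10 sit exactly on the passing
boundary. Missing GQ/DP fails by default (conservative for a
diagnostic-flavoured workflow) and is overridable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .regions import RegionSet
from .vcf_io import VariantRecord

__all__ = [
    "FilterConfig",
    "FilterOutcome",
    "classify_variant",
    "apply_hard_filters",
    "restrict_calls",
]

SMALL_INDEL_MAX = 50  # bp; larger events are the structural-variant callers' job


@dataclass(frozen=True)
class FilterConfig:
    min_gq: int = 20
    min_dp: int = 10
    missing_fails: bool = True

    def __post_init__(self):
        if self.min_gq < 0 or self.min_dp < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class FilterOutcome:
    """Order-preserving partition of the input records."""

    passed: list[VariantRecord]
    failed: list[tuple[VariantRecord, frozenset[str]]]

    @property
    def counts(self) -> dict[str, int]:
        return {"pass": len(self.passed), "fail": len(self.failed)}


def classify_variant(ref: str, alt: str) -> str:
    """Class one ref/alt pair as ``snv``, ``small_indel`` or ``sv_like``.

    SNV: both alleles one base. Small indel: lengths differ and the
    longer allele is at most 50 bp (a 50 bp indel is still "small").
    Everything else — symbolic alleles, breakends, long events, MNPs —
    is ``sv_like`` and out of scope for the hard filters here.
    """
    if alt.startswith("<") or "[" in alt or "]" in alt or alt == "*":
        return "sv_like"
    if len(ref) == 1 and len(alt) == 1:
        return "snv"
    if len(ref) != len(alt) and max(len(ref), len(alt)) <= SMALL_INDEL_MAX:
        return "small_indel"
    return "sv_like"


def filter_reasons(
    record: VariantRecord, config: FilterConfig, sample: Optional[str] = None
) -> frozenset[str]:
    """Failure reasons for one record; empty set means pass."""
    call = record.sample(sample)
    reasons: set[str] = set()
    if call.gq is None:
        if config.missing_fails:
            reasons.add("missing_gq")
    elif call.gq < config.min_gq:
        reasons.add("low_gq")
    if call.dp is None:
        if config.missing_fails:
            reasons.add("missing_dp")
    elif call.dp < config.min_dp:
        reasons.add("low_dp")
    return frozenset(reasons)


def apply_hard_filters(
    records: Iterable[VariantRecord],
    config: FilterConfig = FilterConfig(),
    sample: Optional[str] = None,
) -> FilterOutcome:
    """Partition records into passed / failed-with-reasons.

    ``sample`` selects the evaluated sample column; None means the first
    sample. An unknown sample name raises ``ValueError``.
    """
    outcome = FilterOutcome(passed=[], failed=[])
    for rec in records:
        reasons = filter_reasons(rec, config, sample)
        if reasons:
            outcome.failed.append((rec, reasons))
        else:
            outcome.passed.append(rec)
    return outcome


REASON_TAGS = {
    "low_gq": "lowGQ",
    "missing_gq": "lowGQ",
    "low_dp": "lowDP",
    "missing_dp": "lowDP",
}


def tag_failed(record: VariantRecord, reasons: frozenset[str]) -> VariantRecord:
    """Return the record with FILTER column tags for keep-failed output."""
    tags = tuple(sorted({REASON_TAGS[r] for r in reasons}))
    return record.copy(filters=tags)


def restrict_calls(
    records: Iterable[VariantRecord], regions: RegionSet
) -> list[VariantRecord]:
    """Keep records whose 0-based POS lies inside the region union."""
    return [rec for rec in records if regions.contains_point(rec.contig, rec.pos0)]
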