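"""Variant-call benchmarking: precision, sensitivity and F-measure.

A call set is matched against a truth set after both are normalized
(multiallelic sites split, alleles trimmed and left-anchored). A call is
a true positive iff some truth record shares (contig, pos, ref, alt)
exactly — and, under genotype matching, the same unphased genotype; each
truth record pairs with at most one call and vice versa. Unmatched calls
are false positives, unmatched truth records false negatives, stratified
by variant class (SNV vs small indel).

    precision   = Tp / (Tp + Fp)
    sensitivity = Tp / (Tp + Fn)
    F-measure   = 2 * precision * sensitivity / (precision + sensitivity)

This is exact-allele matching, not a haplotype-aware comparison (RTG
vcfeval style): two different but equivalent representations of the same
haplotype spanning multiple records will not pair. See docs/methods.md.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

from .filters import classify_variant
from .regions import RegionSet
from .vcf_io import SampleCall, VariantRecord

__all__ = [
    "EvalCounts",
    "EvalMetrics",
    "normalize_variant",
    "match_calls",
    "compute_metrics",
]


@dataclass
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass
class EvalMetrics:
    """Derived metrics; a degenerate denominator yields None (rendered
    "NA" in reports, never 0 — a zero would misrank empty call sets)."""

    precision: Optional[float]
    sensitivity: Optional[float]
    f_measure: Optional[float]


def compute_metrics(counts: EvalCounts) -> EvalMetrics:
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else None
    if precision is None or sensitivity is None or (precision + sensitivity) == 0:
        f_measure = None
    else:
        f_measure = 2 * precision * sensitivity / (precision + sensitivity)
    return EvalMetrics(precision, sensitivity, f_measure)


def _trim(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    # shared trailing bases first, then shared leading (advancing pos);
    # always keep >=1 base on each side
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize_variant(
    record: VariantRecord,
) -> tuple[list[VariantRecord], int]:
    """Split multiallelics and trim alleles; deterministic and idempotent.

    Returns (normalized records, number of symbolic alts excluded).
    After splitting, genotype allele indices are remapped so the kept alt
    is 1; indices pointing at other alts collapse to 0 (the record no
    longer represents them).
    """
    out: list[VariantRecord] = []
    n_symbolic = 0
    for alt_index, alt in enumerate(record.alts, start=1):
        if alt.startswith("<") or "[" in alt or "]" in alt or alt == "*":
            n_symbolic += 1
            continue
        pos, ref, alt_trim = _trim(record.pos, record.ref, alt)
        samples = {}
        for name, call in record.samples.items():
            if call.gt is None:
                gt = None
            else:
                gt = tuple(
                    None if a is None else (1 if a == alt_index else 0)
                    for a in call.gt
                )
            samples[name] = SampleCall(
                gt=gt, phased=call.phased, gq=call.gq, dp=call.dp
            )
        out.append(
            record.copy(pos=pos, ref=ref, alts=(alt_trim,), samples=samples)
        )
    return out, n_symbolic


def _match_key(rec: VariantRecord, genotype_match: bool, sample: Optional[str]):
    key = (rec.contig, rec.pos, rec.ref, rec.alts[0])
    if genotype_match:
        gt = None
        if rec.samples:
            gt = rec.sample(sample).unphased_gt()
        key = key + (gt,)
    return key


def match_calls(
    truth: Iterable[VariantRecord],
    calls: Iterable[VariantRecord],
    regions: Optional[RegionSet] = None,
    genotype_match: bool = True,
    truth_sample: Optional[str] = None,
    call_sample: Optional[str] = None,
) -> dict[str, EvalCounts]:
    """Match normalized call records against truth; counts per class.

    Returns EvalCounts keyed by variant class (``snv``, ``small_indel``,
    ``sv_like`` when present) plus the combined ``all``. FP class comes
    from the call record, FN class from the truth record; a matched pair
    has identical alleles, hence one class.
    """

    def prep(records, sample):
        normalized = []
        for rec in records:
            split, _ = normalize_variant(rec)
            normalized.extend(split)
        if regions is not None:
            normalized = [
                r for r in normalized if regions.contains_point(r.contig, r.pos0)
            ]
        return normalized

    truth_n = prep(truth, truth_sample)
    calls_n = prep(calls, call_sample)
    truth_keys = Counter(_match_key(r, genotype_match, truth_sample) for r in truth_n)
    call_keys = Counter(_match_key(r, genotype_match, call_sample) for r in calls_n)

    counts: dict[str, EvalCounts] = {}

    def bucket(rec: VariantRecord) -> EvalCounts:
        cls = classify_variant(rec.ref, rec.alts[0])
        return counts.setdefault(cls, EvalCounts())

    matched = truth_keys & call_keys  # per-key min: one truth pairs one call
    for rec in truth_n:
        key = _match_key(rec, genotype_match, truth_sample)
        if matched[key] > 0:
            matched[key] -= 1
            bucket(rec).tp += 1
        else:
            bucket(rec).fn += 1
    remaining = truth_keys & call_keys
    for rec in calls_n:
        key = _match_key(rec, genotype_match, call_sample)
        if remaining[key] > 0:
            remaining[key] -= 1
        else:
            bucket(rec).fp += 1

    total = EvalCounts()
    for c in counts.values():
        total = total + c
    counts["all"] = total
    return counts
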