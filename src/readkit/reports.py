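"""User-facing tab-delimited variant report and machine-readable run summary."""

from __future__ import annotations

import json
from typing import Iterable, Mapping, Optional, TextIO

from .filters import classify_variant
from .vcf_io import VariantRecord

__all__ = ["variant_report", "run_summary", "read_annotation_table", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1.0"

CORE_COLUMNS = ["contig", "pos", "ref", "alt", "class", "GT", "GQ", "DP"]

AnnoKey = tuple[str, int, str, str]  # (contig, pos_1based, ref, alt)


def read_annotation_table(stream: TextIO) -> tuple[list[str], dict[AnnoKey, list[str]]]:
    """Load a user annotation TSV keyed on (contig, pos, ref, alt).

    The first four columns are the join key; the remaining header names
    become extra report columns. A duplicated key is an error.
    """
    lines = [l.rstrip("\n") for l in stream if l.strip()]
    if not lines:
        return [], {}
    header = lines[0].split("\t")
    if len(header) < 5:
        raise ValueError("annotation table needs contig/pos/ref/alt + >=1 column")
    extra_cols = header[4:]
    table: dict[AnnoKey, list[str]] = {}
    for n, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        key = (fields[0], int(fields[1]), fields[2], fields[3])
        if key in table:
            raise ValueError(f"annotation line {n}: duplicate key {key}")
        table[key] = fields[4 : 4 + len(extra_cols)]
    return extra_cols, table


def variant_report(
    records: Iterable[VariantRecord],
    sample: Optional[str] = None,
    annotation_columns: Optional[list[str]] = None,
    annotations: Optional[Mapping[AnnoKey, list[str]]] = None,
) -> str:
    """Render one TSV row per (variant, alt allele).

    Rows are sorted by (contig, pos, alt); the header row is always
    present; user annotation columns appear to the right of the core
    columns, joined on (contig, pos, ref, alt).
    """
    annotation_columns = annotation_columns or []
    annotations = annotations or {}
    rows = []
    for rec in records:
        call = rec.sample(sample) if rec.samples else None
        for alt in rec.alts:
            row = [
                rec.contig,
                str(rec.pos),
                rec.ref,
                alt,
                classify_variant(rec.ref, alt),
                call.gt_string() if call else ".",
                "." if call is None or call.gq is None else str(call.gq),
                "." if call is None or call.dp is None else str(call.dp),
            ]
            extra = annotations.get((rec.contig, rec.pos, rec.ref, alt))
            for i in range(len(annotation_columns)):
                row.append(extra[i] if extra and i < len(extra) else ".")
            rows.append(row)
    rows.sort(key=lambda r: (r[0], int(r[1]), r[3]))
    out = ["\t".join(CORE_COLUMNS + annotation_columns)]
    out += ["\t".join(r) for r in rows]
    return "\n".join(out) + "\n"


def run_summary(
    triage: Optional[dict] = None,
    hotspots: Optional[dict] = None,
    filters: Optional[dict] = None,
    screen: Optional[dict] = None,
    evaluation: Optional[dict] = None,
) -> str:
    """Schema-versioned JSON tally of whichever stages ran."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "triage": triage,
        "hotspots": hotspots,
        "filters": filters,
        "screen": screen,
        "evaluation": evaluation,
    }
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"
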