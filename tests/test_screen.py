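"""Computational-subtraction screen: classification, counts, breadth."""

import io
import math

import numpy as np
import pytest

from readkit.sam import FLAG_PAIRED, FLAG_READ1, FLAG_READ2, FLAG_UNMAPPED
from readkit.screen import (
    GenomeHit,
    classify_reads,
    log10_reads,
    read_length_table,
    subtract_host,
    summarize_hits,
    top_hits,
)

from conftest import bitmap_union, mk_read, random_mapped_reads


def test_subtract_host_partition():
    records = [mk_read(f"m{i}", cigar="50M") for i in range(9)]
    records.append(mk_read("u0", cigar=None, contig=None, pos=None, flag=FLAG_UNMAPPED))
    host, nonhost = subtract_host(records)
    assert len(host) == 9 and len(nonhost) == 1
    assert ("u0", 0) in nonhost


def test_subtract_host_all_unmapped():
    records = [
        mk_read(f"u{i}", cigar=None, contig=None, pos=None, flag=FLAG_UNMAPPED)
        for i in range(4)
    ]
    host, nonhost = subtract_host(records)
    assert host == set() and len(nonhost) == 4


def test_subtract_host_mates_classified_independently():
    r1 = mk_read("p", cigar="50M", flag=FLAG_PAIRED | FLAG_READ1)
    r2 = mk_read(
        "p", cigar=None, contig=None, pos=None,
        flag=FLAG_PAIRED | FLAG_READ2 | FLAG_UNMAPPED,
    )
    host, nonhost = subtract_host([r1, r2])
    assert host == {("p", 1)} and nonhost == {("p", 2)}


def test_summarize_hits_interval_union():
    lengths = {"gA": 10}
    reads = [
        mk_read("r1", contig="gA", pos=0, cigar="5M"),
        mk_read("r2", contig="gA", pos=3, cigar="5M"),
    ]
    (hit,) = summarize_hits(reads, lengths)
    assert hit.read_count == 2 and hit.covered_bases == 8
    assert hit.breadth_fraction == pytest.approx(0.8)


def test_summarize_hits_single_read_breadth():
    (hit,) = summarize_hits(
        [mk_read("r", contig="g", pos=0, cigar="95M")], {"g": 1000}
    )
    assert hit.covered_bases == 95 and hit.breadth_fraction == pytest.approx(0.095)


def test_summarize_hits_deletion_bases_not_covered():
    (hit,) = summarize_hits(
        [mk_read("r", contig="g", pos=0, cigar="10M5D10M")], {"g": 100}
    )
    assert hit.covered_bases == 20  # the 5 deleted bases are not aligned bases


def test_summarize_hits_missing_genome_errors():
    with pytest.raises(KeyError, match="gX"):
        summarize_hits([mk_read("r", contig="gX", pos=0, cigar="10M")], {"gA": 10})


def test_summarize_hits_secondary_counting_modes():
    primary = mk_read("r", contig="gA", pos=0, cigar="10M")
    secondary = mk_read("r", contig="gB", pos=0, cigar="10M", flag=0x100)
    lengths = {"gA": 100, "gB": 100}
    default = {h.genome_id: h.read_count for h in summarize_hits([primary, secondary], lengths)}
    assert default == {"gA": 1}
    permissive = {
        h.genome_id: h.read_count
        for h in summarize_hits([primary, secondary], lengths, count_secondary=True)
    }
    assert permissive == {"gA": 1, "gB": 1}


def test_coverage_matches_boolean_array_oracle(rng):
    lengths = {"g": 4000}
    reads = random_mapped_reads(rng, "g", 4000, 60)
    (hit,) = summarize_hits(reads, lengths)
    mask = np.zeros(4000, dtype=bool)
    for rec in reads:
        cursor = rec.pos
        for length, op in rec.cigar:
            if op in "M=X":
                mask[cursor : cursor + length] = True
                cursor += length
            elif op in "DN":
                cursor += length
    assert hit.covered_bases == int(mask.sum())


def test_classify_reads_proportions():
    host = {(f"h{i}", 0) for i in range(91)}
    microbial_reads = [mk_read(f"v{i}", contig="g", pos=0, cigar="50M") for i in range(5)]
    unknown = [
        mk_read(f"x{i}", cigar=None, contig=None, pos=None, flag=FLAG_UNMAPPED)
        for i in range(4)
    ]
    nonhost = {(r.query_name, 0) for r in microbial_reads + unknown}
    summary = classify_reads(host, nonhost, microbial_reads + unknown, {"g": 100})
    assert (summary.n_human, summary.n_microbial, summary.n_unknown) == (91, 5, 4)
    assert summary.proportions == pytest.approx(
        {"human": 0.91, "microbial": 0.05, "unknown": 0.04}
    )


def test_classify_reads_no_hits_means_unknown_equals_nonhost():
    nonhost = {(f"x{i}", 0) for i in range(7)}
    summary = classify_reads(set(), nonhost, [], {})
    assert summary.n_unknown == 7 and summary.n_microbial == 0


def test_classify_reads_empty_universe():
    summary = classify_reads(set(), set(), [], {})
    assert summary.n_total == 0
    assert summary.proportions == {"human": 0.0, "microbial": 0.0, "unknown": 0.0}


def test_classify_reads_rejects_host_microbial_clash():
    host = {("r", 0)}
    with pytest.raises(ValueError, match="both"):
        classify_reads(host, set(), [mk_read("r", contig="g", pos=0, cigar="10M")], {"g": 100})


def test_top_hits_ranking_and_ties():
    hits = [
        GenomeHit("A", 100, 5, 10),
        GenomeHit("B", 100, 9, 10),
        GenomeHit("C", 100, 9, 10),
    ]
    assert [h.genome_id for h in top_hits(hits, 2)] == ["B", "C"]
    assert [h.genome_id for h in top_hits(hits, 10)] == ["B", "C", "A"]
    assert log10_reads(GenomeHit("D", 10, 1000, 5)) == pytest.approx(3.0)


def test_read_length_table_tsv_and_fai():
    assert read_length_table(io.StringIO("gA\t100\ngB\t250\n")) == {"gA": 100, "gB": 250}
    fai = "gA\t100\t4\t60\t61\ngB\t250\t112\t60\t61\n"
    assert read_length_table(io.StringIO(fai)) == {"gA": 100, "gB": 250}


def test_genome_hit_invariants():
    with pytest.raises(ValueError):
        GenomeHit("g", 10, 1, 11)  # covered > length
    with pytest.raises(ValueError):
        GenomeHit("g", 10, 0, 3)  # bases without reads
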