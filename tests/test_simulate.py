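"""Fixture generators: determinism, validity, planted-truth recovery."""

import io

import pytest

from readkit.evaluate import EvalCounts, match_calls
from readkit.filters import FilterConfig, apply_hard_filters
from readkit.hotspots import HotspotConfig, collect_hotspots
from readkit.regions import GenomicInterval
from readkit.sam import read_sam, write_sam
from readkit.screen import classify_reads, subtract_host, summarize_hits, top_hits
from readkit.simulate import (
    AlignmentPlan,
    MixturePlan,
    PlantedIndel,
    VcfPairPlan,
    fai_table,
    make_reference,
    simulate_alignments,
    simulate_microbial_mixture,
    simulate_screen_inputs,
    simulate_vcf_pair,
    write_fasta,
)
from readkit.triage import triage
from readkit.vcf_io import write_vcf


def fasta_bytes(contigs, seed):
    out = io.StringIO()
    write_fasta(make_reference(contigs, seed), out)
    return out.getvalue()


def test_make_reference_deterministic_and_wrapped():
    a = fasta_bytes({"chrT": 1000}, 7)
    b = fasta_bytes({"chrT": 1000}, 7)
    assert a == b
    lines = a.splitlines()
    assert lines[0] == ">chrT"
    assert all(len(l) <= 60 for l in lines[1:])
    assert fasta_bytes({"chrT": 1000}, 8) != a


def test_make_reference_degenerate_single_base():
    seqs = make_reference({"c": 1}, 1)
    assert len(seqs["c"]) == 1 and seqs["c"] in "ACGT"


def test_make_reference_gc_fraction_near_uniform():
    seq = make_reference({"big": 100_000}, 3)["big"]
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    assert 0.45 <= gc <= 0.55


def test_fai_table_matches_layout():
    seqs = {"a": "ACGT" * 40, "b": "A" * 61}
    out = io.StringIO()
    write_fasta(seqs, out)
    lines = fai_table(seqs).splitlines()
    assert lines[0].split("\t")[:2] == ["a", "160"]
    assert lines[1].split("\t")[:2] == ["b", "61"]
    # offsets index into the written FASTA correctly
    text = out.getvalue()
    for name, line in zip(seqs, lines):
        offset = int(line.split("\t")[2])
        assert text[offset] == seqs[name][0]


CONTIGS = {"c1": 4000, "c2": 3000}


def test_simulate_alignments_deterministic():
    plan = AlignmentPlan(n_clean=20, n_softclip=5, n_unmapped=3)

    def render(seed):
        header, records, _ = simulate_alignments(CONTIGS, plan, seed)
        out = io.StringIO()
        write_sam(header, records, out)
        return out.getvalue()

    assert render(11) == render(11)
    assert render(11) != render(12)


def test_simulate_alignments_parses_through_own_reader():
    plan = AlignmentPlan(
        n_clean=10,
        n_softclip=4,
        n_unmapped=2,
        indels=(PlantedIndel("c1", 500, "D", 3, 2),),
    )
    header, records, manifest = simulate_alignments(CONTIGS, plan, 5)
    out = io.StringIO()
    write_sam(header, records, out)
    header2, records2 = read_sam(io.StringIO(out.getvalue()))
    assert len(list(records2)) == len(records) == 18


def test_simulate_alignments_triage_recovery():
    plan = AlignmentPlan(n_clean=15, n_softclip=6, n_unmapped=4)
    _, records, manifest = simulate_alignments(CONTIGS, plan, 21)
    result = triage(records)
    got = sorted(r.query_name for r in result.to_realign)
    planted = sorted(
        manifest.planted["softclip_names"] + manifest.planted["unmapped_names"]
    )
    assert got == planted


def test_simulate_alignments_no_candidates_when_clean():
    plan = AlignmentPlan(n_clean=8)
    _, records, _ = simulate_alignments(CONTIGS, plan, 2)
    assert triage(records).to_realign == []


def test_simulate_alignments_hotspot_recovery():
    planted = PlantedIndel("c1", 105, "D", 2, 2)
    plan = AlignmentPlan(n_clean=10, indels=(planted,))
    _, records, manifest = simulate_alignments(CONTIGS, plan, 9)
    out = collect_hotspots(records, HotspotConfig(padding=0, min_reads=1))
    assert out.intervals == [GenomicInterval("c1", 105, 107)]
    assert manifest.planted["indel_loci"][0]["start"] == 105


def test_simulate_alignments_duplicate_fraction_in_manifest():
    plan = AlignmentPlan(n_clean=100, duplicate_fraction=0.5)
    _, records, manifest = simulate_alignments(CONTIGS, plan, 13)
    flagged = sorted(r.query_name for r in records if r.is_duplicate)
    assert flagged == manifest.planted["duplicate_names"]
    assert len(flagged) == 50


def test_simulate_alignments_rejects_out_of_bounds_indel():
    plan = AlignmentPlan(indels=(PlantedIndel("c1", 3999, "D", 10, 1),))
    with pytest.raises(ValueError):
        simulate_alignments(CONTIGS, plan, 1)
    with pytest.raises(ValueError, match="unknown contig"):
        simulate_alignments(CONTIGS, AlignmentPlan(indels=(PlantedIndel("nope", 5, "D", 1, 1),)), 1)


def test_simulate_vcf_pair_match_structure():
    plan = VcfPairPlan(n_shared=80, n_call_only=20, n_truth_only=20)
    truth, calls, _, manifest = simulate_vcf_pair(plan, 31)
    counts = match_calls(truth, calls, genotype_match=True)["all"]
    assert counts == EvalCounts(80, 20, 20)
    assert manifest.planted["n_shared"] == 80


def test_simulate_vcf_pair_empty_is_valid():
    truth, calls, lengths, _ = simulate_vcf_pair(VcfPairPlan(), 1)
    assert truth == [] and calls == []
    out = io.StringIO()
    write_vcf(truth, out, ["SAMPLE1"], contig_lengths=lengths)
    assert out.getvalue().startswith("##fileformat=VCFv4.2")


def test_simulate_vcf_pair_planted_filter_split():
    plan = VcfPairPlan(n_shared=100, n_low_gq=20, n_low_dp=17)
    _, calls, _, manifest = simulate_vcf_pair(plan, 8)
    outcome = apply_hard_filters(calls, FilterConfig())
    assert outcome.counts == {"pass": 63, "fail": 37}
    assert manifest.planted["n_call_fail"] == 37
    failing = sorted(rec.pos for rec, _ in outcome.failed)
    assert failing == manifest.planted["failing_call_positions"]


def test_simulate_vcf_pair_all_low_gq_passes_nothing():
    plan = VcfPairPlan(n_shared=10, n_low_gq=10)
    _, calls, _, _ = simulate_vcf_pair(plan, 4)
    assert apply_hard_filters(calls, FilterConfig()).counts["pass"] == 0


MIX = MixturePlan(
    counts={"gA": 100, "gB": 10, "gC": 1},
    genome_lengths={"gA": 20_000, "gB": 5_000, "gC": 1_000},
    n_unknown=4,
    n_host=91,
)


def test_mixture_recovers_planted_counts_and_coverage():
    _, records, manifest = simulate_microbial_mixture(MIX, 17)
    hits = summarize_hits(records, MIX.genome_lengths)
    by_id = {h.genome_id: h for h in hits}
    for genome, planted in manifest.planted["per_genome"].items():
        assert by_id[genome].read_count == planted["read_count"]
        assert by_id[genome].covered_bases == planted["covered_bases"]
    assert [h.genome_id for h in top_hits(hits, 3)] == ["gA", "gB", "gC"]


def test_mixture_single_spanning_read():
    plan = MixturePlan(
        counts={"g": 1}, genome_lengths={"g": 1000}, footprints={"g": [(0, 95)]},
        read_length=95,
    )
    _, records, _ = simulate_microbial_mixture(plan, 2)
    (hit,) = summarize_hits(records, {"g": 1000})
    assert hit.covered_bases == 95


def test_mixture_empty_plan():
    _, records, manifest = simulate_microbial_mixture(MixturePlan(), 1)
    assert records == [] and manifest.planted["per_genome"] == {}


def test_screen_inputs_classify_exactly():
    host_header, host_records, _, microbe_records, manifest = simulate_screen_inputs(
        MIX, 23
    )
    host, nonhost = subtract_host(host_records)
    summary = classify_reads(host, nonhost, microbe_records, MIX.genome_lengths)
    assert summary.n_human == 91
    assert summary.n_microbial == 111
    assert summary.n_unknown == 4
    assert summary.n_total == len(host_records)
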