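"""Synthetic fixture generators with machine-readable planted truth.

Every generator is a pure function of (seed, plan): identical inputs
reproduce byte-identical FASTA/SAM/VCF output plus a
:class:`TruthManifest` recording exactly what was planted — indel loci,
soft-clipped/unmapped read names, per-genome microbial read counts and
coverage footprints, shared/call-only/truth-only variant lists and GQ/DP
assignments. Tests read ground truth only from the manifest.

Reads default to 150 bp (a common short-read instrument length); no
sequencing-error or quality model is simulated because no stage here
consumes base qualities.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, TextIO

import numpy as np

from .sam import (
    FLAG_DUP,
    FLAG_UNMAPPED,
    AlignmentRecord,
    CigarOp,
)
from .vcf_io import SampleCall, VariantRecord

__all__ = [
    "TruthManifest",
    "make_reference",
    "write_fasta",
    "fai_table",
    "AlignmentPlan",
    "PlantedIndel",
    "simulate_alignments",
    "VcfPairPlan",
    "simulate_vcf_pair",
    "MixturePlan",
    "simulate_microbial_mixture",
    "simulate_screen_inputs",
]

BASES = np.array(list("ACGT"))
DEFAULT_READ_LENGTH = 150
SAMPLE_NAME = "SAMPLE1"


@dataclass
class TruthManifest:
    """Planted ground truth for one generated fixture set."""

    seed: int
    kind: str
    planted: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        return cls(**json.loads(text))


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


# ---------------------------------------------------------------------------
# reference FASTA


def make_reference(
    contigs: Mapping[str, int], seed: int
) -> dict[str, str]:
    """Uniform-base random contigs; deterministic per (contigs, seed)."""
    rng = _rng(seed)
    out = {}
    for name, length in contigs.items():
        if length < 1:
            raise ValueError(f"contig {name!r} length must be >= 1")
        out[name] = _random_seq(rng, length)
    return out


def write_fasta(seqs: Mapping[str, str], stream: TextIO, width: int = 60) -> None:
    for name, seq in seqs.items():
        stream.write(f">{name}\n")
        for i in range(0, len(seq), width):
            stream.write(seq[i : i + width] + "\n")


def fai_table(seqs: Mapping[str, str], width: int = 60) -> str:
    """faidx-dialect index for a FASTA written by :func:`write_fasta`."""
    lines = []
    offset = 0
    for name, seq in seqs.items():
        offset += len(name) + 2  # ">name\n"
        lines.append(f"{name}\t{len(seq)}\t{offset}\t{width}\t{width + 1}")
        n_lines = -(-len(seq) // width)
        offset += len(seq) + n_lines
    return "\n".join(lines) + "\n"


def sam_header(contig_lengths: Mapping[str, int]) -> list[str]:
    header = ["@HD\tVN:1.6\tSO:unsorted"]
    header += [f"@SQ\tSN:{name}\tLN:{ln}" for name, ln in contig_lengths.items()]
    return header


# ---------------------------------------------------------------------------
# alignment fixtures


@dataclass(frozen=True)
class PlantedIndel:
    """One indel locus: ``kind`` is "I" or "D"; ``pos`` is the 0-based
    reference coordinate of the deletion start / insertion anchor."""

    contig: str
    pos: int
    kind: str
    length: int
    n_reads: int = 1

    def locus(self) -> tuple[str, int, int]:
        if self.kind == "D":
            return (self.contig, self.pos, self.pos + self.length)
        return (self.contig, self.pos, self.pos + 1)


@dataclass
class AlignmentPlan:
    n_clean: int = 0
    n_softclip: int = 0
    n_unmapped: int = 0
    indels: tuple[PlantedIndel, ...] = ()
    duplicate_fraction: float = 0.0
    read_length: int = DEFAULT_READ_LENGTH


def _mapped_record(
    name: str,
    contig: str,
    pos: int,
    cigar: list[CigarOp],
    rng: np.random.Generator,
    flag: int = 0,
) -> AlignmentRecord:
    qlen = sum(l for l, op in cigar if op in "MIS=X")
    return AlignmentRecord(
        query_name=name,
        flag=flag,
        contig=contig,
        pos=pos,
        mapq=60,
        cigar=cigar,
        seq=_random_seq(rng, qlen),
        quals="I" * qlen,
    )


def simulate_alignments(
    contig_lengths: Mapping[str, int],
    plan: AlignmentPlan,
    seed: int,
) -> tuple[list[str], list[AlignmentRecord], TruthManifest]:
    """SAM fixture with planted clean/soft-clipped/unmapped/indel reads.

    Raises ``ValueError`` when a planted indel cannot be spanned by a
    read inside its contig.
    """
    rng = _rng(seed)
    contigs = list(contig_lengths)
    records: list[AlignmentRecord] = []
    L = plan.read_length

    def pick_contig(min_len: int) -> str:
        ok = [c for c in contigs if contig_lengths[c] >= min_len]
        if not ok:
            raise ValueError(f"no contig of length >= {min_len} for a read")
        return ok[int(rng.integers(0, len(ok)))]

    clean_names = []
    for i in range(plan.n_clean):
        name = f"clean{i:04d}"
        contig = pick_contig(L)
        pos = int(rng.integers(0, contig_lengths[contig] - L + 1))
        records.append(_mapped_record(name, contig, pos, [CigarOp(L, "M")], rng))
        clean_names.append(name)

    softclip_names = []
    for i in range(plan.n_softclip):
        name = f"clip{i:04d}"
        contig = pick_contig(L)
        clip = int(rng.integers(5, min(31, L - 1)))
        pos = int(rng.integers(0, contig_lengths[contig] - (L - clip) + 1))
        cigar = [CigarOp(clip, "S"), CigarOp(L - clip, "M")]
        records.append(_mapped_record(name, contig, pos, cigar, rng))
        softclip_names.append(name)

    unmapped_names = []
    for i in range(plan.n_unmapped):
        name = f"unm{i:04d}"
        records.append(
            AlignmentRecord(
                query_name=name,
                flag=FLAG_UNMAPPED,
                seq=_random_seq(rng, L),
                quals="I" * L,
            )
        )
        unmapped_names.append(name)

    indel_read_names: dict[str, list[str]] = {}
    for j, planted in enumerate(plan.indels):
        clen = contig_lengths.get(planted.contig)
        if clen is None:
            raise ValueError(f"planted indel on unknown contig {planted.contig!r}")
        if planted.kind not in "ID":
            raise ValueError(f"indel kind must be I or D, got {planted.kind!r}")
        names = []
        for k in range(planted.n_reads):
            name = f"indel{j:03d}_{k:02d}"
            if planted.kind == "D":
                # query = lead + trail; reference = lead + length + trail
                max_lead = min(L - 1, planted.pos)
                # trail must fit after the deleted span: trail <= clen - pos - len
                min_lead = max(1, L - (clen - planted.pos - planted.length))
                if max_lead < min_lead:
                    raise ValueError(f"indel {planted} does not fit its contig")
                lead = int(rng.integers(min_lead, max_lead + 1))
                trail = L - lead
                pos = planted.pos - lead
                if pos < 0 or planted.pos + planted.length + trail > clen:
                    raise ValueError(f"indel {planted} does not fit its contig")
                cigar = [
                    CigarOp(lead, "M"),
                    CigarOp(planted.length, "D"),
                    CigarOp(trail, "M"),
                ]
            else:
                # query = lead + length + trail; reference = lead + trail
                if planted.length >= L - 1:
                    raise ValueError(f"insertion {planted} longer than the read")
                max_lead = min(L - planted.length - 1, planted.pos)
                min_lead = max(1, L - planted.length - (clen - planted.pos))
                if max_lead < min_lead:
                    raise ValueError(f"indel {planted} does not fit its contig")
                lead = int(rng.integers(min_lead, max_lead + 1))
                trail = L - planted.length - lead
                pos = planted.pos - lead
                if pos < 0 or planted.pos + trail > clen:
                    raise ValueError(f"indel {planted} does not fit its contig")
                cigar = [
                    CigarOp(lead, "M"),
                    CigarOp(planted.length, "I"),
                    CigarOp(trail, "M"),
                ]
            records.append(_mapped_record(name, planted.contig, pos, cigar, rng))
            names.append(name)
        indel_read_names["|".join(map(str, planted.locus()))] = names

    duplicate_names: list[str] = []
    if plan.duplicate_fraction > 0 and clean_names:
        n_dup = int(round(plan.duplicate_fraction * len(clean_names)))
        chosen = rng.choice(len(clean_names), size=n_dup, replace=False)
        chosen_names = {clean_names[i] for i in chosen}
        for rec in records:
            if rec.query_name in chosen_names:
                rec.flag |= FLAG_DUP
        duplicate_names = sorted(chosen_names)

    manifest = TruthManifest(
        seed=seed,
        kind="alignments",
        planted={
            "contig_lengths": dict(contig_lengths),
            "read_length": L,
            "clean_names": clean_names,
            "softclip_names": softclip_names,
            "unmapped_names": unmapped_names,
            "duplicate_names": duplicate_names,
            "indel_loci": [
                {
                    "contig": p.contig,
                    "start": p.locus()[1],
                    "end": p.locus()[2],
                    "kind": p.kind,
                    "length": p.length,
                    "n_reads": p.n_reads,
                }
                for p in plan.indels
            ],
        },
    )
    return sam_header(contig_lengths), records, manifest


# ---------------------------------------------------------------------------
# VCF pair fixtures


@dataclass
class VcfPairPlan:
    """Plan for a (truth, calls) VCF pair with a known match structure.

    ``n_low_gq``/``n_low_dp`` plant that many call records with GQ in
    [0, 19] / DP in [0, 9] (disjoint sets, in call-file order); all other
    records draw GQ in [20, 99] and DP in [10, 60].
    """

    n_shared: int = 0
    n_call_only: int = 0
    n_truth_only: int = 0
    n_low_gq: int = 0
    n_low_dp: int = 0
    indel_fraction: float = 0.25
    contig: str = "chrT"


def _make_site(
    rng: np.random.Generator, contig: str, pos: int, indel: bool
) -> tuple[str, str]:
    ref_base = str(BASES[int(rng.integers(0, 4))])
    if not indel:
        alt = str(BASES[int(rng.integers(0, 4))])
        while alt == ref_base:
            alt = str(BASES[int(rng.integers(0, 4))])
        return ref_base, alt
    extra = _random_seq(rng, int(rng.integers(1, 4)))
    if rng.integers(0, 2):  # insertion
        return ref_base, ref_base + extra
    return ref_base + extra, ref_base


def simulate_vcf_pair(
    plan: VcfPairPlan, seed: int
) -> tuple[list[VariantRecord], list[VariantRecord], dict[str, int], TruthManifest]:
    """Truth and call record lists whose exact match structure is
    (n_shared, n_call_only, n_truth_only) under genotype matching."""
    rng = _rng(seed)
    total = plan.n_shared + plan.n_call_only + plan.n_truth_only
    contig_len = 10 * (total + 2) + 100

    sites = []
    for i in range(total):
        pos = 10 * (i + 1)  # spaced so trimming can never collide sites
        indel = bool(rng.random() < plan.indel_fraction)
        ref, alt = _make_site(rng, plan.contig, pos, indel)
        gt = (0, 1) if rng.integers(0, 2) else (1, 1)
        sites.append((pos, ref, alt, gt))

    def rec(pos, ref, alt, gt, gq, dp):
        return VariantRecord(
            contig=plan.contig,
            pos=pos,
            ref=ref,
            alts=(alt,),
            qual=100.0,
            samples={SAMPLE_NAME: SampleCall(gt=gt, gq=gq, dp=dp)},
        )

    def pass_gq():
        return int(rng.integers(20, 100))

    def pass_dp():
        return int(rng.integers(10, 61))

    shared = sites[: plan.n_shared]
    call_only = sites[plan.n_shared : plan.n_shared + plan.n_call_only]
    truth_only = sites[plan.n_shared + plan.n_call_only :]

    truth_records = [
        rec(pos, ref, alt, gt, pass_gq(), pass_dp())
        for pos, ref, alt, gt in shared + truth_only
    ]
    call_sites = shared + call_only
    n_fail = plan.n_low_gq + plan.n_low_dp
    if n_fail > len(call_sites):
        raise ValueError("more planted failures than call records")
    call_records = []
    failing_positions = []
    for i, (pos, ref, alt, gt) in enumerate(call_sites):
        if i < plan.n_low_gq:
            gq, dp = int(rng.integers(0, 20)), pass_dp()
            failing_positions.append(pos)
        elif i < n_fail:
            gq, dp = pass_gq(), int(rng.integers(0, 10))
            failing_positions.append(pos)
        else:
            gq, dp = pass_gq(), pass_dp()
        call_records.append(rec(pos, ref, alt, gt, gq, dp))
    truth_records.sort(key=lambda r: r.pos)
    call_records.sort(key=lambda r: r.pos)

    manifest = TruthManifest(
        seed=seed,
        kind="vcf_pair",
        planted={
            "contig_lengths": {plan.contig: contig_len},
            "n_shared": plan.n_shared,
            "n_call_only": plan.n_call_only,
            "n_truth_only": plan.n_truth_only,
            "shared": [[plan.contig, p, r, a] for p, r, a, _ in shared],
            "call_only": [[plan.contig, p, r, a] for p, r, a, _ in call_only],
            "truth_only": [[plan.contig, p, r, a] for p, r, a, _ in truth_only],
            "failing_call_positions": sorted(failing_positions),
            "n_call_pass": len(call_sites) - n_fail,
            "n_call_fail": n_fail,
        },
    )
    return truth_records, call_records, {plan.contig: contig_len}, manifest


# ---------------------------------------------------------------------------
# microbial mixture fixtures


@dataclass
class MixturePlan:
    """Planted per-genome read counts and coverage footprints.

    ``footprints`` maps genome -> non-overlapping [start, end) spans to
    cover exactly; when omitted for a genome, a single span from 0 sized
    to need at most ``counts[genome]`` reads is used. ``n_unknown`` adds
    reads mapping to no genome; ``n_host`` (used by
    :func:`simulate_screen_inputs`) adds host-mapped reads.
    """

    counts: dict[str, int] = field(default_factory=dict)
    genome_lengths: dict[str, int] = field(default_factory=dict)
    footprints: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    n_unknown: int = 0
    n_host: int = 0
    read_length: int = DEFAULT_READ_LENGTH


def _footprint_tiles(
    span: tuple[int, int], read_length: int
) -> list[tuple[int, int]]:
    start, end = span
    tiles = []
    while start < end:
        tiles.append((start, min(start + read_length, end)))
        start += read_length
    return tiles


def simulate_microbial_mixture(
    plan: MixturePlan, seed: int
) -> tuple[list[str], list[AlignmentRecord], TruthManifest]:
    """Non-host SAM whose per-genome read counts and covered bases are
    exactly the planted values (footprints are tiled without overlap
    ambiguity)."""
    rng = _rng(seed)
    records: list[AlignmentRecord] = []
    per_genome: dict[str, dict[str, int]] = {}
    for genome in sorted(plan.counts):
        n_reads = plan.counts[genome]
        length = plan.genome_lengths.get(genome)
        if length is None:
            raise ValueError(f"genome {genome!r} missing from genome_lengths")
        spans = plan.footprints.get(genome)
        if spans is None:
            spans = [(0, min(length, n_reads * plan.read_length))]
        spans = sorted(spans)
        for (s0, e0), (s1, _e1) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping footprints for {genome!r}")
        if spans and spans[-1][1] > length:
            raise ValueError(f"footprint beyond genome end for {genome!r}")
        tiles = [t for span in spans for t in _footprint_tiles(span, plan.read_length)]
        if n_reads < len(tiles):
            raise ValueError(
                f"{genome!r}: {n_reads} reads cannot tile {len(tiles)} footprint chunks"
            )
        for k in range(n_reads):
            s, e = tiles[k % len(tiles)] if tiles else (0, 0)
            if e <= s:
                raise ValueError(f"{genome!r}: empty footprint with planted reads")
            records.append(
                _mapped_record(
                    f"{genome}_r{k:05d}",
                    genome,
                    s,
                    [CigarOp(e - s, "M")],
                    rng,
                )
            )
        per_genome[genome] = {
            "read_count": n_reads,
            "covered_bases": sum(e - s for s, e in spans),
        }
    unknown_names = []
    for i in range(plan.n_unknown):
        name = f"unknown{i:05d}"
        records.append(
            AlignmentRecord(
                query_name=name,
                flag=FLAG_UNMAPPED,
                seq=_random_seq(rng, plan.read_length),
                quals="I" * plan.read_length,
            )
        )
        unknown_names.append(name)
    manifest = TruthManifest(
        seed=seed,
        kind="microbial_mixture",
        planted={
            "genome_lengths": {g: plan.genome_lengths[g] for g in sorted(plan.counts)},
            "per_genome": per_genome,
            "unknown_names": unknown_names,
            "n_unknown": plan.n_unknown,
            "n_host": plan.n_host,
        },
    )
    header = sam_header({g: plan.genome_lengths[g] for g in sorted(plan.counts)})
    return header, records, manifest


HOST_CONTIG = "chrH"
HOST_CONTIG_LENGTH = 100_000


def simulate_screen_inputs(
    plan: MixturePlan, seed: int
) -> tuple[
    list[str],
    list[AlignmentRecord],
    list[str],
    list[AlignmentRecord],
    TruthManifest,
]:
    """Host-pass and microbe-pass SAM streams over one read universe.

    The host pass maps ``plan.n_host`` reads to a synthetic host contig
    and carries every non-host read (planted microbial + unknown) as an
    unmapped record, exactly as a subtraction alignment would.
    Returns (host_header, host_records, microbe_header, microbe_records,
    manifest).
    """
    microbe_header, microbe_records, manifest = simulate_microbial_mixture(plan, seed)
    rng = _rng(seed + 1)
    L = min(plan.read_length, HOST_CONTIG_LENGTH)
    host_records: list[AlignmentRecord] = []
    host_names = []
    for i in range(plan.n_host):
        name = f"host{i:06d}"
        pos = int(rng.integers(0, HOST_CONTIG_LENGTH - L + 1))
        host_records.append(
            _mapped_record(name, HOST_CONTIG, pos, [CigarOp(L, "M")], rng)
        )
        host_names.append(name)
    for rec in microbe_records:
        host_records.append(
            AlignmentRecord(
                query_name=rec.query_name,
                flag=FLAG_UNMAPPED,
                seq=rec.seq,
                quals=rec.quals,
            )
        )
    manifest.planted["host_names"] = host_names
    host_header = sam_header({HOST_CONTIG: HOST_CONTIG_LENGTH})
    return host_header, host_records, microbe_header, microbe_records, manifest
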