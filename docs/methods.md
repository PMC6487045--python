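# Methods

This note documents the models, conventions and design choices behind
`readkit`'s five analysis stages, what the synthetic fixtures do and do not
emulate, and the package's known limitations.

## Coordinates and record semantics

All interval arithmetic is 0-based half-open; SAM's 1-based `POS` and VCF's
1-based positions are converted at the I/O boundary, so internal coordinates
match BED natively. CIGAR semantics follow the SAM specification: `M`, `=`,
`X`, `D`, `N` consume reference; `M`, `=`, `X`, `I`, `S` consume query; `H`
and `P` consume neither. An unmapped record's CIGAR is treated as absent for
all reference arithmetic. Records are processed streaming in a single pass —
no index (BAI/CSI) is ever assumed, which keeps every operation valid on
plain SAM text. Secondary and supplementary records never carry primary
evidence: they pass through triage untouched, are skipped in hotspot
counting, and carry no verdict in the screen.

## Alignment triage

A record needs realignment if it is unmapped, or mapped with any soft-clip
run of at least `min_clip` bases. `min_clip` defaults to 1 — the most literal
reading of "realign soft-clipped reads" — and is exposed as a flag because
larger thresholds (e.g. 10) suppress realignment of trivially clipped reads.
Hard clips never trigger selection: the clipped bases are not present in the
record, so there is nothing to realign. Selected records are emitted with
alignment fields cleared and, when the reverse flag was set, with SEQ
reverse-complemented (and quality string reversed) back to the instrument
orientation, so the downstream aligner sees the original read. Duplicate-
flagged records are not re-examined.

The realignment itself is deliberately out of process: the module writes a
FASTQ (or unaligned-SAM) hand-off and consumes whatever alignments come
back. `merge_refined` enforces that each (query_name, segment) appears as a
primary record in exactly one input, then sorts by (contig, position,
query_name) with unmapped records in a trailing block; the query-name
tie-break makes the order deterministic. Only the selected records are
re-extracted — mates of selected reads are not pulled in for paired
realignment. That alternative would give a paired-end aligner more signal at
the cost of re-aligning reads whose placement was fine; with the hand-off
interface either policy can be layered on top.

## Indel hotspot targeting

The intensive-mode targeting step walks each primary mapped read's CIGAR
with a reference cursor. A deletion of length *L* at cursor *c* contributes
its full span *[c, c+L)* — a multi-base event should expose its whole extent
to a windowed caller. An insertion, which lives between two reference bases,
is anchored to the single base immediately following the insertion point,
*[c, c+1)*: the minimal, caller-friendly convention for a between-base
event. Within one read, evidenced bases are de-duplicated before counting,
so adjacent ops cannot let a single read satisfy a 2-read threshold.

Per-base evidence counts are thresholded at `min_reads` (default 1: "at
least one read"), padded by `padding` bases per side (default 10 — local
reassembly callers need flanking context; clamped at 0 and at the contig
length when `@SQ` lengths are available) and merged into a sorted,
non-overlapping BED. Duplicate-flagged reads are excluded by default because
the downstream callers are duplicate-aware and the targeting evidence should
match what they will see; `N` ops are excluded by default because in DNA
data a reference skip is a spliced-alignment artifact, not deletion
evidence. Both exclusions are flags.

The implementation is checked against a brute-force per-base pileup oracle
(an integer array per contig, each read walked independently) for exact set
equality, and against planted-truth fixtures for exact recovery.

## Variant hard-filtering

The filter rule is read literally from its source phrasing — *calls with
genotype quality smaller than 20 and depth smaller than 10 are discarded* —
so the pass condition is GQ ≥ `min_gq` AND DP ≥ `min_dp`, and the boundary
values GQ = 20, DP = 10 pass. Missing GQ or DP fails by default
(conservative for diagnostic use) with distinct reason tags
(`missing_gq`/`missing_dp` vs `low_gq`/`low_dp`); `missing_fails=False`
relaxes this. Filtering evaluates the first sample column unless a sample
name is given. Failed records are dropped by default; `--keep-failed`
writes them with `lowGQ`/`lowDP` FILTER tags instead, for auditability.

Variant classes: SNV iff both alleles are a single base; small indel iff the
allele lengths differ and the longer allele is ≤ 50 bp — 50 bp itself is
unassigned by the usual "< 50 bp small / > 50 bp structural" convention, and
is assigned to *small* here; everything else (symbolic alleles, breakends,
longer events, MNPs) is `sv_like` and outside the scope of these filters.
Only the GQ and DP filters are contracted; `FilterConfig` is the extension
point for additional hard filters.

## Microbe screen

Computational subtraction uses two alignment passes over one read universe.
Each (read, segment) — mates are independent units — is *human* iff its
primary host-pass record is mapped; *microbial* iff non-host and
primary-mapped to at least one database genome; *unknown* otherwise. The
partition is validated on every run (a read claimed as both host and
microbial is an input inconsistency and raises).

Per-genome `read_count` counts distinct (read, segment) whose **primary**
alignment maps to that genome — this avoids double-counting multi-mappers;
`--count-secondary` switches to the permissive reading in which every genome
a read aligns to is credited. Breadth of coverage always uses primary
alignments only and counts a base as covered only when an `M`/`=`/`X`
segment spans it: bases under a `D` or `N` gap inside an alignment are not
aligned bases. Breadth is checked against a per-base boolean-array oracle in
the tests. The genome database is whatever FASTA/length-table the user
supplies (viral, bacterial, custom); a two-column TSV and the `.fai` dialect
are both accepted since their first two columns coincide.

## Benchmarking

Both record sets are normalized first: multiallelic sites are split one alt
per record (genotype indices for other alts collapse to 0, since the split
record no longer represents them), symbolic alts are excluded with a tally,
and alleles are trimmed — shared trailing bases first, then shared leading
bases advancing the position, always keeping at least one base on each side
— which left-anchors the representation deterministically and idempotently.

Matching is exact on (contig, pos, ref, alt), plus the unphased genotype
when genotype matching is on (the default, matching the usual behaviour of
genotype-aware comparison tools). Each truth record matches at most one call
and vice versa. Unmatched calls are Fp (classed from the call record),
unmatched truth records Fn (classed from the truth record). This is **not**
a haplotype-aware comparison: two different-but-equivalent multi-record
representations of the same haplotype will not pair, so metrics here can be
slightly pessimistic relative to a haplotype-resolving engine such as RTG
vcfeval. Re-implementing that engine is out of scope; the exact matcher is
the documented approximation.

Metrics are the standard Precision = Tp/(Tp+Fp), Sensitivity = Tp/(Tp+Fn),
and their harmonic mean F = 2PS/(P+S). Any zero denominator makes that
metric undefined — reported `NA`, never 0, because a 0 would misrank
degenerate call sets — and F is undefined unless both P and S are defined
with P+S > 0.

## Modes

The three-speed configuration is represented as stage toggles: fast =
{triage off, hotspots off}, normal = {triage on, hotspots off}, intensive =
{triage on, hotspots on}; the microbe screen is available in every mode.
Aligner/caller identities per mode are an orchestration concern of the
surrounding pipeline and are represented here only by the hand-off files
(FASTQ/SAM/BED/VCF) between stages. Explicit per-stage flags override the
mode defaults and the resolved configuration is echoed, so a run's effective
toggles are always auditable.

## Synthetic fixtures

The generators are pure functions of (seed, plan): byte-identical outputs
for identical inputs, with every planted feature recorded in a JSON truth
manifest — tests and the acceptance script read ground truth only from
manifests. Reads are 150 bp by default (a common short-read instrument
length), single-end, error-free, with uniform random bases and constant
quality: no sequencing-error, quality, GC-bias or duplicate-tower model is
included, because no in-scope stage consumes base qualities or error
profiles. Planted indel reads spell their event exactly once at the planned
locus; mixture reads tile their coverage footprints without overlap
ambiguity so planted breadth is exact. Consequently, passing tests
demonstrate the *logic* of selection, targeting, filtering, screening and
scoring — not robustness to alignment noise, mapping ambiguity or error-rich
data, which enter only through the external aligners this package
deliberately does not run.

Problem sizes in the tests and the acceptance script (hundreds of reads,
10 kb contigs, 100 kb genomes, ~100-record call sets, a 10,000-read screen
universe) were chosen as the smallest scales at which every contract —
oracle equality, planted recovery, partition conservation — is exercised
meaningfully; all quantities they compute are scale-free (fractions, exact
counts of planted features).

## Numerical and degenerate-input choices

Interval merging joins abutting intervals at gap 0, producing the minimal
representation of a base set; merging is idempotent and order-insensitive.
Empty inputs yield empty outputs everywhere (empty VCFs keep valid headers;
the screen reports all-zero classes without division errors). Hotspot
padding clamps at contig bounds. Ranking ties in the screen break
lexicographically by genome id. Gene-name region lookup is case-insensitive
exact matching against a user-supplied annotation BED (column 4 = symbol);
unmatched names produce a warning and an empty contribution rather than an
error — the whole-exome option is the same path with an exome BED. No gene
model or reference data is bundled.

## Known limitations

- Exact-allele benchmarking understates concordance for complex/MNP
  representations (see above).
- The screen attributes multi-mapped reads by primary alignment; with
  `--count-secondary` a read can legitimately count toward several genomes,
  and neither mode resolves taxonomy.
- BAM/CRAM are not parsed natively; convert to SAM text at the boundary.
- Paired-end structure is carried through (segments, flags) but mates are
  not co-selected at triage and insert-size information is unused.
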