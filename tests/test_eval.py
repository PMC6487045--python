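"""Variant-call benchmarking: normalization, matching, metric formulas."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from readkit.evaluate import (
    EvalCounts,
    compute_metrics,
    match_calls,
    normalize_variant,
)
from readkit.regions import GenomicInterval, RegionSet
from readkit.vcf_io import SampleCall, VariantRecord


def var(pos=100, ref="A", alts=("G",), gt=(0, 1), contig="chr1"):
    return VariantRecord(
        contig=contig,
        pos=pos,
        ref=ref,
        alts=tuple(alts),
        samples={"S": SampleCall(gt=gt)},
    )


def test_normalize_trims_shared_bases():
    (out,), n_sym = normalize_variant(var(pos=100, ref="ATT", alts=("AT",)))
    assert (out.pos, out.ref, out.alts) == (100, "AT", ("A",))
    assert n_sym == 0


def test_normalize_left_anchors_trailing_context():
    (out,), _ = normalize_variant(var(pos=100, ref="CAT", alts=("CGT",)))
    assert (out.pos, out.ref, out.alts) == (101, "A", ("G",))


def test_normalize_splits_multiallelic_and_remaps_genotypes():
    out, _ = normalize_variant(var(ref="A", alts=("G", "T"), gt=(1, 2)))
    assert [(r.alts, r.samples["S"].gt) for r in out] == [
        (("G",), (1, 0)),
        (("T",), (0, 1)),
    ]


def test_normalize_excludes_symbolic_alts():
    out, n_sym = normalize_variant(var(ref="A", alts=("<DEL>", "G")))
    assert len(out) == 1 and out[0].alts == ("G",)
    assert n_sym == 1


def test_normalize_is_idempotent():
    (once,), _ = normalize_variant(var(pos=50, ref="GCC", alts=("GC",)))
    (twice,), _ = normalize_variant(once)
    assert (twice.pos, twice.ref, twice.alts) == (once.pos, once.ref, once.alts)


def test_match_identity_and_allele_mismatch():
    assert match_calls([var()], [var()])["all"] == EvalCounts(1, 0, 0)
    counts = match_calls([var(alts=("G",))], [var(alts=("T",))])["all"]
    assert counts == EvalCounts(0, 1, 1)


def test_match_respects_genotype_mode():
    truth = [var(gt=(1, 1))]
    calls = [var(gt=(0, 1))]
    assert match_calls(truth, calls, genotype_match=True)["all"] == EvalCounts(0, 1, 1)
    assert match_calls(truth, calls, genotype_match=False)["all"] == EvalCounts(1, 0, 0)


def test_match_equivalent_representations_pair_after_normalization():
    truth = [var(pos=100, ref="ATT", alts=("AT",))]
    calls = [var(pos=100, ref="AT", alts=("A",))]
    assert match_calls(truth, calls)["all"] == EvalCounts(1, 0, 0)


def test_match_stratifies_by_class():
    truth = [var(pos=10, ref="A", alts=("G",)), var(pos=20, ref="AT", alts=("A",))]
    calls = [var(pos=10, ref="A", alts=("G",)), var(pos=30, ref="C", alts=("CA",))]
    counts = match_calls(truth, calls)
    assert counts["snv"] == EvalCounts(1, 0, 0)
    assert counts["small_indel"] == EvalCounts(0, 1, 1)
    assert counts["all"] == EvalCounts(1, 1, 1)


def test_match_swap_symmetry():
    truth = [var(pos=p) for p in (10, 20, 30)]
    calls = [var(pos=p) for p in (20, 30, 40, 50)]
    fwd = match_calls(truth, calls)["all"]
    rev = match_calls(calls, truth)["all"]
    assert (fwd.tp, fwd.fp, fwd.fn) == (rev.tp, rev.fn, rev.fp)


def test_match_region_restriction_commutes():
    regions = RegionSet([GenomicInterval("chr1", 0, 25)])
    truth = [var(pos=10), var(pos=30)]
    calls = [var(pos=10), var(pos=20), var(pos=30)]
    restricted = match_calls(truth, calls, regions=regions)["all"]
    assert restricted == EvalCounts(1, 1, 0)


@pytest.mark.parametrize(
    "counts, precision, sensitivity, f_measure",
    [
        (EvalCounts(8, 2, 2), 0.8, 0.8, 0.8),
        (EvalCounts(9, 1, 3), 0.9, 0.75, 2 * 0.9 * 0.75 / 1.65),
        (EvalCounts(0, 0, 5), None, 0.0, None),
        (EvalCounts(0, 5, 0), 0.0, None, None),
        (EvalCounts(0, 0, 0), None, None, None),
        (EvalCounts(0, 3, 4), 0.0, 0.0, None),
    ],
)
def test_compute_metrics(counts, precision, sensitivity, f_measure):
    m = compute_metrics(counts)
    assert m.precision == pytest.approx(precision) if precision is not None else m.precision is None
    assert m.sensitivity == pytest.approx(sensitivity) if sensitivity is not None else m.sensitivity is None
    if f_measure is None:
        assert m.f_measure is None
    else:
        assert m.f_measure == pytest.approx(f_measure)


@given(
    st.integers(min_value=0, max_value=10_000),
    st.integers(min_value=0, max_value=10_000),
    st.integers(min_value=0, max_value=10_000),
)
def test_metrics_harmonic_mean_identity(tp, fp, fn):
    """F * (P + S) == 2 P S and F lies between harmonic-mean bounds."""
    m = compute_metrics(EvalCounts(tp, fp, fn))
    if m.precision is not None and m.sensitivity is not None and m.f_measure is not None:
        p, s, f = m.precision, m.sensitivity, m.f_measure
        assert abs(f * (p + s) - 2 * p * s) < 1e-12
        assert 0.0 <= f <= max(p, s) + 1e-12
        assert f <= min(2 * p, 2 * s) + 1e-12
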