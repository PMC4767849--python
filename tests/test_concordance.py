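"""Variant matching, normalization and derived statistics.

The normalization oracle is an independent string-diff implementation: apply
the variant to a reference window, trim the common suffix then prefix of the
two window strings, and re-anchor indels on the preceding base.  The
classification oracle is an exhaustive per-key matcher.
"""

import math
import random

import pytest

from panelqc.concordance import (
    ConfusionCounts,
    UndefinedStatistic,
    VariantCall,
    classify_calls,
    filter_by_quality,
    mcc,
    normalize_variant,
    precision,
    read_vcf,
    reference_from_fasta,
    sensitivity,
    ts_tv,
)
from panelqc.intervals import EvaluationRegion, GenomicInterval
from panelqc.simulate import write_vcf


def oracle_normalize(call, seq):
    """String-diff normalization over a window (independent oracle)."""
    w0 = max(0, call.pos - 1 - 50)
    w1 = min(len(seq), call.pos - 1 + len(call.ref) + 50)
    refwin = seq[w0: w1]
    hap = seq[w0: call.pos - 1] + call.alt + seq[call.pos - 1 + len(call.ref): w1]
    # trim common suffix
    i, j = len(refwin), len(hap)
    while i > 0 and j > 0 and refwin[i - 1] == hap[j - 1]:
        i, j = i - 1, j - 1
    # trim common prefix
    k = 0
    while k < min(i, j) and refwin[k] == hap[k]:
        k += 1
    ref_block, alt_block = refwin[k:i], hap[k:j]
    pos0 = w0 + k
    if not ref_block or not alt_block:  # indel: anchor on preceding base
        pos0 -= 1
        ref_block = seq[pos0] + ref_block
        alt_block = seq[pos0] + alt_block
    return (call.chrom, pos0 + 1, ref_block, alt_block)


@pytest.fixture
def ref():
    random.seed(4)
    seq = "ACGTA" + "".join(random.choice("ACGT") for _ in range(200)) + "CAAAAATG"
    return {"chr1": seq}


class TestNormalize:
    def test_snv_unchanged(self, ref):
        acc = reference_from_fasta(ref)
        base = ref["chr1"][9]
        alt = "A" if base != "A" else "C"
        v = VariantCall("chr1", 10, base, alt)
        assert normalize_variant(v, acc).key == v.key

    def test_deletion_left_aligns_through_homopolymer(self):
        # reference ...ACAAAT...: any single-A deletion in the run left-aligns
        # to the CA>C representation anchored on the C
        seq = "GGACAAATGG"
        acc = reference_from_fasta({"chr1": seq})
        for pos in (4, 5, 6):  # anchor base, deleting the A that follows it
            v = VariantCall("chr1", pos, seq[pos - 1: pos + 1], seq[pos - 1])
            got = normalize_variant(v, acc)
            assert (got.pos, got.ref, got.alt) == (4, "CA", "C")

    def test_ref_mismatch_raises(self, ref):
        acc = reference_from_fasta(ref)
        base = ref["chr1"][9]
        wrong = "G" if base != "G" else "T"
        with pytest.raises(ValueError, match="REF mismatch"):
            normalize_variant(VariantCall("chr1", 10, wrong, base), acc)

    def test_matches_string_diff_oracle_and_is_idempotent(self, ref):
        acc = reference_from_fasta(ref)
        seq = ref["chr1"]
        rng = random.Random(9)
        for _ in range(300):
            pos0 = rng.randrange(20, len(seq) - 30)
            kind = rng.choice(["snv", "del", "ins", "messy"])
            if kind == "snv":
                alt = rng.choice([b for b in "ACGT" if b != seq[pos0]])
                v = VariantCall("chr1", pos0 + 1, seq[pos0], alt)
            elif kind == "del":
                n = rng.randrange(1, 6)
                v = VariantCall("chr1", pos0 + 1, seq[pos0: pos0 + 1 + n], seq[pos0])
            elif kind == "ins":
                ins = "".join(rng.choice("ACGT") for _ in range(rng.randrange(1, 6)))
                v = VariantCall("chr1", pos0 + 1, seq[pos0], seq[pos0] + ins)
            else:  # shared context on both sides of an indel
                n = rng.randrange(1, 4)
                pad = seq[pos0 + 1 + n: pos0 + 1 + n + 2]
                v = VariantCall(
                    "chr1", pos0 + 1, seq[pos0: pos0 + 1 + n] + pad, seq[pos0] + pad
                )
            got = normalize_variant(v, acc)
            assert got.key == oracle_normalize(v, seq)
            assert normalize_variant(got, acc).key == got.key  # idempotent


def region_100():
    return EvaluationRegion.from_intervals([GenomicInterval("chr1", 0, 100)])


class TestClassify:
    def test_single_shared_snv(self):
        v = VariantCall("chr1", 10, "A", "G")
        counts = classify_calls([v], [v], region_100())
        assert counts["SNV"] == ConfusionCounts(tp=1, fp=0, fn=0, tn=99)

    def test_multiallelic_rejected(self):
        with pytest.raises(ValueError, match="multiallelic"):
            VariantCall("chr1", 10, "A", "G,C")

    def test_calls_outside_region_ignored(self):
        inside = VariantCall("chr1", 10, "A", "G")
        outside = VariantCall("chr1", 500, "A", "G")
        counts = classify_calls([inside, outside], [inside], region_100())
        assert counts["SNV"].fp == 0

    def test_swap_exchanges_fp_fn_and_keeps_mcc(self):
        shared = [VariantCall("chr1", p, "A", "G") for p in (10, 20, 30)]
        q_only = [VariantCall("chr1", 40, "C", "T")]
        t_only = [VariantCall("chr1", 50, "G", "A"), VariantCall("chr1", 60, "T", "C")]
        region = region_100()
        fwd = classify_calls(shared + q_only, shared + t_only, region)["all"]
        rev = classify_calls(shared + t_only, shared + q_only, region)["all"]
        assert (fwd.fp, fwd.fn) == (rev.fn, rev.fp)
        assert fwd.tn == rev.tn
        assert sensitivity(fwd) == precision(rev)
        assert mcc(fwd) == pytest.approx(mcc(rev))

    def test_agrees_with_brute_force_matcher_on_random_instances(self):
        rng = random.Random(13)
        region = EvaluationRegion.from_intervals([GenomicInterval("chr1", 0, 10_000)])
        for _ in range(25):
            positions = rng.sample(range(20, 9900, 15), k=rng.randrange(5, 60))
            calls = []
            for p in positions:
                if rng.random() < 0.7:
                    calls.append(VariantCall("chr1", p, "A", rng.choice("CGT")))
                else:
                    calls.append(VariantCall("chr1", p, "AC", "A"))
            rng.shuffle(calls)
            cut_q, cut_t = rng.randrange(len(calls)), rng.randrange(len(calls))
            query, truth = calls[cut_q:], calls[:cut_t]
            counts = classify_calls(query, truth, region)
            qk, tk = {c.key for c in query}, {c.key for c in truth}
            for cls in ("SNV", "indel", "all"):
                def ok(c):
                    return cls == "all" or c.variant_class == cls
                tp = sum(1 for c in truth if ok(c) and c.key in qk)
                fn = sum(1 for c in truth if ok(c) and c.key not in qk)
                fp = sum(1 for c in query if ok(c) and c.key not in tk)
                occupied = sum(
                    len(c.ref) for c in calls if ok(c) and (c.key in qk or c.key in tk)
                )
                got = counts[cls]
                assert (got.tp, got.fp, got.fn) == (tp, fp, fn)
                assert got.tn == region.total_bp - occupied
                # conservation: tp+fn = truth sites, tp+fp = query sites
                assert got.tp + got.fn == sum(1 for c in truth if ok(c))
                assert got.tp + got.fp == sum(1 for c in query if ok(c))

    def test_perfect_agreement_gives_100_everywhere(self):
        calls = [VariantCall("chr1", 10, "A", "G"), VariantCall("chr1", 30, "CT", "C")]
        counts = classify_calls(calls, calls, region_100())
        for cls in ("SNV", "indel", "all"):
            c = counts[cls]
            assert sensitivity(c) == precision(c) == 100.0
            assert mcc(c) == pytest.approx(100.0)

    def test_unnormalized_input_rejected_when_reference_given(self):
        seq = "GGACAAATGG" + "A" * 90
        acc = reference_from_fasta({"chr1": seq})
        not_norm = VariantCall("chr1", 6, "AA", "A")  # shifts left to CA>C
        with pytest.raises(ValueError, match="not normalized"):
            classify_calls([not_norm], [not_norm], region_100(), reference=acc)


class TestStatistics:
    """Derived statistics at the published benchmark's printed counts."""

    def test_sensitivity_cells(self):
        assert sensitivity(ConfusionCounts(tp=249, fn=1)) == pytest.approx(99.6, abs=0.05)
        assert sensitivity(ConfusionCounts(tp=4, fn=1)) == pytest.approx(80.0)
        assert sensitivity(ConfusionCounts(tp=0, fn=5)) == 0.0
        with pytest.raises(UndefinedStatistic):
            sensitivity(ConfusionCounts(tp=0, fn=0, fp=3, tn=10))

    def test_precision_cells(self):
        assert precision(ConfusionCounts(tp=245, fp=1)) == pytest.approx(99.6, abs=0.05)
        assert precision(ConfusionCounts(tp=249, fp=0)) == 100.0
        assert precision(ConfusionCounts(tp=0, fp=3)) == 0.0
        with pytest.raises(UndefinedStatistic):
            precision(ConfusionCounts(tp=0, fp=0, fn=3, tn=10))

    def test_mcc_cells(self):
        assert mcc(ConfusionCounts(4, 0, 1, 522754)) == pytest.approx(89.4, abs=0.05)
        assert mcc(ConfusionCounts(245, 0, 0, 522518)) == pytest.approx(100.0)
        assert mcc(ConfusionCounts(249, 1, 1, 522508)) == pytest.approx(99.6, abs=0.05)
        with pytest.raises(UndefinedStatistic):
            mcc(ConfusionCounts(tp=0, fp=0, fn=1, tn=10))

    def test_mcc_integer_path_matches_float_reference(self):
        cases = [
            (249, 0, 1, 522509), (245, 0, 0, 522518), (4, 0, 1, 522754),
            (245, 1, 0, 522517), (249, 1, 1, 522508), (7, 3, 2, 991),
        ]
        for tp, fp, fn, tn in cases:
            got = mcc(ConfusionCounts(tp, fp, fn, tn))
            want = 100.0 * (tp * tn - fp * fn) / math.sqrt(
                float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
            )
            assert got == pytest.approx(want, rel=1e-6)


class TestTsTv:
    def test_basic_ratio(self):
        calls = [
            VariantCall("chr1", 1, "A", "G"),
            VariantCall("chr1", 2, "C", "T"),
            VariantCall("chr1", 3, "A", "C"),
        ]
        assert ts_tv(calls) == pytest.approx(2.0)

    def test_all_transitions_is_undefined(self):
        calls = [VariantCall("chr1", 1, "A", "G")]
        with pytest.raises(UndefinedStatistic):
            ts_tv(calls)

    def test_non_snvs_ignored(self):
        calls = [VariantCall("chr1", 1, "A", "G"), VariantCall("chr1", 5, "AT", "A"),
                 VariantCall("chr1", 9, "G", "T")]
        assert ts_tv(calls) == pytest.approx(1.0)


class TestQualityFilter:
    def test_qd_threshold_boundary(self):
        passing_call = VariantCall("chr1", 1, "A", "G", {"QD": 2.1})
        failing_call = VariantCall("chr1", 2, "A", "G", {"QD": 1.9})
        passing, failing = filter_by_quality([passing_call, failing_call], "QD", 2.0)
        assert passing == [passing_call] and failing == [failing_call]

    def test_partition_conserves_and_missing_policy(self):
        rng = random.Random(2)
        calls = [
            VariantCall("chr1", p, "A", "G", {"QD": rng.uniform(0, 5)} if rng.random() < 0.8 else {})
            for p in range(1, 40)
        ]
        passing, failing = filter_by_quality(calls, "QD", 2.0)
        assert len(passing) + len(failing) == len(calls)
        lax_pass, _ = filter_by_quality(calls, "QD", 2.0, missing_fails=False)
        n_missing = sum(1 for c in calls if "QD" not in c.annotations)
        assert len(lax_pass) == len(passing) + n_missing


class TestVcfIO:
    def test_round_trip_and_filtered_exclusion(self, tmp_path, ref):
        calls = [
            VariantCall("chr1", 10, ref["chr1"][9], "A" if ref["chr1"][9] != "A" else "C",
                        {"QD": 12.5}),
            VariantCall("chr1", 30, ref["chr1"][29], "T" if ref["chr1"][29] != "T" else "G"),
        ]
        dropped = VariantCall("chr1", 50, ref["chr1"][49],
                              "G" if ref["chr1"][49] != "G" else "A", {"QD": 1.5})
        path = tmp_path / "calls.vcf"
        write_vcf(calls, ref, path, filtered_calls=[(dropped, "lowQD")])
        default = read_vcf(path)
        assert [c.key for c in default] == [c.key for c in calls]
        assert default[0].annotations["QD"] == pytest.approx(12.5)
        everything = read_vcf(path, include_filtered=True)
        assert len(everything) == 3

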