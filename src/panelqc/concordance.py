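"""Variant-call concordance against a high-confidence truth set.

Query calls are matched to truth calls by exact normalized
(chrom, pos, ref, alt) identity inside an evaluation region, and classified
into TP (in both), FP (query only) and FN (truth only).  TN is a base count:
evaluation-region bases occupied by no variant site of the class under
consideration.  From the confusion counts the module derives sensitivity
TP/(TP+FN), precision TP/(TP+FP) and the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

which stays informative under the extreme class imbalance of per-base
evaluation (a few hundred variant sites against ~5e5 reference bases).
Genotype concordance is not evaluated; matching is allele-level only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Literal, Sequence

from .intervals import EvaluationRegion, GenomicInterval, interval_union, total_bp

VariantClass = Literal["SNV", "indel", "other"]
_BASES = frozenset("ACGT")

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class UndefinedStatistic(ValueError):
    """A ratio statistic whose denominator is empty (distinct from zero)."""


@dataclass(frozen=True)
class VariantCall:
    """One decomposed variant record (1-based position, explicit alleles)."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    annotations: dict = field(default_factory=dict, compare=False, hash=False)

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if "," in self.alt:
            raise ValueError(
                f"multiallelic record at {self.chrom}:{self.pos}; decompose upstream"
            )

    @property
    def variant_class(self) -> VariantClass:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        if len(self.ref) != len(self.alt):
            return "indel"
        return "other"  # MNPs are not decomposed into SNVs

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def span_bp(self) -> int:
        """Reference footprint used for TN accounting (span occupancy).

        The bases a site occupies are those its REF allele consumes: 1 for an
        SNV or insertion, 1 + deleted length for a deletion.  Inserted bases
        exist only on the alternate haplotype and never displace a
        reference-base TN.
        """
        return len(self.ref)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


# ---------------------------------------------------------------------------
# normalization


def normalize_variant(
    call: VariantCall, reference: Callable[[str, int, int], str]
) -> VariantCall:
    """Left-align and parsimony-trim a variant against the reference.

    ``reference(chrom, start0, end0)`` must return uppercase sequence for the
    0-based half-open range.  The algorithm removes the shared allele suffix
    (pulling in the preceding reference base when an allele empties), then the
    shared prefix while both alleles keep >= 1 base; it is idempotent.
    """
    chrom, pos, ref, alt = call.chrom, call.pos, call.ref.upper(), call.alt.upper()
    if not set(ref) <= _BASES or not set(alt) <= _BASES:
        raise ValueError(f"non-ACGT allele at {chrom}:{pos}")
    seen = reference(chrom, pos - 1, pos - 1 + len(ref)).upper()
    if seen != ref:
        raise ValueError(
            f"REF mismatch at {chrom}:{pos}: VCF says {ref!r}, reference has {seen!r}"
        )
    changed = True
    while changed:
        changed = False
        # trim shared suffix; extend left when an allele would empty
        while ref[-1] == alt[-1]:
            if len(ref) == 1 or len(alt) == 1:
                if pos == 1:
                    break
                prev = reference(chrom, pos - 2, pos - 1).upper()
                ref, alt, pos = prev + ref[:-1], prev + alt[:-1], pos - 1
            else:
                ref, alt = ref[:-1], alt[:-1]
            changed = True
        # trim shared prefix keeping >= 1 base each
        while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
            ref, alt, pos = ref[1:], alt[1:], pos + 1
            changed = True
    return replace(call, chrom=chrom, pos=pos, ref=ref, alt=alt)


def reference_from_fasta(fasta) -> Callable[[str, int, int], str]:
    """Adapt a pyfaidx.Fasta (or dict of str) to the accessor protocol."""
    if isinstance(fasta, dict):
        return lambda chrom, s, e: fasta[chrom][s:e]
    return lambda chrom, s, e: str(fasta[chrom][s:e])


# ---------------------------------------------------------------------------
# classification


def _site_occupancy_intervals(
    calls: Iterable[VariantCall], occupancy: str
) -> list[GenomicInterval]:
    ivs = []
    for c in calls:
        span = 1 if occupancy == "one" else c.span_bp
        ivs.append(GenomicInterval(c.chrom, c.pos - 1, c.pos - 1 + span))
    return ivs


def classify_calls(
    query: Sequence[VariantCall],
    truth: Sequence[VariantCall],
    region: EvaluationRegion,
    site_occupancy: Literal["span", "one"] = "span",
    reference: Callable[[str, int, int], str] | None = None,
) -> dict[str, ConfusionCounts]:
    """Confusion counts per variant class ("SNV", "indel", "all").

    Both call sets must already be normalized; when a reference accessor is
    supplied this is verified and a violation raises.  Only calls whose
    position lies in the region participate.  TN is the region base count
    minus bases occupied by the class's TP/FP/FN sites (under "span"
    occupancy a site occupies its reference footprint — one base for an SNV
    or insertion, 1 + deleted length for a deletion; under "one" every site
    occupies a single base).
    """
    if reference is not None:
        for c in list(query) + list(truth):
            if normalize_variant(c, reference).key != c.key:
                raise ValueError(f"call {c.key} is not normalized")

    def in_region(c: VariantCall) -> bool:
        return region.contains(c.chrom, c.pos - 1)

    q = [c for c in query if in_region(c)]
    t = [c for c in truth if in_region(c)]
    qkeys = {c.key: c for c in q}
    tkeys = {c.key: c for c in t}
    if len(qkeys) != len(q) or len(tkeys) != len(t):
        raise ValueError("duplicate (chrom, pos, ref, alt) records in input")

    out: dict[str, ConfusionCounts] = {}
    for cls in ("SNV", "indel", "all"):
        def of_class(c: VariantCall) -> bool:
            return cls == "all" or c.variant_class == cls

        tp_calls = [c for k, c in tkeys.items() if k in qkeys and of_class(c)]
        fn_calls = [c for k, c in tkeys.items() if k not in qkeys and of_class(c)]
        fp_calls = [c for k, c in qkeys.items() if k not in tkeys and of_class(c)]
        occupied = total_bp(
            interval_union(
                _site_occupancy_intervals(tp_calls + fn_calls + fp_calls, site_occupancy)
            )
        )
        out[cls] = ConfusionCounts(
            tp=len(tp_calls),
            fp=len(fp_calls),
            fn=len(fn_calls),
            tn=region.total_bp - occupied,
        )
    return out


# ---------------------------------------------------------------------------
# derived statistics (percentages on the 0-100 scale)


def sensitivity(counts: ConfusionCounts) -> float:
    """100 * TP / (TP + FN)."""
    if counts.tp + counts.fn == 0:
        raise UndefinedStatistic("sensitivity undefined: no truth-positive sites")
    return 100.0 * counts.tp / (counts.tp + counts.fn)


def precision(counts: ConfusionCounts) -> float:
    """100 * TP / (TP + FP)."""
    if counts.tp + counts.fp == 0:
        raise UndefinedStatistic("precision undefined: no query-positive sites")
    return 100.0 * counts.tp / (counts.tp + counts.fp)


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient as a percentage.

    The numerator and radicand are computed in exact integer arithmetic so the
    statistic does not lose precision at TN ~ 5e5.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    for s in (tp + fp, tp + fn, tn + fp, tn + fn):
        if s == 0:
            raise UndefinedStatistic("MCC undefined: a marginal sum is zero")
    num = tp * tn - fp * fn
    rad = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    return 100.0 * num / math.sqrt(rad)


def ts_tv(variants: Iterable[VariantCall]) -> float:
    """Transition/transversion ratio over the SNVs in the collection."""
    ts = tv = 0
    for v in variants:
        if v.variant_class != "SNV":
            continue
        if (v.ref, v.alt) in TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if tv == 0:
        raise UndefinedStatistic("Ts/Tv undefined: no transversions observed")
    return ts / tv


def filter_by_quality(
    calls: Iterable[VariantCall],
    key: str,
    min_value: float,
    missing_fails: bool = True,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Partition calls into (passing, failing) on an annotation threshold.

    Passing means annotation value >= min_value; a missing annotation fails
    unless ``missing_fails`` is False.
    """
    passing: list[VariantCall] = []
    failing: list[VariantCall] = []
    for c in calls:
        val = c.annotations.get(key)
        if val is None:
            (failing if missing_fails else passing).append(c)
        elif float(val) >= min_value:
            passing.append(c)
        else:
            failing.append(c)
    return passing, failing


# ---------------------------------------------------------------------------
# VCF I/O and the assembled result


def read_vcf(
    path: str | Path,
    include_filtered: bool = False,
    annotation_keys: Sequence[str] = ("QD",),
) -> list[VariantCall]:
    """Read decomposed variant records from an (uncompressed or bgzipped) VCF.

    Non-PASS records are excluded by default — a filtered record did not count
    as called.  Multiallelic records raise; split them upstream.
    """
    import pysam

    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None:
                continue
            if len(rec.alts) > 1:
                raise ValueError(
                    f"multiallelic record at {rec.chrom}:{rec.pos}; decompose upstream"
                )
            filters = set(rec.filter.keys())
            if not include_filtered and filters and filters != {"PASS"}:
                continue
            ann = {}
            for k in annotation_keys:
                if k in rec.info:
                    v = rec.info[k]
                    ann[k] = float(v[0] if isinstance(v, tuple) else v)
            calls.append(
                VariantCall(rec.chrom, rec.pos, str(rec.ref).upper(),
                            str(rec.alts[0]).upper(), ann)
            )
    return calls


@dataclass(frozen=True)
class ConcordanceResult:
    """Per-class confusion counts with derived statistics for one call set."""

    counts: dict[str, ConfusionCounts]
    region: EvaluationRegion
    label: str = ""

    def stats(self, cls: str) -> dict[str, float]:
        c = self.counts[cls]
        return {
            "tp": c.tp,
            "fp": c.fp,
            "fn": c.fn,
            "tn": c.tn,
            "sensitivity_pct": sensitivity(c),
            "precision_pct": precision(c),
            "mcc_pct": mcc(c),
        }


def evaluate_concordance(
    query: Sequence[VariantCall],
    truth: Sequence[VariantCall],
    region: EvaluationRegion,
    label: str = "",
    site_occupancy: Literal["span", "one"] = "span",
    reference: Callable[[str, int, int], str] | None = None,
) -> ConcordanceResult:
    counts = classify_calls(query, truth, region, site_occupancy, reference)
    return ConcordanceResult(counts=counts, region=region, label=label)
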