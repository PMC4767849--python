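"""Synthetic fixtures with recorded ground truth.

Everything the toolkit consumes can be generated here at desk scale: a
reference sequence with per-exon GC control, a gene panel BED, per-sample
qualifying-depth profiles with GC- and mappability-dependent dropout,
aligned-read records (plain SAM) with per-read qualities and duplicate flags,
truth/query call sets with an injection ledger, and cohort read statistics
with planted outliers.  Each generator also emits a :class:`SimulationTruth`
record — the oracle the test suite checks the analysis modules against.

Depth is drawn per base from a negative binomial (capture data are
overdispersed relative to Poisson); GC dropout is a step-function penalty
applied outside a configurable GC window, and per-exon mappability scales the
mean multiplicatively.  Exons engineered with very low effective mean depth
become guaranteed coverage gaps (the tail probability of reaching 20x from a
mean of ~2 is negligible), mimicking the recurrent first-exon and
titin-exon dropouts seen in real capture data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .callability import DepthProfile
from .concordance import TRANSITIONS, VariantCall
from .intervals import EvaluationRegion, GenomicInterval
from .panel import GenePanel, TargetRegion
from .sample_qc import SampleReadStats

_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS_OF = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


# ---------------------------------------------------------------------------
# configuration and truth records


@dataclass(frozen=True)
class ExonPlan:
    """Per-exon generative parameters; mappability in [0, 1]."""

    gene: str
    length_bp: int
    gc: float
    mappability: float = 1.0
    engineered_gap: bool = False


@dataclass(frozen=True)
class CallsetPlan:
    """Counts of variant sites by ledger label and class."""

    shared_snv: int = 20
    shared_indel: int = 2
    query_only_snv: int = 0
    query_only_indel: int = 0
    truth_only_snv: int = 0
    truth_only_indel: int = 0
    max_indel_bp: int = 10
    homopolymer_indels: int = 0  # truth-only deletions placed before an A-run
    shared_indel_insertions: int | None = None  # None: draw ins/del at random

    @property
    def total_sites(self) -> int:
        return (
            self.shared_snv + self.shared_indel + self.query_only_snv
            + self.query_only_indel + self.truth_only_snv + self.truth_only_indel
        )


@dataclass(frozen=True)
class OutlierPlan:
    inflate_indices: tuple[int, ...] = ()
    deflate_indices: tuple[int, ...] = ()
    inflate_factor: float = 3.0
    deflate_factor: float = 0.2


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    chrom: str = "chr1"
    n_genes: int = 5
    exons_per_gene: tuple[int, int] = (3, 5)
    exon_length_bp: tuple[int, int] = (100, 160)
    intron_length_bp: tuple[int, int] = (200, 400)
    flank_bp: int = 500
    gc_range: tuple[float, float] = (0.35, 0.60)
    mean_depth: float = 100.0
    depth_dispersion: float = 8.0
    gc_dropout: tuple[float, float, float] = (0.25, 0.65, 0.15)  # low, high, penalty
    n_samples: int = 3
    ts_tv_odds: float = 3.5
    exon_plans: tuple[ExonPlan, ...] | None = None  # overrides the ranges above
    n_homopolymer_runs: int = 2
    read_length: int = 100

    def __post_init__(self) -> None:
        lo, hi, penalty = self.gc_dropout
        if not 0.0 < penalty <= 1.0:
            raise ValueError("GC dropout penalty must be in (0, 1]")
        if self.mean_depth < 0 or self.depth_dispersion <= 0:
            raise ValueError("rates must be non-negative; dispersion positive")


class _SiteRetry(Exception):
    """A candidate site cannot host the requested variant; pick another."""


@dataclass
class LedgerEntry:
    call: VariantCall
    label: Literal["shared", "query_only", "truth_only"]
    near_homopolymer: bool = False


@dataclass
class SimulationTruth:
    """Ground truth the generators promise; the oracle for every other module."""

    panel_total_bp: int = 0
    exon_records: list[dict] = field(default_factory=list)
    expected_mean_depth: dict[tuple[str, int, int], float] = field(default_factory=dict)
    engineered_gaps: list[tuple[str, GenomicInterval]] = field(default_factory=list)
    ledger: list[LedgerEntry] = field(default_factory=list)
    expected_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    region: EvaluationRegion | None = None
    planted_outliers: tuple[str, ...] = ()
    planted_threshold_failures: tuple[str, ...] = ()
    homopolymer_runs: list[tuple[str, int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# reference + panel


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.45) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)


def _gc_controlled_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    """Sequence of length n with exactly round(gc*n) G/C bases."""
    n_gc = round(gc * n)
    if not 0 <= n_gc <= n:
        raise ValueError(f"infeasible GC target {gc} for length {n}")
    bases = np.concatenate(
        [
            rng.choice(np.frombuffer(b"GC", dtype="S1"), size=n_gc),
            rng.choice(np.frombuffer(b"AT", dtype="S1"), size=n - n_gc),
        ]
    )
    rng.shuffle(bases)
    return bases


def _default_exon_plans(config: SimulationConfig, rng: np.random.Generator) -> list[ExonPlan]:
    plans = []
    for g in range(config.n_genes):
        gene = f"GENE{g + 1}"
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        for _ in range(n_exons):
            length = int(rng.integers(config.exon_length_bp[0], config.exon_length_bp[1] + 1))
            gc = float(rng.uniform(*config.gc_range))
            plans.append(ExonPlan(gene, length, gc))
    return plans


def simulate_reference_and_panel(
    config: SimulationConfig,
) -> tuple[dict[str, str], GenePanel, SimulationTruth]:
    """Build a reference sequence, the panel over it, and the truth record.

    Exon GC content is constructed exactly (the emitted sequence has
    round(gc * length) G/C bases).  Homopolymer runs of 15 As are embedded in
    intronic sequence so call-set simulation can place deletions before them.
    """
    rng = np.random.default_rng(config.seed)
    plans = list(config.exon_plans) if config.exon_plans is not None else _default_exon_plans(config, rng)

    truth = SimulationTruth()
    chunks: list[np.ndarray] = []
    regions: list[TargetRegion] = []
    cursor = 0

    def emit(seq: np.ndarray) -> None:
        nonlocal cursor
        chunks.append(seq)
        cursor += len(seq)

    emit(_random_seq(rng, config.flank_bp))
    genes_seen: dict[str, int] = {}
    prev_gene: str | None = None
    for plan in plans:
        if plan.gene != prev_gene and prev_gene is not None:
            emit(_random_seq(rng, config.flank_bp))
        elif plan.gene == prev_gene:
            emit(_random_seq(rng, int(rng.integers(*config.intron_length_bp))))
        prev_gene = plan.gene
        exon_idx = genes_seen.get(plan.gene, 0)
        genes_seen[plan.gene] = exon_idx + 1
        start = cursor
        emit(_gc_controlled_seq(rng, plan.length_bp, plan.gc))
        iv = GenomicInterval(config.chrom, start, cursor)
        regions.append(TargetRegion(iv, plan.gene, label=f"exon{exon_idx + 1}"))
        gc_lo, gc_hi, penalty = config.gc_dropout
        gc_factor = 1.0 if gc_lo <= plan.gc <= gc_hi else penalty
        mean = config.mean_depth * gc_factor * plan.mappability
        truth.exon_records.append(
            {
                "gene": plan.gene,
                "interval": iv,
                "gc": plan.gc,
                "mappability": plan.mappability,
                "expected_mean_depth": mean,
                "engineered_gap": plan.engineered_gap,
            }
        )
        truth.expected_mean_depth[(iv.chrom, iv.start, iv.end)] = mean
        if plan.engineered_gap:
            truth.engineered_gaps.append((plan.gene, iv))
    emit(_random_seq(rng, config.flank_bp))

    seq = np.concatenate(chunks)
    # embed homopolymer runs (15 As) in non-target sequence near targets
    panel = GenePanel(name="simulated", regions=regions)
    target_bases = {(iv.start, iv.end) for iv in panel.merged_intervals()}
    placed = 0
    attempts = 0
    while placed < config.n_homopolymer_runs and attempts < 1000:
        attempts += 1
        pos = int(rng.integers(config.flank_bp, len(seq) - config.flank_bp))
        if any(s - 20 <= pos <= e + 20 for s, e in target_bases):
            continue
        seq[pos: pos + 15] = np.frombuffer(b"A", dtype="S1")[0]
        seq[pos - 1] = np.frombuffer(b"C", dtype="S1")[0]  # non-A anchor base
        truth.homopolymer_runs.append((config.chrom, pos, pos + 15))
        placed += 1

    reference = {config.chrom: seq.tobytes().decode("ascii")}
    truth.panel_total_bp = panel.total_target_bp
    return reference, panel, truth


def write_fasta(reference: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


# ---------------------------------------------------------------------------
# depth


def _negbin(rng: np.random.Generator, mean: float, size_param: float, n: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(n, dtype=np.int64)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n).astype(np.int64)


def simulate_depth(
    config: SimulationConfig,
    panel: GenePanel,
    truth: SimulationTruth,
    n_samples: int | None = None,
) -> list[DepthProfile]:
    """Per-sample per-base qualifying depth: NegBin around each exon's mean.

    The exon mean is mean_depth x gc_factor x mappability as recorded in the
    truth; dispersion is the negative-binomial size parameter.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = n_samples if n_samples is not None else config.n_samples
    profiles = []
    for i in range(n):
        prof = DepthProfile(f"sample{i + 1}")
        for rec in truth.exon_records:
            iv: GenomicInterval = rec["interval"]
            depths = _negbin(rng, rec["expected_mean_depth"], config.depth_dispersion, len(iv))
            prof.set_block(iv.chrom, iv.start, depths.tolist())
        profiles.append(prof)
    return profiles


# ---------------------------------------------------------------------------
# aligned reads (plain SAM)


@dataclass(frozen=True)
class ReadNoisePlan:
    """Fractions of reads/bases failing each qualifying filter."""

    frac_low_mq: float = 0.10
    frac_duplicate: float = 0.10
    frac_low_bq_bases: float = 0.05
    frac_deletion_reads: float = 0.05
    low_mq: int = 10
    high_mq: int = 60
    low_bq: int = 2
    high_bq: int = 30
    deletion_bp: int = 4


def simulate_alignments(
    config: SimulationConfig,
    reference: dict[str, str],
    panel: GenePanel,
    sam_path: str | Path,
    noise: ReadNoisePlan = ReadNoisePlan(),
    depth_per_exon: float | None = None,
) -> dict[tuple[str, int], int]:
    """Write plain SAM reads over the panel; return intended qualifying depth.

    Reads are drawn from the reference (no sequencing errors), with per-read
    mapping quality, per-base qualities, duplicate flags and occasional
    deletion CIGARs.  The returned mapping (chrom, pos0) -> depth is computed
    directly from the emitted read set by the qualifying rules (MQ >= 20,
    BQ >= 20, duplicates excluded, deleted bases skipped) and is the oracle
    for pileup-based depth extraction.
    """
    import pysam

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    L = config.read_length
    target_depth = depth_per_exon if depth_per_exon is not None else config.mean_depth
    expected: dict[tuple[str, int], int] = {
        (iv.chrom, p): 0 for iv in panel.merged_intervals() for p in range(iv.start, iv.end)
    }
    chrom_lengths = {c: len(s) for c, s in reference.items()}
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": n} for c, n in chrom_lengths.items()],
        }
    )
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as sam:
        rid = 0
        for iv in panel.merged_intervals():
            n_reads = int(np.ceil(target_depth * (len(iv) + L) / L))
            starts = rng.integers(max(0, iv.start - L + 1), iv.end, size=n_reads)
            for start in sorted(starts.tolist()):
                rid += 1
                has_del = rng.random() < noise.frac_deletion_reads
                mq = noise.low_mq if rng.random() < noise.frac_low_mq else noise.high_mq
                dup = rng.random() < noise.frac_duplicate
                quals = np.where(
                    rng.random(L) < noise.frac_low_bq_bases, noise.low_bq, noise.high_bq
                ).astype(np.uint8)
                if has_del:
                    half = L // 2
                    ref_positions = list(range(start, start + half)) + list(
                        range(start + half + noise.deletion_bp, start + L + noise.deletion_bp)
                    )
                    cigar = [(0, half), (2, noise.deletion_bp), (0, L - half)]
                else:
                    ref_positions = list(range(start, start + L))
                    cigar = [(0, L)]
                if ref_positions[-1] >= chrom_lengths[iv.chrom]:
                    continue
                seq = "".join(reference[iv.chrom][p] for p in ref_positions)
                a = pysam.AlignedSegment(header)
                a.query_name = f"read{rid}"
                a.query_sequence = seq
                a.flag = 0x400 if dup else 0
                a.reference_id = list(chrom_lengths).index(iv.chrom)
                a.reference_start = start
                a.mapping_quality = mq
                a.cigartuples = cigar
                a.query_qualities = quals.tolist()
                sam.write(a)
                if dup or mq < 20:
                    continue
                for qpos, rpos in enumerate(ref_positions):
                    if quals[qpos] >= 20 and (iv.chrom, rpos) in expected:
                        expected[(iv.chrom, rpos)] += 1
    return expected


# ---------------------------------------------------------------------------
# call sets


def _draw_snv(rng: np.random.Generator, ref_base: str, ts_tv_odds: float) -> str:
    if rng.random() < ts_tv_odds / (1.0 + ts_tv_odds):
        return _TRANSITION_OF[ref_base]
    return _TRANSVERSIONS_OF[ref_base][int(rng.integers(0, 2))]


def simulate_callsets(
    config: SimulationConfig,
    reference: dict[str, str],
    panel: GenePanel,
    plan: CallsetPlan,
    pad_bp: int = 8,
    confidence: Sequence[GenomicInterval] | None = None,
    truth: SimulationTruth | None = None,
) -> SimulationTruth:
    """Place truth/query variants in the evaluation region per the plan.

    Truth = shared + truth_only sites; query = shared + query_only sites.
    SNV alternates are drawn with the configured transition odds; indels are
    1..max_indel_bp insertions or deletions anchored VCF-style on the
    preceding base.  ``homopolymer_indels`` of the truth_only deletions are
    placed immediately before an embedded A-run when one is available.
    Expected confusion counts are derived from the ledger and stored.
    """
    from .panel import pad_and_intersect

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    if confidence is None:
        confidence = [iv.padded(pad_bp) for iv in panel.merged_intervals()]
    region = pad_and_intersect(panel, pad_bp, confidence)
    truth = truth if truth is not None else SimulationTruth()
    truth.region = region

    # candidate anchor positions: leave clearance between sites so spans never
    # overlap, and keep clear of embedded homopolymer runs (reserved for the
    # engineered missed deletions)
    spacing = plan.max_indel_bp + 2
    hp_exclude: set[tuple[str, int]] = set()
    for chrom, s, e in truth.homopolymer_runs:
        hp_exclude.update((chrom, p) for p in range(s - spacing - 1, e + spacing + 1))
    candidates: list[tuple[str, int]] = []
    for iv in region.intervals:
        # skip the first base of each interval so deletion anchors stay inside
        candidates.extend(
            (iv.chrom, p)
            for p in range(iv.start + 1, iv.end - plan.max_indel_bp - 1)
            if (iv.chrom, p) not in hp_exclude
        )
    order = rng.permutation(len(candidates))

    chosen: list[tuple[str, int]] = []
    occupied: set[tuple[str, int]] = set()
    pool_size = plan.total_sites + 20  # surplus sites for constraint retries
    for i in order:
        if len(chosen) == pool_size:
            break
        chrom, pos = candidates[i]
        if any((chrom, pos + d) in occupied for d in range(-spacing, spacing + 1)):
            continue
        chosen.append((chrom, pos))
        occupied.add((chrom, pos))
    if len(chosen) < plan.total_sites:
        raise ValueError(
            f"variant density too high: placed {len(chosen)} of {plan.total_sites} sites"
        )

    def make_snv(chrom: str, pos0: int) -> VariantCall:
        ref_base = reference[chrom][pos0].upper()
        return VariantCall(chrom, pos0 + 1, ref_base, _draw_snv(rng, ref_base, config.ts_tv_odds))

    def make_indel(chrom: str, pos0: int, force: str | None = None) -> VariantCall:
        # normalized-by-construction: a deletion whose last removed base
        # differs from the anchor cannot be suffix-trimmed or left-shifted
        # (same for an insertion whose last inserted base differs)
        anchor = reference[chrom][pos0].upper()
        size = int(rng.integers(1, plan.max_indel_bp + 1))
        want_del = force == "del" or (force is None and rng.random() < 0.5)
        if want_del:
            for s in list(range(size, plan.max_indel_bp + 1)) + list(range(1, size)):
                ref = reference[chrom][pos0: pos0 + 1 + s].upper()
                if ref[-1] != anchor:
                    return VariantCall(chrom, pos0 + 1, ref, anchor)
            if force == "del":
                raise _SiteRetry  # anchor in a homopolymer; try another site
            # unforced: fall through to an insertion
        ins = list("".join(rng.choice(list("ACGT"), size=size)))
        if ins[-1] == anchor:
            ins[-1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[anchor]
        return VariantCall(chrom, pos0 + 1, anchor, anchor + "".join(ins))

    ledger: list[LedgerEntry] = []
    it = iter(chosen)

    def take(n: int, maker, label: str, near_hp: bool = False) -> None:
        for _ in range(n):
            while True:
                try:
                    chrom, pos0 = next(it)
                except StopIteration:
                    raise ValueError(
                        "variant density too high: ran out of candidate sites"
                    ) from None
                try:
                    call = maker(chrom, pos0)
                except _SiteRetry:
                    continue
                break
            ledger.append(LedgerEntry(call, label, near_hp))

    take(plan.shared_snv, make_snv, "shared")
    if plan.shared_indel_insertions is None:
        take(plan.shared_indel, make_indel, "shared")
    else:
        n_ins = plan.shared_indel_insertions
        take(n_ins, lambda c, p: make_indel(c, p, force="ins"), "shared")
        take(plan.shared_indel - n_ins, lambda c, p: make_indel(c, p, force="del"), "shared")
    take(plan.query_only_snv, make_snv, "query_only")
    take(plan.query_only_indel, make_indel, "query_only")
    take(plan.truth_only_snv, make_snv, "truth_only")

    # truth-only indels: place some right before an embedded homopolymer run
    hp_runs = list(truth.homopolymer_runs)
    n_hp = min(plan.homopolymer_indels, plan.truth_only_indel, len(hp_runs))
    placed_hp = 0
    for chrom, run_start, _run_end in hp_runs[:n_hp]:
        pos0 = run_start - 1  # the non-A anchor immediately before the A-run
        if pos0 < 1 or not region.contains(chrom, pos0):
            continue
        # delete the first A of the run: left-aligned because the anchor is not A
        ref = reference[chrom][pos0: pos0 + 2].upper()
        ledger.append(LedgerEntry(VariantCall(chrom, pos0 + 1, ref, ref[0]), "truth_only", True))
        placed_hp += 1
    take(plan.truth_only_indel - placed_hp, make_indel, "truth_only")

    truth.ledger = ledger
    truth.expected_counts = expected_confusion_counts(ledger, region)
    return truth


def expected_confusion_counts(
    ledger: Sequence[LedgerEntry], region: EvaluationRegion
) -> dict[str, dict[str, int]]:
    """Derive TP/FP/FN/TN per class directly from the injection ledger.

    Sites are non-overlapping by construction, so occupied bases are the sum
    of per-site spans.
    """
    out: dict[str, dict[str, int]] = {}
    for cls in ("SNV", "indel", "all"):
        entries = [
            e for e in ledger if cls == "all" or e.call.variant_class == cls
        ]
        tp = sum(e.label == "shared" for e in entries)
        fp = sum(e.label == "query_only" for e in entries)
        fn = sum(e.label == "truth_only" for e in entries)
        occupied = sum(e.call.span_bp for e in entries)
        out[cls] = {"tp": tp, "fp": fp, "fn": fn, "tn": region.total_bp - occupied}
    return out


def ledger_calls(
    ledger: Sequence[LedgerEntry], side: Literal["truth", "query"]
) -> list[VariantCall]:
    labels = {"truth": ("shared", "truth_only"), "query": ("shared", "query_only")}[side]
    return [e.call for e in ledger if e.label in labels]


def write_vcf(
    calls: Sequence[VariantCall],
    reference: dict[str, str],
    path: str | Path,
    filtered_calls: Sequence[tuple[VariantCall, str]] = (),
) -> None:
    """Write an uncompressed VCF 4.2; ``filtered_calls`` carry a FILTER tag."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">')
    header.add_line('##FILTER=<ID=lowQD,Description="QD below threshold">')
    for chrom, seq in reference.items():
        header.contigs.add(chrom, length=len(seq))
    records = [(c, None) for c in calls] + [(c, f) for c, f in filtered_calls]
    records.sort(key=lambda t: (t[0].chrom, t[0].pos))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for call, filt in records:
            rec = vcf.new_record(
                contig=call.chrom,
                start=call.pos - 1,
                stop=call.pos - 1 + len(call.ref),
                alleles=(call.ref, call.alt),
            )
            if "QD" in call.annotations:
                rec.info["QD"] = float(call.annotations["QD"])
            rec.filter.add(filt if filt else "PASS")
            vcf.write(rec)


def write_confidence_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# cohort read statistics


@dataclass(frozen=True)
class CohortPlan:
    n_samples: int = 252
    baseline_log_mean: float = np.log(4.0e6)
    baseline_log_sd: float = 0.08
    truncate_sd: float = 1.5  # reject draws beyond this many log-SDs
    outliers: OutlierPlan = OutlierPlan()
    n_threshold_failures: int = 0
    baseline_pct_gt10x: tuple[float, float] = (85.0, 99.5)
    failure_pct_gt10x: tuple[float, float] = (50.0, 75.0)
    min_pct: float = 80.0


def _oracle_quartiles(values: Sequence[float]) -> tuple[float, float]:
    """Independent quartile computation (inclusive linear interpolation)."""
    import statistics

    q = statistics.quantiles(sorted(values), n=4, method="inclusive")
    return q[0], q[2]


def simulate_cohort_stats(config: SimulationConfig, plan: CohortPlan) -> tuple[list[SampleReadStats], SimulationTruth]:
    """Cohort read counts from a truncated narrow lognormal, plus planted
    IQR outliers and coverage-threshold failures.

    Generation verifies with an independent quartile oracle that the planted
    outliers — and only they — fall outside the Tukey fences, with a margin of
    at least 10% of the IQR; it raises if the plan cannot guarantee that.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    n = plan.n_samples
    bad = set(plan.outliers.inflate_indices) | set(plan.outliers.deflate_indices)
    if bad and max(bad) >= n:
        raise ValueError("outlier plan indices must be < n_samples")

    logs = rng.normal(plan.baseline_log_mean, plan.baseline_log_sd, size=4 * n)
    logs = logs[np.abs(logs - plan.baseline_log_mean) <= plan.truncate_sd * plan.baseline_log_sd][:n]
    if len(logs) < n:
        raise ValueError("truncation rejected too many draws; widen truncate_sd")
    reads = np.exp(logs)
    for i in plan.outliers.inflate_indices:
        reads[i] *= plan.outliers.inflate_factor
    for i in plan.outliers.deflate_indices:
        reads[i] *= plan.outliers.deflate_factor
    reads = np.round(reads).astype(np.int64)

    q1, q3 = _oracle_quartiles(reads.tolist())
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    margin = 0.1 * iqr
    for i in range(n):
        outside = reads[i] > hi or reads[i] < lo
        if i in bad:
            if not (reads[i] > hi + margin or reads[i] < lo - margin):
                raise ValueError(
                    f"planted outlier index {i} does not exceed the IQR fence "
                    "with margin; increase the inflation/deflation factor"
                )
        elif outside:
            raise ValueError(
                f"baseline sample index {i} strays outside the IQR fence; "
                "narrow the baseline distribution"
            )

    pct = rng.uniform(*plan.baseline_pct_gt10x, size=n)
    fail_idx = rng.choice(n, size=plan.n_threshold_failures, replace=False) if plan.n_threshold_failures else np.array([], dtype=int)
    for i in fail_idx:
        pct[i] = rng.uniform(*plan.failure_pct_gt10x)
    if np.any(pct[[i for i in range(n) if i not in set(fail_idx.tolist())]] < plan.min_pct):
        raise ValueError("baseline pct range crosses the inclusion threshold")

    stats = [
        SampleReadStats(f"S{i + 1:04d}", int(reads[i]), float(round(pct[i], 2)))
        for i in range(n)
    ]
    truth = SimulationTruth(
        planted_outliers=tuple(f"S{i + 1:04d}" for i in sorted(bad)),
        planted_threshold_failures=tuple(f"S{i + 1:04d}" for i in sorted(fail_idx.tolist())),
    )
    return stats, truth


def write_stats_tsv(stats: Sequence[SampleReadStats], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            (s.sample_id, s.total_reads, s.pct_bases_gt10x, s.pct_bases_ge20x)
            for s in stats
        ],
        columns=["sample_id", "total_reads", "pct_bases_gt10x", "pct_bases_ge20x"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# presets mirroring the published benchmark configurations


def benchmark_callset_plan(platform: Literal["MiSeq", "NextSeq"] = "MiSeq") -> CallsetPlan:
    """Call-set composition matching the published NA12878 benchmark rows:
    245 shared SNVs, 4 shared 1-bp indels, one missed 1-bp deletion sited
    before a homopolymer run; the NextSeq configuration adds one marginal
    false-positive SNV."""
    return CallsetPlan(
        shared_snv=245,
        shared_indel=4,
        query_only_snv=1 if platform == "NextSeq" else 0,
        truth_only_indel=1,
        max_indel_bp=1,
        homopolymer_indels=1,
        shared_indel_insertions=1,
    )


def benchmark_region_config(seed: int = 0) -> SimulationConfig:
    """A single ~523 kb target whose padded evaluation region intersected with
    the confidence track is exactly 522,763 bp."""
    return SimulationConfig(
        seed=seed,
        n_genes=1,
        exon_plans=(ExonPlan("PANEL", 522_763 + 16, 0.45),),
        flank_bp=300,
        n_homopolymer_runs=0,
        mean_depth=0.0,
    )


def simulate_benchmark(
    seed: int, platform: Literal["MiSeq", "NextSeq"] = "MiSeq"
) -> tuple[dict[str, str], GenePanel, SimulationTruth]:
    """Full benchmark-shaped fixture: the 522,763 bp evaluation region with
    the published call-set composition.

    The confidence track is the target shrunk by the 8 bp pad on each side,
    so pad-then-intersect recovers exactly 522,763 evaluation bases.
    """
    config = benchmark_region_config(seed)
    reference, panel, truth = simulate_reference_and_panel(config)
    target = panel.merged_intervals()[0]
    confidence = [GenomicInterval(target.chrom, target.start + 8, target.end - 8)]
    # embed one homopolymer run inside the confidence region for the missed
    # deletion (reference is mutable only as a string here; rebuild)
    seq = list(reference[target.chrom])
    run_start = target.start + 1000
    seq[run_start: run_start + 15] = ["A"] * 15
    seq[run_start - 1] = "C"  # non-A anchor for the left-aligned deletion
    reference[target.chrom] = "".join(seq)
    truth.homopolymer_runs.append((target.chrom, run_start, run_start + 15))
    truth = simulate_callsets(
        config, reference, panel, benchmark_callset_plan(platform),
        pad_bp=8, confidence=confidence, truth=truth,
    )
    if platform == "NextSeq":
        for e in truth.ledger:
            if e.label == "query_only":
                e.call.annotations["QD"] = 2.1
    return reference, panel, truth
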