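"""Per-base callability, per-gene coverage statistics and gap detection.

A target base is "callable" when covered by at least ``min_depth`` qualifying
read bases, where a read base qualifies if its base quality is >=
``min_base_quality`` on a read with mapping quality >= ``min_mapping_quality``
that is mapped, primary, and (by default) not duplicate-flagged.  The depth
threshold is inclusive: a base at exactly ``min_depth`` is callable.

Qualifying depth can come from an aligned-read file (SAM/BAM pileup) or from a
three-column depth TSV, so the module runs without alignment machinery.
"""

from __future__ import annotations

import os
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .intervals import GenomicInterval, interval_union
from .panel import GenePanel

Z_95 = 1.959964  # two-sided normal 95% quantile


@dataclass(frozen=True)
class CallabilityConfig:
    min_depth: int = 20
    min_base_quality: int = 20
    min_mapping_quality: int = 20
    exclude_duplicates: bool = True
    count_overlapping_mates_once: bool = False
    aux_depth_thresholds: tuple[int, ...] = (10, 20)

    def __post_init__(self) -> None:
        for t in (self.min_depth, self.min_base_quality, self.min_mapping_quality):
            if t < 0:
                raise ValueError("thresholds must be non-negative")


class DepthProfile:
    """Per-base qualifying depth for one sample over arbitrary bases.

    Bases never set are depth 0.  Internally a per-chromosome sorted position
    array plus a depth array, queried with searchsorted.
    """

    def __init__(self, sample_id: str):
        self.sample_id = sample_id
        self._store: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._building: dict[str, dict[int, int]] = {}

    def set_depth(self, chrom: str, pos0: int, depth: int) -> None:
        if depth < 0:
            raise ValueError("depth must be non-negative")
        self._building.setdefault(chrom, {})[pos0] = depth
        self._store.pop(chrom, None)

    def set_block(self, chrom: str, start0: int, depths: Sequence[int]) -> None:
        d = self._building.setdefault(chrom, {})
        for i, v in enumerate(depths):
            d[start0 + i] = int(v)
        self._store.pop(chrom, None)

    def _finalized(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        if chrom not in self._store:
            items = self._building.get(chrom, {})
            pos = np.fromiter(items.keys(), dtype=np.int64, count=len(items))
            dep = np.fromiter(items.values(), dtype=np.int64, count=len(items))
            order = np.argsort(pos)
            self._store[chrom] = (pos[order], dep[order])
        return self._store[chrom]

    def depth_at(self, chrom: str, pos0: int) -> int:
        pos, dep = self._finalized(chrom)
        i = np.searchsorted(pos, pos0)
        if i < len(pos) and pos[i] == pos0:
            return int(dep[i])
        return 0

    def depths_over(self, interval: GenomicInterval) -> np.ndarray:
        """Dense depth vector over [start, end); unset bases are 0."""
        pos, dep = self._finalized(interval.chrom)
        out = np.zeros(len(interval), dtype=np.int64)
        lo = np.searchsorted(pos, interval.start)
        hi = np.searchsorted(pos, interval.end)
        out[pos[lo:hi] - interval.start] = dep[lo:hi]
        return out

    def scale(self, factor: float) -> "DepthProfile":
        """Return a profile with every depth multiplied (floor) by factor > 0."""
        if factor <= 0:
            raise ValueError("factor must be positive")
        out = DepthProfile(self.sample_id)
        for chrom in set(self._building) | set(self._store):
            pos, dep = self._finalized(chrom)
            out._building[chrom] = dict(
                zip(pos.tolist(), (dep.astype(float) * factor).astype(np.int64).tolist())
            )
        return out


@dataclass(frozen=True)
class CallableMask:
    sample_id: str
    intervals: tuple[GenomicInterval, ...]

    def callable_bp_in(self, intervals: Iterable[GenomicInterval]) -> int:
        from .intervals import interval_intersect, total_bp

        return total_bp(interval_intersect(self.intervals, intervals))


@dataclass(frozen=True)
class GapRegion:
    interval: GenomicInterval
    gene: str
    length_bp: int
    mean_depth_in_gap: float


@dataclass(frozen=True)
class GeneCallability:
    gene: str
    per_sample_pct: tuple[float, ...]
    mean_pct: float
    ci95_low: float
    ci95_high: float


def _mean_ci(values: Sequence[float], lo: float = 0.0, hi: float | None = None) -> tuple[float, float, float]:
    """Mean and normal-approximation 95% CI (mean +/- 1.96*SE), truncated.

    With a single observation the CI collapses to the point value.
    """
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    if len(arr) < 2:
        return mean, mean, mean
    se = float(arr.std(ddof=1)) / np.sqrt(len(arr))
    low, high = mean - Z_95 * se, mean + Z_95 * se
    low = max(lo, low)
    if hi is not None:
        high = min(hi, high)
    return mean, low, high


# ---------------------------------------------------------------------------
# depth acquisition


def read_depth_tsv(path: str | Path, sample_id: str | None = None) -> DepthProfile:
    """Read a qualifying-depth TSV with columns: chrom, 1-based pos, depth."""
    path = Path(path)
    profile = DepthProfile(sample_id or path.stem)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns (chrom, pos, depth)")
            try:
                pos1, depth = int(cols[1]), int(cols[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer position or depth") from None
            profile.set_depth(cols[0], pos1 - 1, depth)
    return profile


def write_depth_tsv(profile: DepthProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(set(profile._building) | set(profile._store)):
            pos, dep = profile._finalized(chrom)
            for p, d in zip(pos.tolist(), dep.tolist()):
                fh.write(f"{chrom}\t{p + 1}\t{d}\n")


def _ensure_indexed_bam(path: str | Path) -> tuple[str, tempfile.TemporaryDirectory | None]:
    """Return a coordinate-sorted, indexed BAM path for SAM/BAM input.

    Plain SAM (or an unindexed BAM) is sorted and indexed into a temporary
    directory; the caller keeps the returned handle alive while reading.
    """
    path = str(path)
    if path.endswith(".bam") and os.path.exists(path + ".bai"):
        return path, None
    tmp = tempfile.TemporaryDirectory(prefix="panelqc_bam_")
    sorted_bam = os.path.join(tmp.name, "sorted.bam")
    pysam.sort("-o", sorted_bam, path)
    pysam.index(sorted_bam)
    return sorted_bam, tmp


def qualifying_depth_from_alignments(
    alignments: str | Path,
    panel: GenePanel,
    config: CallabilityConfig = CallabilityConfig(),
    sample_id: str | None = None,
) -> DepthProfile:
    """Compute per-base qualifying depth over panel bases from SAM/BAM.

    Counts aligned read bases with base quality >= ``min_base_quality`` from
    mapped, primary, non-supplementary reads with mapping quality >=
    ``min_mapping_quality``; duplicate-flagged reads are excluded when
    configured.  Deletions within reads contribute no qualifying base.
    """
    bam_path, tmp = _ensure_indexed_bam(alignments)
    profile = DepthProfile(sample_id or Path(str(alignments)).stem)

    def read_ok(read: pysam.AlignedSegment) -> bool:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            return False
        if config.exclude_duplicates and read.is_duplicate:
            return False
        if read.mapping_quality < config.min_mapping_quality:
            return False
        return True

    try:
        with pysam.AlignmentFile(bam_path, "rb") as bam:
            contigs = set(bam.references)
            for iv in panel.merged_intervals():
                if iv.chrom not in contigs:
                    warnings.warn(
                        f"contig {iv.chrom!r} absent from alignments; depth set to 0",
                        stacklevel=2,
                    )
                    profile.set_block(iv.chrom, iv.start, [0] * len(iv))
                    continue
                acgt = bam.count_coverage(
                    iv.chrom,
                    iv.start,
                    iv.end,
                    quality_threshold=config.min_base_quality,
                    read_callback=read_ok,
                )
                depths = np.asarray(acgt, dtype=np.int64).sum(axis=0)
                if config.count_overlapping_mates_once:
                    depths = np.minimum(
                        depths, _fragment_once_depth(bam, iv, config, read_ok)
                    )
                profile.set_block(iv.chrom, iv.start, depths.tolist())
    finally:
        if tmp is not None:
            tmp.cleanup()
    return profile


def _fragment_once_depth(bam, iv, config, read_ok) -> np.ndarray:
    """Depth counting overlapping mate pairs once per fragment per base."""
    per_base: list[set[str]] = [set() for _ in range(len(iv))]
    for read in bam.fetch(iv.chrom, iv.start, iv.end):
        if not read_ok(read):
            continue
        quals = read.query_qualities
        for qpos, rpos in read.get_aligned_pairs(matches_only=True):
            if iv.start <= rpos < iv.end and quals[qpos] >= config.min_base_quality:
                per_base[rpos - iv.start].add(read.query_name)
    return np.array([len(s) for s in per_base], dtype=np.int64)


# ---------------------------------------------------------------------------
# callability statistics


def callable_mask(
    profile: DepthProfile, panel: GenePanel, config: CallabilityConfig = CallabilityConfig()
) -> CallableMask:
    """Mask of panel bases whose qualifying depth >= min_depth (inclusive)."""
    out: list[GenomicInterval] = []
    for iv in panel.merged_intervals():
        depths = profile.depths_over(iv)
        ok = depths >= config.min_depth
        # runs of True -> intervals
        idx = np.flatnonzero(np.diff(np.concatenate(([0], ok.view(np.int8), [0]))))
        for s, e in idx.reshape(-1, 2):
            out.append(GenomicInterval(iv.chrom, iv.start + int(s), iv.start + int(e)))
    return CallableMask(profile.sample_id, tuple(interval_union(out)))


def gene_callability(
    masks: Sequence[CallableMask], panel: GenePanel
) -> list[GeneCallability]:
    """Per-gene mean callable percentage across samples with 95% CI.

    Per sample: 100 x callable bases in gene / gene target bases.  The CI is
    mean +/- 1.96 * SD/sqrt(n) truncated to [0, 100]; with n = 1 it equals the
    point value.
    """
    if not masks:
        raise ValueError("at least one sample mask required")
    results = []
    for gene in panel.genes:
        gene_ivs = panel.gene_intervals(gene)
        gbp = panel.gene_bp(gene)
        if gbp == 0:
            raise ValueError(f"gene {gene} has zero target bases")
        pcts = tuple(100.0 * m.callable_bp_in(gene_ivs) / gbp for m in masks)
        mean, lo, hi = _mean_ci(pcts, 0.0, 100.0)
        results.append(GeneCallability(gene, pcts, mean, lo, hi))
    return results


def find_gaps(
    profile: DepthProfile, panel: GenePanel, config: CallabilityConfig = CallabilityConfig()
) -> list[GapRegion]:
    """Maximal runs of consecutive sub-threshold bases, per gene.

    A run cannot extend across a break in the gene's target intervals, and a
    single callable base splits adjacent runs.
    """
    gaps: list[GapRegion] = []
    for gene in panel.genes:
        for iv in interval_union(panel.gene_intervals(gene)):
            depths = profile.depths_over(iv)
            low = depths < config.min_depth
            idx = np.flatnonzero(np.diff(np.concatenate(([0], low.view(np.int8), [0]))))
            for s, e in idx.reshape(-1, 2):
                sub = GenomicInterval(iv.chrom, iv.start + int(s), iv.start + int(e))
                gaps.append(
                    GapRegion(
                        sub,
                        gene,
                        len(sub),
                        float(depths[int(s): int(e)].mean()),
                    )
                )
    gaps.sort(key=lambda g: (g.interval.chrom, g.interval.start, g.gene))
    return gaps


def gene_gap_bp(gaps: Iterable[GapRegion]) -> dict[str, int]:
    out: dict[str, int] = {}
    for g in gaps:
        out[g.gene] = out.get(g.gene, 0) + g.length_bp
    return out


@dataclass(frozen=True)
class SampleSummary:
    sample_id: str
    mean_depth: float
    pct_at_threshold: dict[int, float] = field(hash=False)


@dataclass(frozen=True)
class PanelSummary:
    per_sample: tuple[SampleSummary, ...]
    mean_depth: float
    mean_depth_ci: tuple[float, float]
    pct_at_threshold: dict[int, tuple[float, float, float]]  # mean, lo, hi


def panel_summary(
    profiles: Sequence[DepthProfile],
    panel: GenePanel,
    config: CallabilityConfig = CallabilityConfig(),
) -> PanelSummary:
    """Per-sample mean depth and percent-at-threshold, with cross-sample CIs."""
    if not profiles:
        raise ValueError("at least one sample required")
    merged = panel.merged_intervals()
    n_bp = sum(len(iv) for iv in merged)
    per_sample: list[SampleSummary] = []
    for prof in profiles:
        all_depths = np.concatenate([prof.depths_over(iv) for iv in merged])
        pct = {
            t: 100.0 * float((all_depths >= t).sum()) / n_bp
            for t in config.aux_depth_thresholds
        }
        per_sample.append(SampleSummary(prof.sample_id, float(all_depths.mean()), pct))
    mean_d, lo_d, hi_d = _mean_ci([s.mean_depth for s in per_sample], 0.0, None)
    pct_stats = {
        t: _mean_ci([s.pct_at_threshold[t] for s in per_sample], 0.0, 100.0)
        for t in config.aux_depth_thresholds
    }
    return PanelSummary(tuple(per_sample), mean_d, (lo_d, hi_d), pct_stats)


def coverage_matrix(per_method: dict[str, list[GeneCallability]], panel: GenePanel):
    """Gene x method matrix of mean callability percentages (Fig-1-shaped).

    Rows follow panel gene order; raises if methods disagree on the gene set.
    """
    import pandas as pd

    gene_order = panel.genes
    expected = set(gene_order)
    for method, results in per_method.items():
        got = {r.gene for r in results}
        if got != expected:
            missing = expected - got
            extra = got - expected
            raise ValueError(
                f"method {method!r} gene set mismatch: missing={sorted(missing)} "
                f"extra={sorted(extra)}"
            )
    data = {
        method: {r.gene: r.mean_pct for r in results}
        for method, results in per_method.items()
    }
    return pd.DataFrame(data, columns=list(per_method)).reindex(gene_order)
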