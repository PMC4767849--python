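"""Genomic intervals and base-set arithmetic.

All internal coordinates are 0-based half-open (BED convention); VCF-style
1-based positions are converted at I/O boundaries.  Interval collections are
kept per chromosome as sorted, disjoint lists, and the set operations below
have base-set semantics: adjacent (touching) intervals merge in unions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_pos(self, chrom: str, pos: int) -> bool:
        """Membership of a 0-based position."""
        return chrom == self.chrom and self.start <= pos < self.end

    def padded(self, pad_bp: int) -> "GenomicInterval":
        if pad_bp < 0:
            raise ValueError("pad_bp must be non-negative")
        return GenomicInterval(self.chrom, max(0, self.start - pad_bp), self.end + pad_bp)


def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for spans in out.values():
        spans.sort()
    return out


def _emit(chrom_spans: dict[str, list[tuple[int, int]]]) -> list[GenomicInterval]:
    return [
        GenomicInterval(chrom, s, e)
        for chrom in sorted(chrom_spans)
        for s, e in chrom_spans[chrom]
    ]


def interval_union(*collections: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of interval collections; adjacent intervals merge."""
    spans = _by_chrom(iv for coll in collections for iv in coll)
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in spans.items():
        acc: list[tuple[int, int]] = []
        for s, e in ivs:
            if acc and s <= acc[-1][1]:  # touching counts as mergeable
                acc[-1] = (acc[-1][0], max(acc[-1][1], e))
            else:
                acc.append((s, e))
        merged[chrom] = acc
    return _emit(merged)


def interval_intersect(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Base-set intersection of two interval collections."""
    am = _by_chrom(interval_union(a))
    bm = _by_chrom(interval_union(b))
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom in am.keys() & bm.keys():
        res: list[tuple[int, int]] = []
        i = j = 0
        xs, ys = am[chrom], bm[chrom]
        while i < len(xs) and j < len(ys):
            s = max(xs[i][0], ys[j][0])
            e = min(xs[i][1], ys[j][1])
            if s < e:
                res.append((s, e))
            if xs[i][1] < ys[j][1]:
                i += 1
            else:
                j += 1
        if res:
            out[chrom] = res
    return _emit(out)


def interval_subtract(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Bases in `a` not in `b`."""
    am = _by_chrom(interval_union(a))
    bm = _by_chrom(interval_union(b))
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, xs in am.items():
        ys = bm.get(chrom, [])
        res: list[tuple[int, int]] = []
        j = 0
        for s, e in xs:
            cur = s
            while j < len(ys) and ys[j][1] <= cur:
                j += 1
            k = j
            while k < len(ys) and ys[k][0] < e:
                bs, be = ys[k]
                if bs > cur:
                    res.append((cur, bs))
                cur = max(cur, be)
                if be >= e:
                    break
                k += 1
            if cur < e:
                res.append((cur, e))
        if res:
            out[chrom] = res
    return _emit(out)


def total_bp(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in interval_union(intervals))


def iter_positions(intervals: Iterable[GenomicInterval]) -> Iterator[tuple[str, int]]:
    """Yield (chrom, 0-based pos) for every base in the collection (small inputs)."""
    for iv in interval_union(intervals):
        for pos in range(iv.start, iv.end):
            yield iv.chrom, pos


@dataclass(frozen=True)
class EvaluationRegion:
    """Disjoint sorted intervals over which concordance is evaluated."""

    intervals: tuple[GenomicInterval, ...]
    total_bp: int = field(default=0)

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "EvaluationRegion":
        merged = tuple(interval_union(intervals))
        return cls(intervals=merged, total_bp=sum(len(iv) for iv in merged))

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based position (binary search per chromosome)."""
        # linear scan is fine at the interval counts this tool sees
        for iv in self.intervals:
            if iv.chrom == chrom and iv.start <= pos0 < iv.end:
                return True
        return False
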