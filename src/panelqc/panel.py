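"""Gene panel representation and BED I/O.

A capture panel is a set of gene-labelled target intervals (coding exons plus
buffer).  Targets overlapping within one gene are merged on load; a base shared
by two genes counts once in panel-level totals but once per gene in per-gene
statistics, so disease-gene tables that list a gene under several conditions do
not double-count panel bases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .intervals import (
    EvaluationRegion,
    GenomicInterval,
    interval_intersect,
    interval_union,
    total_bp,
)


class BedParseError(ValueError):
    """Raised for malformed BED content; carries the offending line number."""


@dataclass(frozen=True)
class TargetRegion:
    interval: GenomicInterval
    gene: str
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")


def _check_dialect(chroms: Iterable[str]) -> None:
    prefixed = {c.startswith("chr") for c in chroms}
    if len(prefixed) > 1:
        raise ValueError(
            "mixed chromosome name dialects ('chr1' vs '1') within one panel; "
            "normalize inputs before loading"
        )


@dataclass
class GenePanel:
    """Named, sorted collection of gene-labelled target regions.

    ``regions`` are sorted by (chrom, start) with same-gene overlaps merged.
    """

    name: str
    regions: list[TargetRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regions = self._merge_per_gene(self.regions)
        _check_dialect({r.interval.chrom for r in self.regions})

    @staticmethod
    def _merge_per_gene(regions: list[TargetRegion]) -> list[TargetRegion]:
        by_gene: dict[str, list[TargetRegion]] = {}
        for r in regions:
            by_gene.setdefault(r.gene, []).append(r)
        merged: list[TargetRegion] = []
        for gene, rs in by_gene.items():
            labels = {r.interval: r.label for r in rs}
            for iv in interval_union(r.interval for r in rs):
                merged.append(TargetRegion(iv, gene, labels.get(iv)))
        merged.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.gene))
        return merged

    @property
    def genes(self) -> list[str]:
        """Gene symbols in panel order (first appearance)."""
        seen: dict[str, None] = {}
        for r in self.regions:
            seen.setdefault(r.gene, None)
        return list(seen)

    @property
    def total_target_bp(self) -> int:
        """Panel-level unique base count (shared bases counted once)."""
        return total_bp(r.interval for r in self.regions)

    def gene_intervals(self, gene: str) -> list[GenomicInterval]:
        return [r.interval for r in self.regions if r.gene == gene]

    def gene_bp(self, gene: str) -> int:
        return total_bp(self.gene_intervals(gene))

    def merged_intervals(self) -> list[GenomicInterval]:
        return interval_union(r.interval for r in self.regions)

    # ---- serialization ------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "regions": [
                {
                    "chrom": r.interval.chrom,
                    "start": r.interval.start,
                    "end": r.interval.end,
                    "gene": r.gene,
                    "label": r.label,
                }
                for r in self.regions
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GenePanel":
        payload = json.loads(Path(path).read_text())
        regions = [
            TargetRegion(
                GenomicInterval(r["chrom"], r["start"], r["end"]), r["gene"], r.get("label")
            )
            for r in payload["regions"]
        ]
        return cls(name=payload["name"], regions=regions)


def read_bed(path: str | Path, with_gene_column: bool = True, name: str | None = None) -> GenePanel:
    """Load a panel from a BED file (0-based half-open; column 4 = gene).

    Records without a gene column get gene ``"NA"``.  Malformed coordinates
    raise :class:`BedParseError` naming the line number.
    """
    path = Path(path)
    regions: list[TargetRegion] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom, s_raw, e_raw = cols[0], cols[1], cols[2]
            try:
                start, end = int(s_raw), int(e_raw)
            except ValueError:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates {s_raw!r}/{e_raw!r}"
                ) from None
            if end <= start or start < 0:
                raise BedParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            gene = cols[3] if (with_gene_column and len(cols) >= 4 and cols[3]) else "NA"
            label = cols[4] if len(cols) >= 5 else None
            regions.append(TargetRegion(GenomicInterval(chrom, start, end), gene, label))
    if not regions:
        raise BedParseError(f"{path}: no target records found")
    return GenePanel(name=name or path.stem, regions=regions)


def write_bed(panel: GenePanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in panel.regions:
            cols = [r.interval.chrom, str(r.interval.start), str(r.interval.end), r.gene]
            if r.label:
                cols.append(r.label)
            fh.write("\t".join(cols) + "\n")


def read_region_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a plain interval BED (e.g. high-confidence regions); labels ignored."""
    return [r.interval for r in read_bed(path, with_gene_column=False).regions]


def pad_and_intersect(
    panel: GenePanel, pad_bp: int, confidence: Iterable[GenomicInterval]
) -> EvaluationRegion:
    """Expand every target by ``pad_bp`` on both sides, union-merge, then
    intersect with the high-confidence intervals.

    This builds the evaluation region for concordance: the padded target
    captures essential splice sites and proximal intronic bases, and the
    confidence intersection restricts scoring to where the truth set asserts
    both variant and reference calls.
    """
    padded = [r.interval.padded(pad_bp) for r in panel.regions]
    conf = interval_union(confidence)
    _check_dialect({iv.chrom for iv in padded} | {iv.chrom for iv in conf})
    return EvaluationRegion.from_intervals(interval_intersect(padded, conf))
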