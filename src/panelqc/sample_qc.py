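"""Cohort-level sample inclusion/exclusion.

Two screens: a Tukey-style IQR rule on total reads per sample (exclude when
outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR], strict inequalities) and a simple
threshold rule on a coverage percentage (exclude when strictly below the
minimum, so a sample exactly at the boundary is kept).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SampleReadStats:
    sample_id: str
    total_reads: int
    pct_bases_gt10x: float = 100.0
    pct_bases_ge20x: float = 100.0

    def __post_init__(self) -> None:
        if self.total_reads < 0:
            raise ValueError("total_reads must be non-negative")
        for p in (self.pct_bases_gt10x, self.pct_bases_ge20x):
            if not 0.0 <= p <= 100.0:
                raise ValueError("percentages must lie in [0, 100]")


@dataclass(frozen=True)
class QCPartition:
    kept: tuple[SampleReadStats, ...]
    excluded: tuple[SampleReadStats, ...]
    reasons: dict[str, str]  # sample_id -> reason (excluded samples only)


def iqr_outliers(stats: Sequence[SampleReadStats], k: float = 1.5) -> QCPartition:
    """Exclude samples whose total reads fall outside [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation between order statistics.  Inequalities
    are strict, so with IQR = 0 (identical counts) nothing is excluded.
    Requires >= 4 samples for the quartiles to be meaningful.
    """
    if len(stats) < 4:
        raise ValueError("IQR screening needs >= 4 samples; review manually")
    reads = np.array([s.total_reads for s in stats], dtype=float)
    q1, q3 = np.percentile(reads, [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    kept, excluded, reasons = [], [], {}
    for s in stats:
        if s.total_reads > hi:
            excluded.append(s)
            reasons[s.sample_id] = f"total_reads {s.total_reads} > Q3+{k}*IQR ({hi:.1f})"
        elif s.total_reads < lo:
            excluded.append(s)
            reasons[s.sample_id] = f"total_reads {s.total_reads} < Q1-{k}*IQR ({lo:.1f})"
        else:
            kept.append(s)
    return QCPartition(tuple(kept), tuple(excluded), reasons)


def threshold_inclusion(
    stats: Sequence[SampleReadStats],
    metric: str = "pct_bases_gt10x",
    min_pct: float = 80.0,
) -> QCPartition:
    """Exclude samples whose metric is strictly below ``min_pct``."""
    kept, excluded, reasons = [], [], {}
    for s in stats:
        value = getattr(s, metric)
        if value < min_pct:
            excluded.append(s)
            reasons[s.sample_id] = f"{metric} {value:.1f} < {min_pct}"
        else:
            kept.append(s)
    return QCPartition(tuple(kept), tuple(excluded), reasons)


# ---------------------------------------------------------------------------
# TSV I/O


def read_stats_tsv(path: str | Path) -> list[SampleReadStats]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "total_reads"}
    if not required <= set(df.columns):
        raise ValueError(f"stats TSV must contain columns {sorted(required)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SampleReadStats(
                sample_id=str(row.sample_id),
                total_reads=int(row.total_reads),
                pct_bases_gt10x=float(getattr(row, "pct_bases_gt10x", 100.0)),
                pct_bases_ge20x=float(getattr(row, "pct_bases_ge20x", 100.0)),
            )
        )
    return out


def write_partition_tsv(partition: QCPartition, path: str | Path) -> None:
    rows = []
    for s in partition.kept:
        rows.append((s.sample_id, s.total_reads, "kept", ""))
    for s in partition.excluded:
        rows.append((s.sample_id, s.total_reads, "excluded", partition.reasons[s.sample_id]))
    pd.DataFrame(rows, columns=["sample_id", "total_reads", "status", "reason"]).to_csv(
        path, sep="\t", index=False
    )
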