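"""Publication-style report tables.

Percentages print to one decimal place, except that a value rounding to 100.0
prints as ``100`` — the convention of clinical-panel coverage tables.  Every
human-readable TSV has a machine-readable JSON twin, and regeneration from the
same inputs is byte-identical (no timestamps in data files).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .callability import GapRegion, GeneCallability, PanelSummary, gene_gap_bp
from .concordance import ConcordanceResult


def format_pct(value: float) -> str:
    rounded = round(value, 1)
    if rounded == 100.0:
        return "100"
    return f"{rounded:.1f}"


def format_pct_ci(mean: float, lo: float, hi: float) -> str:
    return f"{format_pct(mean)} ({format_pct(lo)}–{format_pct(hi)})"


def gene_table(
    results: Sequence[GeneCallability],
    gaps: Sequence[GapRegion] = (),
    disease_groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One row per gene: mean callability with 95% CI and sub-threshold bp."""
    gap_bp = gene_gap_bp(gaps)
    rows = []
    for r in results:
        row = {
            "gene": r.gene,
            "n_samples": len(r.per_sample_pct),
            "mean_callability_pct": format_pct_ci(r.mean_pct, r.ci95_low, r.ci95_high),
            "gap_bp": gap_bp.get(r.gene, 0),
        }
        if disease_groups:
            row = {"disease": disease_groups.get(r.gene, ""), **row}
        rows.append(row)
    return pd.DataFrame(rows)


def method_summary_table(
    summaries: dict[str, PanelSummary],
    metadata: dict[str, dict[str, str]] | None = None,
) -> pd.DataFrame:
    """One column per method: depth and percent-at-threshold with CIs.

    ``metadata`` entries (kit, sequencer, ...) are passed through verbatim.
    """
    columns: dict[str, dict[str, str]] = {}
    for method, s in summaries.items():
        col: dict[str, str] = {}
        if metadata and method in metadata:
            col.update(metadata[method])
        col["samples"] = str(len(s.per_sample))
        lo, hi = s.mean_depth_ci
        col["mean_read_depth"] = f"{s.mean_depth:.0f}× ({lo:.0f}×–{hi:.0f}×)"
        for t, (mean, plo, phi) in s.pct_at_threshold.items():
            col[f"pct_bases_ge{t}x"] = format_pct_ci(mean, plo, phi)
        columns[method] = col
    return pd.DataFrame(columns)


CONCORDANCE_COLUMNS = [
    "platform", "variant_type", "tp", "fp", "fn", "tn",
    "sensitivity_pct", "precision_pct", "mcc_pct",
]


def concordance_table(results: Sequence[ConcordanceResult]) -> pd.DataFrame:
    """Rows (platform x class) with counts and derived statistics."""
    class_display = {"all": "All", "SNV": "SNVs", "indel": "Indels"}
    rows = []
    for res in results:
        for cls in ("all", "SNV", "indel"):
            s = res.stats(cls)
            rows.append(
                {
                    "platform": res.label,
                    "variant_type": class_display[cls],
                    "tp": s["tp"],
                    "fp": s["fp"],
                    "fn": s["fn"],
                    "tn": s["tn"],
                    "sensitivity_pct": format_pct(s["sensitivity_pct"]),
                    "precision_pct": format_pct(s["precision_pct"]),
                    "mcc_pct": format_pct(s["mcc_pct"]),
                }
            )
    return pd.DataFrame(rows, columns=CONCORDANCE_COLUMNS)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV plus its JSON twin (same stem, .json suffix)."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    path.with_suffix(".json").write_text(
        json.dumps(df.to_dict(orient="records"), indent=1, default=str)
    )
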