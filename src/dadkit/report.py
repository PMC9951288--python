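"""Flat-file reports: per-run peak tables, campaign tables, benchmark summaries.

All reports are plain CSV/JSON and are pure functions of their inputs,
so re-rendering the same result is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .campaign import CampaignResult, RunRecord
from .simulate import BenchmarkSummary

__all__ = ["render_peak_table", "write_campaign_reports", "write_benchmark_summary"]

PEAK_TABLE_COLUMNS = [
    "peak", "component", "retention_time", "left_index", "right_index",
    "area", "pure", "compound", "concentration", "saturated", "deconvolved",
    "flags",
]


def render_peak_table(record: RunRecord, time=None) -> pd.DataFrame:
    """One row per peak window plus one per deconvolved component."""
    rows = []
    flags = ";".join(record.flags)
    for i, peak in enumerate(record.peaks):
        rt = float(time[peak.apex_index]) + record.rt_shift if time is not None else None
        rows.append({
            "peak": i, "component": "window", "retention_time": rt,
            "left_index": peak.left_index, "right_index": peak.right_index,
            "area": peak.integral, "pure": peak.pure,
            "compound": peak.assignment, "concentration": peak.concentration,
            "saturated": peak.saturated, "deconvolved": bool(peak.components),
            "flags": flags,
        })
        for j, comp in enumerate(peak.components):
            rows.append({
                "peak": i, "component": f"c{j}", "retention_time": rt,
                "left_index": peak.left_index, "right_index": peak.right_index,
                "area": comp.integral, "pure": False,
                "compound": comp.assignment, "concentration": comp.concentration,
                "saturated": peak.saturated, "deconvolved": True, "flags": flags,
            })
    return pd.DataFrame(rows, columns=PEAK_TABLE_COLUMNS)


def write_campaign_reports(result: CampaignResult, out_dir, campaign=None) -> None:
    """Write the long-format campaign table and one peak table per run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.table.to_csv(out_dir / "campaign_results.csv", index=False)
    times = {}
    if campaign is not None:
        times = {c.meta.run_id: c.time for c in campaign.runs}
    for record in result.records:
        table = render_peak_table(record, times.get(record.run_id))
        table.to_csv(out_dir / f"peaks_{record.run_id}.csv", index=False)


def write_benchmark_summary(summary: BenchmarkSummary, path, level: str,
                            seed: int) -> None:
    payload = {
        "level": level, "seed": seed, "n": summary.n,
        "categories": summary.counts,
        "desired_fraction": (summary.counts["i"] + summary.counts["ii"]) / summary.n,
        "median_error_pct": summary.median_error_pct,
        "q3_error_pct": summary.q3_error_pct,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
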