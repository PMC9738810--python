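"""Single-file HTML report aggregating all samples.

Every number shown is taken verbatim from the machine-readable tables the
pipeline already wrote (per-sample summaries, score strata, candidate
sites), so the report can always be re-derived from the TSVs.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import pandas as pd

from .integration_sites import IntegrationCandidate
from .scoring import SampleSummary

__all__ = [
    "summaries_frame",
    "genus_frame",
    "strata_frame",
    "sites_frame",
    "render_report",
]

_EMPTY = "<p><em>No reads in this table.</em></p>"


def summaries_frame(summaries: Sequence[SampleSummary]) -> pd.DataFrame:
    """Per-sample, per-category proportion table."""
    rows = []
    for s in summaries:
        for cat in sorted(s.category_counts):
            rows.append({
                "sample": s.sample,
                "category": cat,
                "total_reads": s.total_reads,
                "extracted_reads": s.category_counts[cat],
                "kept_microbial_reads": s.kept_counts.get(cat, 0),
                # fixed string formatting so the TSV and the HTML report
                # carry identical digits
                "microbial_proportion": format(
                    s.microbial_proportion.get(cat, 0.0), ".6g"),
            })
    return pd.DataFrame(
        rows,
        columns=["sample", "category", "total_reads", "extracted_reads",
                 "kept_microbial_reads", "microbial_proportion"],
    )


def genus_frame(summaries: Sequence[SampleSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        for genus, (count, mean_score, status) in sorted(s.genus_table.items()):
            rows.append({
                "sample": s.sample,
                "genus": genus,
                "reads": count,
                "mean_taxid_score": round(mean_score, 4),
                "contaminant_status": status or "none",
            })
    return pd.DataFrame(
        rows, columns=["sample", "genus", "reads", "mean_taxid_score",
                       "contaminant_status"],
    )


def strata_frame(strata: List[Dict]) -> pd.DataFrame:
    cols = ["bin_low", "bin_high", "flagged", "blacklisted", "none", "total",
            "flagged_fraction", "blacklisted_fraction", "none_fraction",
            "contaminant_fraction"]
    return pd.DataFrame(strata, columns=cols)


def sites_frame(sites: Sequence[IntegrationCandidate]) -> pd.DataFrame:
    rows = [{
        "chrom": c.chrom, "start": c.start, "end": c.end,
        "support": c.support, "top_genus": c.top_genus,
        "mean_score": round(c.mean_score, 4),
        "genera": ";".join(f"{g}:{n}" for g, n in sorted(c.genera.items())),
    } for c in sites]
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "support", "top_genus",
                       "mean_score", "genera"],
    )


def _table(df: pd.DataFrame) -> str:
    if df.empty:
        return _EMPTY
    return df.to_html(index=False, border=0)


def render_report(
    summaries: Sequence[SampleSummary],
    strata: List[Dict],
    sites: Sequence[IntegrationCandidate],
    out_path,
) -> None:
    """Write the aggregated HTML report."""
    if not summaries:
        raise ValueError("at least one sample summary is required")
    html = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>HGT screening report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; margin-bottom: 1.5em; }}
th, td {{ padding: 4px 10px; border-bottom: 1px solid #ccc; text-align: left; }}
th {{ background: #f0f0f0; }}
</style></head><body>
<h1>Horizontal gene transfer screening report</h1>
<h2>Per-sample microbial proportions</h2>
<p>Kept reads are non-host, genus-level classified reads excluding
blacklisted contaminant genera; proportions are relative to the total
primary records of the sample.</p>
{_table(summaries_frame(summaries))}
<h2>Genus composition</h2>
{_table(genus_frame(summaries))}
<h2>Contamination stratified by classification score</h2>
{_table(strata_frame(strata))}
<h2>Candidate integration sites</h2>
<p>Coordinates are 1-based closed intervals on the host genome.</p>
{_table(sites_frame(sites))}
</body></html>
"""
    with open(out_path, "wt") as fh:
        fh.write(html)
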