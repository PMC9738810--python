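"""Krona-compatible export: pooled per-category read files plus a nested
lineage count table.

Krona's taxonomy importer (``ktImportTaxonomy -t 3``) reads tabular input
with the taxid in column 3, which is exactly the Kraken per-read dialect;
one file is written per read category, pooled across all samples, so a
single chart summarises each category.  Host-classified and blacklisted
reads must already have been removed upstream.  The standalone nested TSV
(semicolon-joined lineage path → count) lets composition be inspected
without Krona itself.
"""

from __future__ import annotations

from typing import Dict, Iterable, TextIO

from .kmer_classifier import write_kraken_output
from .scoring import ScoredClassification
from .taxonomy import TaxonomyTree

__all__ = ["export_krona", "write_lineage_counts"]


def export_krona(scored: Iterable[ScoredClassification], out: TextIO) -> int:
    """Write kept reads in the taxid-in-column-3 Kraken dialect; returns count."""
    return write_kraken_output((sc.record for sc in scored), out)


def write_lineage_counts(
    scored: Iterable[ScoredClassification],
    tree: TaxonomyTree,
    out: TextIO,
) -> int:
    """Write ``lineage;path<TAB>count`` rows, one per distinct lineage."""
    counts: Dict[str, int] = {}
    for sc in scored:
        path = ";".join(
            tree.name.get(t, str(t)) for t in tree.lineage(sc.record.taxid)
        )
        counts[path] = counts.get(path, 0) + 1
    out.write("lineage\tcount\n")
    for path in sorted(counts):
        out.write(f"{path}\t{counts[path]}\n")
    return len(counts)
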