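"""Per-read classification scores, host filtering, contaminant annotation
and per-sample aggregation.

From each read's k-mer string three tallies are computed:

* ``tot_kmers`` — the total number of k-mers analysed in the read, i.e. the
  sum of every token count including unmatched (``0:``) and ambiguous
  (``A:``) runs;
* ``sum_class_kmers`` — the number of classified k-mers (numeric taxid other
  than zero; ambiguous runs count as unclassified);
* ``max_kmers`` — the number of k-mers supporting the assigned taxid.

The headline confidence score is ``taxid_score = max_kmers / tot_kmers``; an
alternative ``alt_score = max_kmers / sum_class_kmers`` expresses the
assigned taxid's share among classified k-mers only.  Zero denominators give
score 0 so downstream stratification is total.

``max_kmers`` counts, by default, only k-mers whose taxid equals the
assignment exactly (strict mode).  Externally produced Kraken2 files can
assign an ancestor of every token taxid via weighted path scoring, which
would make the strict count 0; ``lineage_mode=True`` then counts k-mers on
the assigned taxid's subtree instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .kmer_classifier import ClassificationRecord
from .taxonomy import ContaminantList, TaxonomyTree

__all__ = [
    "ScoredClassification",
    "SampleSummary",
    "DEFAULT_BIN_EDGES",
    "score_record",
    "annotate",
    "summarize_sample",
    "stratify_by_score",
]

logger = logging.getLogger(__name__)

DEFAULT_BIN_EDGES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)

# per-record anomaly warnings are capped to avoid flooding logs
_MAX_ANOMALY_WARNINGS = 10
_anomaly_warnings = 0


def _warn_capped(msg: str, *args) -> None:
    global _anomaly_warnings
    _anomaly_warnings += 1
    if _anomaly_warnings <= _MAX_ANOMALY_WARNINGS:
        logger.warning(msg, *args)
        if _anomaly_warnings == _MAX_ANOMALY_WARNINGS:
            logger.warning("further per-record warnings suppressed")


@dataclass(frozen=True)
class ScoredClassification:
    record: ClassificationRecord
    tot_kmers: int
    max_kmers: int
    sum_class_kmers: int
    taxid_score: float
    alt_score: float
    genus: Optional[int] = None
    genus_name: Optional[str] = None
    contaminant_status: Optional[str] = None  # "flagged" | "blacklisted" | None


def score_record(
    rec: ClassificationRecord,
    tree: Optional[TaxonomyTree] = None,
    lineage_mode: bool = False,
) -> ScoredClassification:
    """Compute the k-mer tallies and both scores for one record."""
    tot = 0
    sum_class = 0
    max_k = 0
    lineage_taxids: Optional[set] = None
    if lineage_mode and tree is not None and rec.taxid in tree:
        lineage_taxids = {
            t for t in tree.parent if rec.taxid in set(tree.lineage(t))
        }
    for label, count in rec.tokens():
        tot += count
        if label == "A" or label == "0":
            continue
        t = int(label)
        sum_class += count
        if lineage_taxids is not None:
            if t in lineage_taxids:
                max_k += count
        elif t == rec.taxid:
            max_k += count
    if rec.taxid != 0 and max_k == 0:
        _warn_capped(
            "read %s: assigned taxid %d has no supporting k-mer token "
            "(foreign assignment rule?); max_kmers = 0",
            rec.qname, rec.taxid,
        )
    taxid_score = max_k / tot if tot > 0 else 0.0
    alt_score = max_k / sum_class if sum_class > 0 else 0.0
    return ScoredClassification(
        record=rec,
        tot_kmers=tot,
        max_kmers=max_k,
        sum_class_kmers=sum_class,
        taxid_score=taxid_score,
        alt_score=alt_score,
    )


def annotate(
    sc: ScoredClassification,
    tree: TaxonomyTree,
    contaminants: ContaminantList,
    host: int,
) -> Optional[ScoredClassification]:
    """Attach genus and contaminant status; return None for discarded reads.

    Unclassified reads and reads on the host lineage (the host itself, its
    ancestors or descendants) are discarded.
    """
    taxid = sc.record.taxid
    if taxid == 0:
        return None
    if taxid not in tree:
        raise KeyError(f"read {sc.record.qname}: taxid {taxid} absent from taxonomy")
    if tree.is_host_lineage(taxid, host):
        return None
    genus = tree.genus_of(taxid)
    genus_name = tree.name.get(genus) if genus is not None else None
    status = contaminants.status_of(genus_name)
    return replace(sc, genus=genus, genus_name=genus_name, contaminant_status=status)


@dataclass
class SampleSummary:
    sample: str
    total_reads: int
    #: category -> number of raw extracted reads
    category_counts: Dict[str, int]
    #: category -> number of kept (non-host, non-blacklisted, genus-level) reads
    kept_counts: Dict[str, int]
    #: category -> kept / total_reads
    microbial_proportion: Dict[str, float]
    #: genus name -> (read count, mean taxid_score, contaminant status)
    genus_table: Dict[str, Tuple[int, float, Optional[str]]]


def summarize_sample(
    sample: str,
    total_reads: int,
    scored_by_category: Dict[str, Sequence[ScoredClassification]],
    drop_flagged: bool = False,
) -> SampleSummary:
    """Aggregate annotated reads of one sample into headline statistics.

    The microbial proportion per category counts reads with a genus-level
    assignment, excluding host-lineage reads (already discarded upstream)
    and blacklisted genera; flagged genera are retained unless
    ``drop_flagged`` is set.
    """
    if total_reads <= 0:
        raise ValueError(f"sample {sample}: total_reads must be positive")
    kept_counts: Dict[str, int] = {}
    proportions: Dict[str, float] = {}
    genus_acc: Dict[str, List[float]] = {}
    genus_status: Dict[str, Optional[str]] = {}
    category_counts = {cat: len(recs) for cat, recs in scored_by_category.items()}
    for cat, recs in scored_by_category.items():
        kept = 0
        for sc in recs:
            if sc.genus is None:
                continue
            if sc.contaminant_status == "blacklisted":
                continue
            if drop_flagged and sc.contaminant_status == "flagged":
                continue
            kept += 1
            gname = sc.genus_name or str(sc.genus)
            genus_acc.setdefault(gname, []).append(sc.taxid_score)
            genus_status[gname] = sc.contaminant_status
        kept_counts[cat] = kept
        proportions[cat] = kept / total_reads
    genus_table = {
        g: (len(scores), sum(scores) / len(scores), genus_status[g])
        for g, scores in genus_acc.items()
    }
    return SampleSummary(
        sample=sample,
        total_reads=total_reads,
        category_counts=category_counts,
        kept_counts=kept_counts,
        microbial_proportion=proportions,
        genus_table=genus_table,
    )


def stratify_by_score(
    scored: Iterable[ScoredClassification],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> List[Dict]:
    """Cross-tabulate contaminant status against taxid_score bins.

    Bins are half-open ``[e_i, e_{i+1})``; the last bin is closed at its
    upper edge so a score of exactly 1.0 is counted.  Returns one dict per
    bin with counts and fractions of flagged / blacklisted / clean reads
    (fractions of an empty bin are 0).
    """
    edges = list(bin_edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin_edges must be strictly increasing")
    if edges[0] < 0.0 or edges[-1] > 1.0:
        raise ValueError("bin_edges must lie within [0, 1]")
    nbins = len(edges) - 1
    rows = [
        {"bin_low": edges[i], "bin_high": edges[i + 1],
         "flagged": 0, "blacklisted": 0, "none": 0}
        for i in range(nbins)
    ]
    for sc in scored:
        s = sc.taxid_score
        if s < edges[0] or s > edges[-1]:
            continue
        idx = nbins - 1
        for i in range(nbins):
            if edges[i] <= s < edges[i + 1]:
                idx = i
                break
        key = sc.contaminant_status or "none"
        rows[idx][key] += 1
    for row in rows:
        total = row["flagged"] + row["blacklisted"] + row["none"]
        row["total"] = total
        for key in ("flagged", "blacklisted", "none"):
            row[f"{key}_fraction"] = row[key] / total if total else 0.0
        row["contaminant_fraction"] = (
            (row["flagged"] + row["blacklisted"]) / total if total else 0.0
        )
    return rows
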