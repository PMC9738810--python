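"""Candidate integration loci from mapped mates of microbially classified reads.

Each single_unmapped read that survived classification and filtering carries
the genomic coordinate of its mapped mate; mates of pairs spanning a real
integration junction scatter within roughly one insert size of the junction.
Single-linkage clustering per chromosome (join two positions iff their
distance is at most ``window``) groups them into candidate loci; clusters
with fewer than ``min_support`` reads are discarded.  Candidates report
their full genus composition — a mixed-genus locus is a real ambiguity
signal and is not resolved automatically.

Intervals are 1-based closed, spanning the min..max member positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, TextIO, Tuple

from .sam_extract import MatePosition
from .scoring import ScoredClassification

__all__ = [
    "IntegrationCandidate",
    "DEFAULT_WINDOW",
    "DEFAULT_MIN_SUPPORT",
    "merge_coordinates",
    "cluster_sites",
    "write_sites_bed",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 1000
DEFAULT_MIN_SUPPORT = 2


@dataclass(frozen=True)
class IntegrationCandidate:
    chrom: str
    start: int  # 1-based closed
    end: int
    support: int
    genera: Dict[str, int]
    mean_score: float

    @property
    def top_genus(self) -> str:
        return max(self.genera.items(), key=lambda kv: (kv[1], kv[0]))[0]


def merge_coordinates(
    scored: Sequence[ScoredClassification],
    mates: Sequence[MatePosition],
) -> List[Tuple[ScoredClassification, MatePosition]]:
    """Inner-join kept classifications with mate positions on read id.

    Unmatched rows on either side are dropped (counts logged); a duplicate
    read id on either side is an error, since primary-alignment filtering
    should have removed multi-records.
    """
    by_qname: Dict[str, MatePosition] = {}
    for m in mates:
        if m.qname in by_qname:
            raise ValueError(f"duplicate read id {m.qname!r} in mate positions")
        by_qname[m.qname] = m
    seen: set = set()
    merged: List[Tuple[ScoredClassification, MatePosition]] = []
    for sc in scored:
        qname = sc.record.qname
        if qname in seen:
            raise ValueError(f"duplicate read id {qname!r} in classifications")
        seen.add(qname)
        mate = by_qname.get(qname)
        if mate is not None:
            merged.append((sc, mate))
    dropped_scored = len(scored) - len(merged)
    dropped_mates = len(mates) - len(merged)
    if dropped_scored or dropped_mates:
        logger.info(
            "coordinate merge: %d classified reads without mate position, "
            "%d mate positions without kept classification",
            dropped_scored, dropped_mates,
        )
    return merged


def cluster_sites(
    merged: Sequence[Tuple[ScoredClassification, MatePosition]],
    window: int = DEFAULT_WINDOW,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> List[IntegrationCandidate]:
    """Single-linkage clustering of mate positions into candidate loci."""
    if window <= 0:
        raise ValueError("window must be positive")
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    by_chrom: Dict[str, List[Tuple[int, ScoredClassification]]] = {}
    for sc, mate in merged:
        by_chrom.setdefault(mate.mate_chrom, []).append((mate.mate_pos, sc))
    candidates: List[IntegrationCandidate] = []
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda t: t[0])
        cluster: List[Tuple[int, ScoredClassification]] = []
        for pos, sc in members:
            if cluster and pos - cluster[-1][0] > window:
                candidates.extend(_finalize(chrom, cluster, min_support))
                cluster = []
            cluster.append((pos, sc))
        if cluster:
            candidates.extend(_finalize(chrom, cluster, min_support))
    candidates.sort(key=lambda c: (c.chrom, c.start))
    return candidates


def _finalize(
    chrom: str,
    cluster: List[Tuple[int, ScoredClassification]],
    min_support: int,
) -> List[IntegrationCandidate]:
    if len(cluster) < min_support:
        return []
    positions = [pos for pos, _ in cluster]
    genera: Dict[str, int] = {}
    scores = []
    for _, sc in cluster:
        gname = sc.genus_name or (str(sc.genus) if sc.genus is not None else "unassigned")
        genera[gname] = genera.get(gname, 0) + 1
        scores.append(sc.taxid_score)
    return [
        IntegrationCandidate(
            chrom=chrom,
            start=min(positions),
            end=max(positions),
            support=len(cluster),
            genera=genera,
            mean_score=sum(scores) / len(scores),
        )
    ]


def write_sites_bed(candidates: Sequence[IntegrationCandidate], out: TextIO) -> int:
    """Write candidates as a BED-like TSV (1-based closed coordinates)."""
    out.write("# coordinates are 1-based closed\n")
    out.write("chrom\tstart\tend\tsupport\ttop_genus\tmean_score\n")
    for c in candidates:
        out.write(
            f"{c.chrom}\t{c.start}\t{c.end}\t{c.support}\t{c.top_genus}"
            f"\t{c.mean_score:.4f}\n"
        )
    return len(candidates)
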