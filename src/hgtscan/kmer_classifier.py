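"""Exact k-mer → LCA classifier speaking the Kraken-style per-read dialect.

Database building: every canonical k-mer (lexicographic minimum of a k-mer
and its reverse complement) of every library genome is stored with the
lowest common ancestor of all taxids whose genomes contain it, so a k-mer
shared between two sibling species points at their genus.  K-mers spanning
non-ACGT characters are skipped.

Classification: each of a read's L−k+1 windows is looked up (0 when absent,
an ``A`` label when the window contains an ambiguous base); the consecutive
labels are run-length encoded into the familiar ``taxid:count`` k-mer string,
and the read is assigned the taxid with the highest total supporting k-mer
count.  Ties are broken by the LCA of the tied taxids.  Reads with no
matching window — or shorter than k, which get the single token ``0:0`` —
are unclassified (status ``U``, taxid 0).

This is deliberately the simple max-count assignment rule (not a weighted
root-to-leaf path score) because the downstream per-read scores are defined
in terms of k-mers supporting the single assigned taxid; externally produced
Kraken2 files, whose assignments may differ, are still parsed faithfully.
No minimizers, no probabilistic tables: exact matching at desk scale.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, TextIO, Tuple, Union

from Bio import SeqIO

from .taxonomy import TaxonomyTree

__all__ = [
    "KmerIndex",
    "ClassificationRecord",
    "KrakenFormatError",
    "DEFAULT_K",
    "build_index",
    "classify_read",
    "write_kraken_output",
    "parse_kraken_output",
    "write_kraken_report",
]

DEFAULT_K = 35

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_TAXID_HEADER_RE = re.compile(r"\|kraken:taxid\|(\d+)")
_TOKEN_RE = re.compile(r"^(\d+|A):(\d+)$")


class KrakenFormatError(ValueError):
    pass


def canonical_kmer(kmer: str) -> str:
    """Lexicographic min of a k-mer and its reverse complement."""
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


@dataclass
class KmerIndex:
    """Canonical k-mer → LCA taxid map over a set of source genomes."""

    k: int
    entries: Dict[str, int] = field(default_factory=dict)
    source_taxids: set = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, kmer: str) -> int:
        """Taxid for a k-mer (canonicalised here), 0 if absent."""
        return self.entries.get(canonical_kmer(kmer), 0)


@dataclass(frozen=True)
class ClassificationRecord:
    """One Kraken-format per-read result line."""

    status: str  # "C" or "U"
    qname: str
    taxid: int  # 0 iff status == "U"
    read_length: int
    kmer_string: str  # space-separated taxid:count tokens

    def tokens(self) -> List[Tuple[str, int]]:
        """Parse the kmer_string into (label, count) pairs; label is "0", "A" or a taxid."""
        out = []
        for tok in self.kmer_string.split():
            m = _TOKEN_RE.match(tok)
            if not m:
                raise KrakenFormatError(f"malformed k-mer token {tok!r}")
            out.append((m.group(1), int(m.group(2))))
        return out


def _taxid_from_header(header: str, seqid_map: Optional[Dict[str, int]]) -> int:
    m = _TAXID_HEADER_RE.search(header)
    if m:
        return int(m.group(1))
    seqid = header.split()[0]
    if seqid_map and seqid in seqid_map:
        return seqid_map[seqid]
    raise KrakenFormatError(
        f"sequence {seqid!r}: header lacks |kraken:taxid|<int> and no seqid map entry"
    )


def build_index(
    tree: TaxonomyTree,
    libraries: Sequence[Union[str, Path]],
    k: int = DEFAULT_K,
    seqid_map: Optional[Dict[str, int]] = None,
) -> KmerIndex:
    """Build the canonical-k-mer → LCA database from taxid-labelled FASTA files.

    Each sequence's taxid comes from a ``|kraken:taxid|<int>`` header tag or
    the optional ``seqid_map``.  A k-mer seen under several taxids is stored
    with their LCA (updated incrementally, which equals the fold of pairwise
    LCAs and is therefore independent of library order).
    """
    if k < 3 or k % 2 == 0:
        raise ValueError(f"k must be an odd integer >= 3, got {k}")
    index = KmerIndex(k=k)
    for lib in libraries:
        for rec in SeqIO.parse(str(lib), "fasta"):
            taxid = _taxid_from_header(rec.description, seqid_map)
            if taxid not in tree:
                raise KrakenFormatError(
                    f"sequence {rec.id}: taxid {taxid} absent from taxonomy"
                )
            index.source_taxids.add(taxid)
            seq = str(rec.seq).upper()
            seen: set = set()  # this genome's k-mers, counted once each
            for i in range(len(seq) - k + 1):
                window = seq[i : i + k]
                if not _is_acgt(window):
                    continue
                seen.add(canonical_kmer(window))
            for kmer in seen:
                prev = index.entries.get(kmer)
                index.entries[kmer] = taxid if prev is None else tree.lca(prev, taxid)
    return index


def _is_acgt(window: str) -> bool:
    return all(c in "ACGT" for c in window)


def classify_read(
    index: KmerIndex,
    tree: TaxonomyTree,
    qname: str,
    seq: str,
) -> ClassificationRecord:
    """Classify one read by sliding-window k-mer lookup and max-count vote."""
    seq = seq.upper()
    L = len(seq)
    k = index.k
    if L < k:
        return ClassificationRecord("U", qname, 0, L, "0:0")

    labels: List[str] = []
    for i in range(L - k + 1):
        window = seq[i : i + k]
        if not _is_acgt(window):
            labels.append("A")
        else:
            labels.append(str(index.lookup(window)))

    kmer_string = _run_length_encode(labels)

    counts: Dict[int, int] = {}
    for label in labels:
        if label in ("A", "0"):
            continue
        t = int(label)
        counts[t] = counts.get(t, 0) + 1
    if not counts:
        return ClassificationRecord("U", qname, 0, L, kmer_string)
    best = max(counts.values())
    tied = sorted(t for t, c in counts.items() if c == best)
    taxid = tied[0] if len(tied) == 1 else tree.lca_of(tied)
    return ClassificationRecord("C", qname, taxid, L, kmer_string)


def _run_length_encode(labels: Sequence[str]) -> str:
    parts: List[str] = []
    prev: Optional[str] = None
    run = 0
    for label in labels:
        if label == prev:
            run += 1
        else:
            if prev is not None:
                parts.append(f"{prev}:{run}")
            prev, run = label, 1
    if prev is not None:
        parts.append(f"{prev}:{run}")
    return " ".join(parts)


# ---------------------------------------------------------------------------
# Kraken per-read dialect I/O

def write_kraken_output(records: Iterable[ClassificationRecord], out: TextIO) -> int:
    """Write records as 5-field tab-separated Kraken-style per-read lines."""
    n = 0
    for rec in records:
        out.write(
            f"{rec.status}\t{rec.qname}\t{rec.taxid}\t{rec.read_length}\t{rec.kmer_string}\n"
        )
        n += 1
    return n


def parse_kraken_output(path: Union[str, Path]) -> Iterator[ClassificationRecord]:
    """Parse Kraken-style per-read output, splitting paired lines into two records.

    A paired line carries ``len1|len2`` in the length column and a ``|:|``
    separator inside the k-mer string; both halves share the read id.
    """
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise KrakenFormatError(
                    f"{path}: line {lineno}: expected 5 tab-separated fields"
                )
            status, qname, taxid_s, length_s, kmer_string = fields[:5]
            if status not in ("C", "U"):
                raise KrakenFormatError(
                    f"{path}: line {lineno}: bad status {status!r}"
                )
            try:
                taxid = int(taxid_s)
            except ValueError:
                raise KrakenFormatError(
                    f"{path}: line {lineno}: bad taxid {taxid_s!r}"
                ) from None
            if "|" in length_s:
                lengths = length_s.split("|")
                halves = [h.strip() for h in kmer_string.split("|:|")]
                if len(lengths) != 2 or len(halves) != 2:
                    raise KrakenFormatError(
                        f"{path}: line {lineno}: malformed paired-line record"
                    )
                for length, half in zip(lengths, halves):
                    yield _validated_record(
                        status, qname, taxid, int(length), half, path, lineno
                    )
            else:
                yield _validated_record(
                    status, qname, taxid, int(length_s), kmer_string, path, lineno
                )


def _validated_record(
    status: str, qname: str, taxid: int, length: int, kmer_string: str,
    path, lineno: int,
) -> ClassificationRecord:
    for tok in kmer_string.split():
        if not _TOKEN_RE.match(tok):
            raise KrakenFormatError(
                f"{path}: line {lineno}: malformed k-mer token {tok!r}"
            )
    return ClassificationRecord(status, qname, taxid, length, kmer_string)


def write_kraken_report(
    records: Iterable[ClassificationRecord],
    tree: TaxonomyTree,
    out: TextIO,
) -> int:
    """Write a Kraken-style summary report (percentage, clade count, direct
    count, rank code, taxid, indented name), one row per observed clade."""
    direct: Dict[int, int] = {}
    unclassified = 0
    total = 0
    for rec in records:
        total += 1
        if rec.status == "U" or rec.taxid == 0:
            unclassified += 1
        else:
            direct[rec.taxid] = direct.get(rec.taxid, 0) + 1
    clade: Dict[int, int] = {}
    for taxid, n in direct.items():
        for anc in tree.lineage(taxid):
            clade[anc] = clade.get(anc, 0) + n

    rank_codes = {"root": "R", "superkingdom": "D", "kingdom": "K", "phylum": "P",
                  "class": "C", "order": "O", "family": "F", "genus": "G",
                  "species": "S"}
    rows = 0
    if total:
        out.write(
            f"{100.0 * unclassified / total:6.2f}\t{unclassified}\t{unclassified}"
            f"\tU\t0\tunclassified\n"
        )
        rows += 1
    for taxid in sorted(clade, key=lambda t: (tree.depth(t), t)):
        pct = 100.0 * clade[taxid] / total if total else 0.0
        code = rank_codes.get(tree.rank.get(taxid, ""), "-")
        indent = "  " * tree.depth(taxid)
        name = tree.name.get(taxid, str(taxid))
        out.write(
            f"{pct:6.2f}\t{clade[taxid]}\t{direct.get(taxid, 0)}\t{code}\t{taxid}"
            f"\t{indent}{name}\n"
        )
        rows += 1
    return rows
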