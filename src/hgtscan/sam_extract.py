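"""Extraction of unmapped-read categories from aligned paired-end data.

A host-aligned BAM/SAM contains two kinds of read pairs that are interesting
for horizontal-gene-transfer screening:

* ``both_unmapped`` — paired reads where neither mate aligned to the host
  (flag bits 0x1, 0x4 and 0x8 all set; ``samtools view -f 13``), candidate
  fully-foreign fragments;
* ``single_unmapped`` — an unmapped read whose mate did align
  (bits 0x1 and 0x4 set, 0x8 unset), candidate junction-spanning fragments
  whose mapped mate pins a putative integration locus on the host genome.

Secondary alignments (bit 0x100) are excluded from both categories.  The two
categories are disjoint: a ``-f 5`` filter alone would also match both-unmapped
records, so single_unmapped additionally requires the mate-unmapped bit clear
(equivalent to ``samtools view -f 5 -F 264``).

Coordinates are 1-based throughout, as in SAM.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, TextIO, Union

__all__ = [
    "AlignmentRecord",
    "UnmappedCategory",
    "MatePosition",
    "SamFormatError",
    "BOTH_UNMAPPED_INCLUDE_FLAG",
    "SINGLE_UNMAPPED_INCLUDE_FLAG",
    "EXCLUDE_FLAG",
    "read_alignments",
    "categorize",
    "extract_mate_positions",
    "to_fastq",
    "write_mate_positions",
]

# SAM bitwise-flag constants
FLAG_PAIRED = 0x1
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_SECONDARY = 0x100

#: include-filter for pairs with both mates unmapped (``samtools view -f 13``)
BOTH_UNMAPPED_INCLUDE_FLAG = FLAG_PAIRED | FLAG_UNMAPPED | FLAG_MATE_UNMAPPED
#: include-filter for unmapped reads with a mapped mate (``samtools view -f 5``)
SINGLE_UNMAPPED_INCLUDE_FLAG = FLAG_PAIRED | FLAG_UNMAPPED
#: exclude-filter for non-primary alignments (``samtools view -F 256``)
EXCLUDE_FLAG = FLAG_SECONDARY


class SamFormatError(ValueError):
    """A SAM body line that cannot be interpreted, annotated with its line number."""


class UnmappedCategory(enum.Enum):
    BOTH_UNMAPPED = "both_unmapped"
    SINGLE_UNMAPPED = "single_unmapped"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class AlignmentRecord:
    """One SAM alignment line (the fields this tool consumes)."""

    qname: str
    flag: int
    rname: Optional[str]  # None encodes "*"
    pos: Optional[int]    # 1-based; None encodes 0/"*"
    rnext: Optional[str]
    pnext: Optional[int]
    seq: str
    qual: str

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)


@dataclass(frozen=True)
class MatePosition:
    """Mapped-mate coordinate of a single_unmapped read (QNAME, RNAME, PNEXT)."""

    qname: str
    mate_chrom: str
    mate_pos: int  # 1-based


def _none_if_star(field: str) -> Optional[str]:
    return None if field == "*" else field


def _parse_sam_line(line: str, lineno: int) -> AlignmentRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 11:
        raise SamFormatError(
            f"line {lineno}: expected >=11 tab-separated fields, got {len(fields)}"
        )
    try:
        flag = int(fields[1])
        pos = int(fields[3])
        pnext = int(fields[7])
    except ValueError as exc:
        raise SamFormatError(f"line {lineno}: non-integer numeric field: {exc}") from exc
    return AlignmentRecord(
        qname=fields[0],
        flag=flag,
        rname=_none_if_star(fields[2]),
        pos=pos if pos > 0 else None,
        rnext=_none_if_star(fields[6]),
        pnext=pnext if pnext > 0 else None,
        seq=fields[9],
        qual=fields[10],
    )


def _is_bam(path: Path) -> bool:
    try:
        with open(path, "rb") as fh:
            magic = fh.read(2)
    except OSError:
        return False
    return magic == b"\x1f\x8b"  # BGZF container


def read_alignments(path: Union[str, Path]) -> Iterator[AlignmentRecord]:
    """Yield every alignment record of a SAM or BAM file, in file order.

    Plain-text SAM is parsed directly so malformed body lines raise
    :class:`SamFormatError` naming the offending line; BAM is read through
    pysam.  Header lines are skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_bam(path):
        yield from _read_bam(path)
        return
    with open(path, "rt") as fh:
        yield from _read_sam_stream(fh)


def _read_sam_stream(fh: TextIO) -> Iterator[AlignmentRecord]:
    for lineno, line in enumerate(fh, start=1):
        if line.startswith("@") or not line.strip():
            continue
        yield _parse_sam_line(line, lineno)


def _read_bam(path: Path) -> Iterator[AlignmentRecord]:
    import pysam

    with pysam.AlignmentFile(str(path), "rb", check_sq=False) as bam:
        for aln in bam.fetch(until_eof=True):
            yield AlignmentRecord(
                qname=aln.query_name or "",
                flag=aln.flag,
                rname=aln.reference_name,
                pos=None if aln.reference_start is None or aln.reference_start < 0
                else aln.reference_start + 1,
                rnext=aln.next_reference_name,
                pnext=None if aln.next_reference_start is None or aln.next_reference_start < 0
                else aln.next_reference_start + 1,
                seq=aln.query_sequence or "",
                qual="".join(chr(q + 33) for q in aln.query_qualities)
                if aln.query_qualities is not None else "*",
            )


def categorize(record: AlignmentRecord) -> Optional[UnmappedCategory]:
    """Assign a record to one of the two unmapped categories, or ``None``.

    both_unmapped   iff (flag & 13) == 13 and bit 0x100 unset;
    single_unmapped iff (flag & 5) == 5, bit 0x8 unset and bit 0x100 unset.
    Total on valid records; the categories are disjoint by construction.
    """
    flag = record.flag
    if flag & EXCLUDE_FLAG:
        return None
    if (flag & BOTH_UNMAPPED_INCLUDE_FLAG) == BOTH_UNMAPPED_INCLUDE_FLAG:
        return UnmappedCategory.BOTH_UNMAPPED
    if (flag & SINGLE_UNMAPPED_INCLUDE_FLAG) == SINGLE_UNMAPPED_INCLUDE_FLAG:
        # mate-unmapped bit is known clear here, else the first branch matched
        return UnmappedCategory.SINGLE_UNMAPPED
    return None


def extract_mate_positions(
    records: Iterable[AlignmentRecord],
) -> list[MatePosition]:
    """Project single_unmapped records onto their mapped mate's coordinates.

    Mirrors ``samtools view | cut -f 1,3,8``: QNAME, RNAME (aligners co-place
    an unmapped read on its mate's chromosome) and PNEXT.  When RNAME is "*"
    (a SAM dialect that does not co-place), RNEXT is used instead.  Records
    with no usable mate position are dropped.
    """
    out: list[MatePosition] = []
    for rec in records:
        chrom = rec.rname if rec.rname is not None else rec.rnext
        if chrom is None or rec.pnext is None:
            logging.getLogger(__name__).warning(
                "read %s: mate flagged mapped but has no usable coordinate; dropped",
                rec.qname,
            )
            continue
        out.append(MatePosition(qname=rec.qname, mate_chrom=chrom, mate_pos=rec.pnext))
    return out


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def to_fastq(records: Iterable[AlignmentRecord], out: TextIO) -> int:
    """Write records as 4-line FASTQ entries; returns the number written.

    Reverse-flagged records (bit 0x10) are reverse-complemented (and their
    quality string reversed) so the emitted sequence is in original read
    orientation.
    """
    n = 0
    for rec in records:
        if not rec.seq or rec.seq == "*":
            raise ValueError(f"record {rec.qname}: empty sequence cannot be written as FASTQ")
        qual = rec.qual if rec.qual != "*" else "I" * len(rec.seq)
        if len(qual) != len(rec.seq):
            raise ValueError(
                f"record {rec.qname}: seq length {len(rec.seq)} != qual length {len(qual)}"
            )
        seq = rec.seq
        if rec.is_reverse:
            seq = reverse_complement(seq)
            qual = qual[::-1]
        out.write(f"@{rec.qname}\n{seq}\n+\n{qual}\n")
        n += 1
    return n


def write_mate_positions(mates: Iterable[MatePosition], out: TextIO) -> int:
    """Write a mate-position TSV with header ``read_id  chrom  pos`` (1-based)."""
    out.write("read_id\tchrom\tpos\n")
    n = 0
    for m in mates:
        out.write(f"{m.qname}\t{m.mate_chrom}\t{m.mate_pos}\n")
        n += 1
    return n
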