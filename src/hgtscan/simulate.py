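"""Synthetic fixtures: toy taxonomy, genomes and aligner-style SAM output
with planted HGT integrations.

The simulator writes the *output* of a short-read aligner directly — flags
and coordinates follow the SAM conventions of bwa/samtools, including
co-placement of an unmapped read at its mapped mate's coordinate — so no
external binaries are needed.  Genomes are i.i.d. uniform ACGT, which makes
k-mer collisions between genomes vanishingly rare at k ≥ 21 and gives the
classifier a unique-k-mer regime.

Four pair origins are emitted:

* ``host`` — proper pairs mapped to the host chromosome (flags 99/147);
* ``microbe`` — both mates unmapped, drawn from a clean microbial genome
  (flags 77/141, RNAME ``*``);
* ``junction`` — a pair spanning a planted integration: the host-side mate
  maps at its true position (flag 73), the microbial mate is unmapped and
  co-placed (flag 133);
* ``contaminant`` — both mates unmapped, drawn from flagged/blacklisted
  genus genomes.

Quality strings are constant ``I``; base errors are substitution-only.
A truth table records every pair's origin and the planted junctions.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from .kmer_classifier import ClassificationRecord
from .sam_extract import reverse_complement
from .scoring import ScoredClassification, annotate, score_record
from .taxonomy import ContaminantList, TaxonomyTree

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "FixturePaths",
    "make_taxonomy_and_genomes",
    "simulate_sam",
    "simulate_fixture",
    "simulate_scored_mixture",
]

HOST_CHROM = "chr1"

# fixed toy phylogeny: ids follow NCBI where a real counterpart exists
ROOT, BACTERIA, EUKARYOTA = 1, 2, 2759
HOST_GENUS, HOST_SPECIES = 9605, 9606
GENUS_CLEAN, GENUS_BLACKLISTED, GENUS_FLAGGED = 953, 48736, 561
SPECIES_CLEAN, SPECIES_BLACKLISTED, SPECIES_FLAGGED = 955, 329, 562

_FIXED_NODES: List[Tuple[int, int, str, str]] = [
    (ROOT, ROOT, "root", "root"),
    (BACTERIA, ROOT, "superkingdom", "Bacteria"),
    (EUKARYOTA, ROOT, "superkingdom", "Eukaryota"),
    (HOST_GENUS, EUKARYOTA, "genus", "Homo"),
    (HOST_SPECIES, HOST_GENUS, "species", "Homo sapiens"),
    (GENUS_CLEAN, BACTERIA, "genus", "Wolbachia"),
    (GENUS_BLACKLISTED, BACTERIA, "genus", "Ralstonia"),
    (GENUS_FLAGGED, BACTERIA, "genus", "Escherichia"),
    (SPECIES_CLEAN, GENUS_CLEAN, "species", "Wolbachia pipientis"),
    (SPECIES_BLACKLISTED, GENUS_BLACKLISTED, "species", "Ralstonia pickettii"),
    (SPECIES_FLAGGED, GENUS_FLAGGED, "species", "Escherichia coli"),
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic dataset."""

    seed: int = 0
    host_length: int = 50_000
    n_microbes: int = 3
    microbe_length: int = 20_000
    n_pairs: int = 1000
    read_length: int = 100
    insert_mean: int = 300
    insert_sd: int = 30
    n_integrations: int = 1
    reads_per_integration: int = 6
    contaminant_fraction: float = 0.10
    microbe_fraction: float = 0.10
    error_rate: float = 0.0

    def validate(self, k: int = 31) -> None:
        if self.read_length < k:
            raise ValueError("read_length must be >= classifier k")
        if self.insert_mean < 2 * self.read_length:
            raise ValueError("insert_mean must be >= 2 * read_length")
        for frac in (self.contaminant_fraction, self.microbe_fraction, self.error_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class TruthTable:
    """Ground truth of a simulation run."""

    #: qname -> origin label ("host", "microbe_<taxid>", "junction_<i>",
    #: "contaminant_<taxid>")
    origins: Dict[str, str] = field(default_factory=dict)
    #: planted junctions: (chrom, 1-based position, microbe taxid)
    integrations: List[Tuple[str, int, int]] = field(default_factory=list)

    def count(self, prefix: str) -> int:
        return sum(1 for o in self.origins.values() if o.startswith(prefix))


@dataclass
class FixturePaths:
    outdir: Path
    nodes_tsv: Path
    nodes_dmp: Path
    names_dmp: Path
    library_fasta: Path
    contaminants_tsv: Path
    sam: Path
    fastq1: Path
    fastq2: Path
    truth_tsv: Path


def _random_genome(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def build_toy_taxonomy(n_microbes: int = 3) -> Tuple[TaxonomyTree, List[int]]:
    """The fixed toy tree plus synthetic extra species for n_microbes > 3.

    Microbial species are assigned round-robin to the clean, blacklisted and
    flagged genera; returns the tree and the list of microbial species taxids
    in assignment order (clean first).
    """
    tree = TaxonomyTree()
    for taxid, parent, rank, name in _FIXED_NODES:
        tree.add_node(taxid, parent, rank, name)
    base_species = [SPECIES_CLEAN, SPECIES_BLACKLISTED, SPECIES_FLAGGED]
    genera = [GENUS_CLEAN, GENUS_BLACKLISTED, GENUS_FLAGGED]
    species = list(base_species[:n_microbes])
    next_id = 100_001
    while len(species) < n_microbes:
        i = len(species)
        genus = genera[i % 3]
        tree.add_node(next_id, genus, "species", f"synthetic species {next_id}")
        species.append(next_id)
        next_id += 1
    tree.validate()
    return tree, species


def make_taxonomy_and_genomes(
    cfg: SimulationConfig, outdir: Path
) -> Tuple[TaxonomyTree, Dict[int, str], FixturePaths]:
    """Write taxonomy (both dialects), FASTA library and contaminant list.

    Returns the in-memory tree, the taxid → genome map (host included) and
    the file locations.  Deterministic in ``cfg.seed``.
    """
    cfg.validate(k=3)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(cfg.seed)
    tree, species = build_toy_taxonomy(cfg.n_microbes)

    genomes: Dict[int, str] = {HOST_SPECIES: _random_genome(rng, cfg.host_length)}
    for taxid in species:
        genomes[taxid] = _random_genome(rng, cfg.microbe_length)

    paths = FixturePaths(
        outdir=outdir,
        nodes_tsv=outdir / "nodes.tsv",
        nodes_dmp=outdir / "nodes.dmp",
        names_dmp=outdir / "names.dmp",
        library_fasta=outdir / "library.fa",
        contaminants_tsv=outdir / "contaminants.tsv",
        sam=outdir / "aligned.sam",
        fastq1=outdir / "reads_1.fastq",
        fastq2=outdir / "reads_2.fastq",
        truth_tsv=outdir / "truth.tsv",
    )

    with open(paths.nodes_tsv, "wt") as fh:
        for taxid in sorted(tree.parent):
            fh.write(
                f"{taxid}\t{tree.parent[taxid]}\t{tree.rank[taxid]}"
                f"\t{tree.name.get(taxid, '')}\n"
            )
    with open(paths.nodes_dmp, "wt") as fh:
        for taxid in sorted(tree.parent):
            fh.write(f"{taxid}\t|\t{tree.parent[taxid]}\t|\t{tree.rank[taxid]}\t|\n")
    with open(paths.names_dmp, "wt") as fh:
        for taxid in sorted(tree.parent):
            fh.write(
                f"{taxid}\t|\t{tree.name.get(taxid, str(taxid))}\t|\t\t|"
                f"\tscientific name\t|\n"
            )
    with open(paths.library_fasta, "wt") as fh:
        for taxid in sorted(genomes):
            name = tree.name.get(taxid, str(taxid))
            fh.write(f">seq{taxid}|kraken:taxid|{taxid} {name}\n")
            seq = genomes[taxid]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    with open(paths.contaminants_tsv, "wt") as fh:
        fh.write("genus\tstatus\n")
        fh.write(f"{tree.name[GENUS_BLACKLISTED]}\tblacklisted\n")
        fh.write(f"{tree.name[GENUS_FLAGGED]}\tflagged\n")
    return tree, genomes, paths


def _mutate(rng: random.Random, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    bases = list(seq)
    for i, b in enumerate(bases):
        if rng.random() < error_rate:
            bases[i] = rng.choice([c for c in "ACGT" if c != b])
    return "".join(bases)


def _sam_line(qname, flag, rname, pos, mapq, cigar, rnext, pnext, tlen, seq, qual):
    return (
        f"{qname}\t{flag}\t{rname}\t{pos}\t{mapq}\t{cigar}\t{rnext}\t{pnext}"
        f"\t{tlen}\t{seq}\t{qual}\n"
    )


def simulate_sam(
    cfg: SimulationConfig,
    tree: TaxonomyTree,
    genomes: Dict[int, str],
    paths: FixturePaths,
) -> TruthTable:
    """Emit aligner-style SAM, paired FASTQ and the truth table.

    Pair budget: ``round(contaminant_fraction * n_pairs)`` contaminant pairs
    and ``round(microbe_fraction * n_pairs)`` clean both-unmapped microbial
    pairs; ``n_integrations * reads_per_integration`` junction pairs are
    added on top; the remainder of ``n_pairs`` is host pairs.
    """
    cfg.validate(k=3)
    rng = random.Random(cfg.seed + 1)  # distinct stream from genome generation
    truth = TruthTable()
    rl = cfg.read_length
    qual = "I" * rl
    host = genomes[HOST_SPECIES]
    microbe_taxids = [t for t in sorted(genomes) if t != HOST_SPECIES]
    clean_taxids = [t for t in microbe_taxids if tree.genus_of(t) == GENUS_CLEAN]
    contam_taxids = [t for t in microbe_taxids if tree.genus_of(t) != GENUS_CLEAN]

    n_contam = round(cfg.contaminant_fraction * cfg.n_pairs) if contam_taxids else 0
    n_microbe = round(cfg.microbe_fraction * cfg.n_pairs) if clean_taxids else 0
    n_host = max(cfg.n_pairs - n_contam - n_microbe, 0)

    # planted integrations: position on host chromosome plus a foreign insert
    inserts: List[Tuple[int, int, str]] = []  # (host pos, taxid, insert seq)
    for i in range(cfg.n_integrations):
        taxid = clean_taxids[i % len(clean_taxids)] if clean_taxids else microbe_taxids[0]
        donor = genomes[taxid]
        ins_len = min(5000, len(donor))
        start = rng.randrange(0, len(donor) - ins_len + 1)
        margin = cfg.insert_mean + 4 * cfg.insert_sd
        pos = rng.randrange(margin, len(host) - margin)
        inserts.append((pos, taxid, donor[start : start + ins_len]))
        truth.integrations.append((HOST_CHROM, pos + 1, taxid))  # 1-based

    sam_lines: List[str] = []
    fq1: List[str] = []
    fq2: List[str] = []

    def emit_fastq(qname: str, s1: str, s2: str) -> None:
        fq1.append(f"@{qname}/1\n{s1}\n+\n{qual}\n")
        fq2.append(f"@{qname}/2\n{s2}\n+\n{qual}\n")

    def frag_len() -> int:
        # truncated normal: fragments stay within 3 sd of the mean so mate
        # positions of junction pairs are provably near the planted site
        f = int(round(rng.gauss(cfg.insert_mean, cfg.insert_sd)))
        return min(max(2 * rl, f), cfg.insert_mean + 3 * cfg.insert_sd)

    serial = 0
    for _ in range(n_host):
        serial += 1
        qname = f"pair{serial:06d}"
        f = frag_len()
        start = rng.randrange(0, len(host) - f)
        frag = host[start : start + f]
        s1 = _mutate(rng, frag[:rl], cfg.error_rate)
        s2_fwd = _mutate(rng, frag[-rl:], cfg.error_rate)
        pos1 = start + 1
        pos2 = start + f - rl + 1
        # 99 = paired, proper, mate reverse, first; 147 = paired, proper, reverse, second
        sam_lines.append(_sam_line(qname, 99, HOST_CHROM, pos1, 60, f"{rl}M",
                                   "=", pos2, f, s1, qual))
        sam_lines.append(_sam_line(qname, 147, HOST_CHROM, pos2, 60, f"{rl}M",
                                   "=", pos1, -f, reverse_complement(s2_fwd), qual))
        emit_fastq(qname, s1, s2_fwd)
        truth.origins[qname] = "host"

    def emit_unmapped_pair(qname: str, genome: str, origin: str) -> None:
        f = min(frag_len(), len(genome))
        start = rng.randrange(0, len(genome) - f + 1)
        frag = genome[start : start + f]
        s1 = _mutate(rng, frag[:rl], cfg.error_rate)
        s2_fwd = _mutate(rng, frag[-rl:], cfg.error_rate)
        # 77 = paired, unmapped, mate unmapped, first; 141 = same, second
        sam_lines.append(_sam_line(qname, 77, "*", 0, 0, "*", "*", 0, 0, s1, qual))
        sam_lines.append(_sam_line(qname, 141, "*", 0, 0, "*", "*", 0, 0,
                                   reverse_complement(s2_fwd), qual))
        emit_fastq(qname, s1, s2_fwd)
        truth.origins[qname] = origin

    for i in range(n_microbe):
        serial += 1
        taxid = clean_taxids[i % len(clean_taxids)]
        emit_unmapped_pair(f"pair{serial:06d}", genomes[taxid], f"microbe_{taxid}")

    for i in range(n_contam):
        serial += 1
        taxid = contam_taxids[i % len(contam_taxids)]
        emit_unmapped_pair(f"pair{serial:06d}", genomes[taxid], f"contaminant_{taxid}")

    for idx, (pos, taxid, insert) in enumerate(inserts):
        for _ in range(cfg.reads_per_integration):
            serial += 1
            qname = f"pair{serial:06d}"
            f = frag_len()
            # fragment straddles the junction: at least one full read on each side
            a = rng.randrange(rl, f - rl + 1)  # host-side extent of the fragment
            host_part = host[pos - a : pos]
            ins_part = insert[: f - a]
            s_host = _mutate(rng, host_part[:rl], cfg.error_rate)
            s_micro_fwd = _mutate(rng, (host_part + ins_part)[-rl:], cfg.error_rate)
            mate_pos = pos - a + 1
            # 73 = paired, mate unmapped, first; 133 = paired, unmapped, second
            sam_lines.append(_sam_line(qname, 73, HOST_CHROM, mate_pos, 60,
                                       f"{rl}M", "=", mate_pos, 0, s_host, qual))
            # unmapped mate co-placed at the mapped mate's coordinate
            sam_lines.append(_sam_line(qname, 133, HOST_CHROM, mate_pos, 0, "*",
                                       "=", mate_pos, 0,
                                       reverse_complement(s_micro_fwd), qual))
            emit_fastq(qname, s_host, s_micro_fwd)
            truth.origins[qname] = f"junction_{idx}"

    with open(paths.sam, "wt") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{HOST_CHROM}\tLN:{len(host)}\n")
        fh.writelines(sam_lines)
    with open(paths.fastq1, "wt") as fh:
        fh.writelines(fq1)
    with open(paths.fastq2, "wt") as fh:
        fh.writelines(fq2)
    with open(paths.truth_tsv, "wt") as fh:
        fh.write("qname\torigin\n")
        for qname in sorted(truth.origins):
            fh.write(f"{qname}\t{truth.origins[qname]}\n")
        for chrom, pos, taxid in truth.integrations:
            fh.write(f"#integration\t{chrom}:{pos}:{taxid}\n")
    return truth


def simulate_fixture(
    cfg: SimulationConfig, outdir: Path
) -> Tuple[TaxonomyTree, Dict[int, str], FixturePaths, TruthTable]:
    """Generate the complete fixture dataset under one directory."""
    tree, genomes, paths = make_taxonomy_and_genomes(cfg, outdir)
    truth = simulate_sam(cfg, tree, genomes, paths)
    return tree, genomes, paths, truth


def simulate_scored_mixture(
    seed: int,
    n_reads: int = 2000,
    contaminant_fraction: float = 0.4,
    tot_kmers: int = 70,
    contaminants: Optional[ContaminantList] = None,
) -> List[ScoredClassification]:
    """Annotated reads with contamination planted preferentially at low scores.

    Contaminant-genus reads draw their taxid_score below 0.5 and clean-genus
    reads at or above 0.5, so the contaminated fraction is non-increasing
    across ascending score bins by construction.  Records flow through the
    real scoring and annotation path.
    """
    rng = random.Random(seed)
    tree, _ = build_toy_taxonomy()
    if contaminants is None:
        contaminants = ContaminantList({
            tree.name[GENUS_BLACKLISTED]: "blacklisted",
            tree.name[GENUS_FLAGGED]: "flagged",
        })
    out: List[ScoredClassification] = []
    for i in range(n_reads):
        contaminated = rng.random() < contaminant_fraction
        if contaminated:
            taxid = rng.choice([SPECIES_BLACKLISTED, SPECIES_FLAGGED])
            score = rng.uniform(0.0, 0.5)
        else:
            taxid = SPECIES_CLEAN
            score = rng.uniform(0.5, 1.0)
        max_k = min(tot_kmers, max(1, round(score * tot_kmers)))
        if contaminated:
            max_k = min(max_k, (tot_kmers - 1) // 2)  # keep strictly below 0.5
            max_k = max(max_k, 1)
        rest = tot_kmers - max_k
        kmer_string = f"{taxid}:{max_k}" + (f" 0:{rest}" if rest else "")
        rec = ClassificationRecord("C", f"mix{i:05d}", taxid,
                                   tot_kmers + 30, kmer_string)
        sc = annotate(score_record(rec), tree, contaminants, HOST_SPECIES)
        assert sc is not None
        out.append(sc)
    return out
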