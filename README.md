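# hgtscan

Screen host-aligned paired-end sequencing data for candidate horizontal
gene transfer (HGT). Host genome sequencing experiments — exomes and whole
genomes alike — routinely contain reads of microbial origin: genuine
integrations of foreign DNA, environmental organisms, or reagent ("kitome")
contamination. `hgtscan` takes an aligned SAM/BAM, pulls out the reads the
aligner could not place, identifies what they are taxonomically, scores how
confident each assignment is, separates plausible signal from known
contaminant genera, and — where one mate of a pair did map — points at the
host locus a putative integration would sit at.

It is aimed at desk-scale analyses and method development: everything runs
from plain-text inputs, a bundled simulator generates complete test
datasets with planted integrations, and no external binaries or downloads
are needed.

## What it computes

**Read extraction.** Paired reads are split by SAM bitwise flag into two
categories: *both_unmapped* (`-f 13`: paired + read unmapped + mate
unmapped) and *single_unmapped* (`-f 5` with the mate-unmapped bit clear:
paired + read unmapped, mate mapped). Non-primary alignments (`-F 256`) are
excluded, and the two categories are disjoint. For single_unmapped reads
the mapped mate's chromosome and position (SAM columns 3 and 8) are
recorded.

**Classification.** An exact k-mer classifier: every canonical k-mer
(default k = 35 standalone, k = 31 in the pipeline defaults) of the
reference library maps to the lowest common ancestor (LCA) of all genomes
containing it. A read's L−k+1 windows are looked up, run-length encoded
into the Kraken-style `taxid:count` string, and the read is assigned the
taxid with the most supporting k-mers (ties broken by LCA). Pre-computed
Kraken2 per-read files can be supplied instead.

**Scoring.** From each read's k-mer string:

- `tot_kmers` — all k-mers analysed (matched, unmatched `0:`, ambiguous `A:`)
- `sum_class_kmers` — k-mers with a non-zero taxid
- `max_kmers` — k-mers supporting the assigned taxid

giving `taxid_score = max_kmers / tot_kmers` and
`alt_score = max_kmers / sum_class_kmers`. Host-lineage reads are filtered
out; each remaining read's genus is looked up against a contaminant list
(status `flagged` = potentially host-associated, inspect; `blacklisted` =
known reagent contaminant, removed from headline counts). Per-sample
microbial proportions and score-stratified contamination tables follow.

**Integration sites.** Classified single_unmapped reads are joined with
their mates' coordinates and clustered per chromosome by single linkage
(default window 1000 bp, minimum support 2) into candidate loci with genus
composition and mean score.

## Worked example

Generate a synthetic dataset (one planted Wolbachia integration, 10%
kitome contamination, error-free reads) and run the pipeline:

```
hgtscan simulate --seed 4 --out fix
printf 's1\tfix/aligned.sam\n' > manifest.tsv
cat > cfg.yaml <<EOF
host_taxid: 9606
nodes_path: fix/nodes.tsv
library_paths: [fix/library.fa]
contaminants_path: fix/contaminants.tsv
k: 31
EOF
hgtscan run --manifest manifest.tsv --config cfg.yaml --out out
```

`out/sample_summaries.tsv`:

```
sample  category         total_reads  extracted_reads  kept_microbial_reads  microbial_proportion
s1      both_unmapped    2012         400              300                   0.149105
s1      single_unmapped  2012         6                6                     0.00298211
```

400 reads had both mates unmapped; 300 survive host filtering and
blacklisted-genus removal (the 100 planted Ralstonia reads are dropped),
i.e. a microbial proportion of 0.149 of the sample's 2012 primary records.
The 6 single_unmapped reads are junction-spanning mates of the planted
integration, and clustering them (`out/s1/integration_sites.tsv`) recovers
it:

```
chrom  start  end    support  top_genus  mean_score
chr1   16964  17031  6        Wolbachia  1.0000
```

a single candidate within one insert size of the planted junction. Per-read
detail (taxid, genus, contaminant status, the three k-mer tallies and both
scores) is in `out/s1/scored_reads.tsv`; pooled Krona-importer files
(taxid in column 3, one per category across all samples) and a
self-contained HTML report round out the outputs.

Standalone pieces of the chain are exposed as `hgtscan score` (score an
existing Kraken-format file) and `hgtscan sites` (cluster a scored table
against a mate-position table).

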