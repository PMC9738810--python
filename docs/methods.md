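# Methods

## Problem and model

Sequencing reads from a host organism that fail to align to the host
reference are a mixture of genuine foreign DNA (candidate horizontal gene
transfer or infection), reagent contamination, and alignment artefacts.
`hgtscan` models the screening problem as four sequential inferences:

1. **Which reads are unplaced, and how?** SAM flag logic splits paired
   reads into *both_unmapped* (include-filter 13 = paired + unmapped +
   mate-unmapped) and *single_unmapped* (include-filter 5 with the
   mate-unmapped bit additionally required clear), both excluding
   non-primary alignments (bit 256). Requiring bit 0x8 clear for
   single_unmapped is deliberate: a bare `-f 5` filter also matches every
   flag-13 record, and the category is defined by its mate being *mapped*,
   so the stricter mask (`-f 5 -F 264`) makes the two categories a true
   partition of the primary unmapped reads. Supplementary alignments
   (0x800) are retained because only bit 256 is excluded.

2. **What are they?** Exact k-mer LCA classification. The database maps
   each canonical k-mer (lexicographic minimum of the k-mer and its
   reverse complement, so classification is strand-invariant) to the
   lowest common ancestor of every library genome containing it. A read is
   assigned the taxid with the highest total k-mer support. This is the
   simple max-count rule rather than Kraken2's weighted root-to-leaf path
   score: the per-read confidence scores below are defined in terms of
   k-mers supporting the single assigned taxid, which presupposes this
   reading. Files produced by real Kraken2 are still parsed and scored
   (see lineage mode). Ties between taxids with equal support are broken
   by taking their LCA — deterministic and topology-aware. Reads shorter
   than k emit the single token `0:0` and are unclassified. No minimizers
   or probabilistic tables: exact matching favours fidelity over speed at
   desk scale.

3. **How confident is each call?** Per read: `tot_kmers` counts every
   analysed k-mer including unmatched (`0:`) and ambiguous-base (`A:`)
   runs; `sum_class_kmers` counts k-mers with a non-zero numeric taxid
   (ambiguous runs count as unclassified); `max_kmers` counts k-mers whose
   taxid equals the assignment exactly. `taxid_score = max/tot`,
   `alt_score = max/sum_class`; zero denominators give score 0 rather than
   NaN so stratification is total. In **lineage mode** (for externally
   produced files whose assignment may be an ancestor of every token
   taxid) `max_kmers` instead counts k-mers in the assigned taxid's
   subtree; strict mode is the default and the two are never mixed within
   a run.

4. **Where would an integration sit?** Mapped-mate coordinates of kept
   single_unmapped reads are clustered per chromosome by single linkage:
   two positions join iff within `window` bp; clusters below `min_support`
   are dropped. Mate positions of junction-spanning pairs scatter within
   roughly one insert size of the true junction, so `window` should be of
   that order. Genus composition is reported per candidate instead of
   forcing a single genus: mixed-genus loci are a real ambiguity signal.

## Filtering and contamination

Host filtering discards reads whose assigned taxid equals the host, or is
an ancestor or descendant of it. Contaminant genera are matched by exact
scientific name against a two-status list: `blacklisted` (known
reagent/kitome contaminants) are removed from headline counts and Krona
exports; `flagged` (genera that include host-associated species) are kept
but labelled, with a `drop_flagged` switch to remove them too. The bundled
default list is a curated approximation compiled from the negative-control
contamination literature; it is data, editable, and not normative.
Headline microbial proportions count kept genus-level classified reads per
category divided by the sample's total primary records.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 35 (library), 31 (pipeline/simulator conditions) | k-mer length; odd, so a k-mer never equals its reverse complement |
| `window` | 1000 bp | single-linkage joining distance for site clustering |
| `min_support` | 2 | minimum reads per candidate locus — the weakest non-singleton evidence |
| `bin_edges` | 0, 0.2, …, 1.0 | score-stratification bins; last bin closed at 1.0 |
| `drop_flagged` | off | also remove flagged genera from headline counts |
| `lineage_mode` | off | subtree-inclusive `max_kmers` for external Kraken2 files |

## The simulator

The fixture generator writes aligner *output* directly — SAM flags and
coordinates per the bwa/samtools conventions, including co-placement of an
unmapped read at its mapped mate's coordinate — so the pipeline's actual
entry point (pre-aligned data) is exercised without any aligner. Default
study conditions: a 50 kb host chromosome; three 20 kb microbial genomes
under a clean genus (Wolbachia), a blacklisted genus (Ralstonia) and a
flagged genus (Escherichia); 1000 pairs of 2×100 bp reads at insert
300±30 bp; 10% contaminant pairs and 10% clean microbial both-unmapped
pairs; one planted integration supported by 6 junction-spanning pairs;
substitution-only errors at rate 0 by default; constant `I` qualities
(trimming is out of scope, so qualities are inert). Fragment lengths are
truncated at ±3 sd so junction mate positions provably fall within
`insert_mean + 3·insert_sd` of the planted junction.

Genomes are i.i.d. uniform ACGT. At k = 31 the chance that two random
20 kb genomes share any k-mer is vanishingly small, so every genome's
k-mers are effectively unique to it. This is what makes near-100%
species-level recovery the *expected* behaviour of a correct classifier on
these fixtures — and also what the fixtures do **not** show: real genomes
share homologous sequence, real classification is ambiguous at low
taxonomic distance, and real data contain indels, quality artefacts and
chimeras. Passing tests demonstrate correctness of the mechanics (flag
logic, index/LCA construction, score arithmetic, clustering, round trips),
not real-data sensitivity or specificity.

The score-stratification fixture plants its structure directly: contaminant
-genus reads draw `taxid_score` below 0.5 and clean-genus reads at or above
0.5, so the contaminated fraction per ascending score bin is non-increasing
by construction, exercising the stratification machinery end to end.

## Numerical and design choices

- Coordinates are 1-based closed everywhere, as in SAM; output tables say so.
- Mate chromosome comes from RNAME (column 3), matching the
  `samtools view | cut -f 1,3,8` idiom and the co-placement convention;
  when RNAME is `*` the implementation falls back to RNEXT for SAM
  dialects that do not co-place.
- Classification is single-end per mate; the paired `|:|` Kraken dialect
  is split into two records on input only.
- The k-mer index is built incrementally (k-mer → running LCA); because
  LCA folding is associative and commutative the result is independent of
  library file order, and a per-genome k-mer set ensures a genome
  contributes each k-mer once.
- Site clustering sorts positions before linkage, so results are invariant
  to input order; candidates are reported sorted by (chrom, start).
- Per-record anomaly warnings (e.g. an assignment with no supporting
  token) are capped at 10 per process to avoid log flooding.
- Scales were chosen for interactive turnaround: the default simulation
  classifies ~400 unmapped reads against a ~110k-entry index in a couple
  of seconds; all sizes are configuration, not constants.

## Limitations

- Exact matching and a Python dict index do not scale to real reference
  libraries; the classifier is for desk-scale analysis and testing, with
  real Kraken2 output ingestible where scale demands it.
- Merged/deprecated taxids are not resolved (no `merged.dmp` support).
- FASTQ input mode performs no alignment and therefore no host
  subtraction; it requires an external classification file and warns
  prominently.
- No split-read or soft-clip junction resolution: candidate loci are
  mate-position clusters, accurate to roughly one insert size.
- No statistical significance is attached to candidate sites or
  contamination enrichment.
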