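"""K-mer index building, read classification and the Kraken per-read dialect."""

import io
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hgtscan.kmer_classifier import (
    ClassificationRecord, KrakenFormatError, build_index, canonical_kmer,
    classify_read, parse_kraken_output, write_kraken_output,
    write_kraken_report,
)
from hgtscan.sam_extract import reverse_complement


def write_fasta(path, entries):
    with open(path, "wt") as fh:
        for header, seq in entries:
            fh.write(f">{header}\n{seq}\n")


K = 5  # tiny k for hand-checkable indexes


def brute_force_index(tree, genomes, k):
    """Oracle: explicit per-k-mer LCA over genome sets."""
    kmer_sources = {}
    for taxid, seq in genomes:
        for i in range(len(seq) - k + 1):
            w = seq[i:i + k]
            if set(w) <= set("ACGT"):
                kmer_sources.setdefault(canonical_kmer(w), set()).add(taxid)
    return {kmer: tree.lca_of(sorted(s)) for kmer, s in kmer_sources.items()}


def test_build_index_single_source(deep_tree, tmp_path):
    seq = "ACGTACGTTGCA"
    lib = tmp_path / "lib.fa"
    write_fasta(lib, [(f"s1|kraken:taxid|11", seq)])
    idx = build_index(deep_tree, [lib], k=K)
    assert 0 < len(idx) <= len(seq) - K + 1
    assert set(idx.entries.values()) == {11}
    assert idx.source_taxids == {11}


def test_build_index_shared_kmers_map_to_lca(deep_tree, tmp_path):
    rng = random.Random(0)
    shared = "".join(rng.choice("ACGT") for _ in range(30))
    lib = tmp_path / "lib.fa"
    write_fasta(lib, [("a|kraken:taxid|11", shared), ("b|kraken:taxid|12", shared)])
    idx = build_index(deep_tree, [lib], k=K)
    oracle = brute_force_index(deep_tree, [(11, shared), (12, shared)], K)
    assert idx.entries == oracle
    assert set(idx.entries.values()) == {10}  # genus of the two siblings


def test_build_index_matches_oracle_on_random_libraries(deep_tree, tmp_path):
    rng = random.Random(3)
    genomes = [(t, "".join(rng.choice("ACGT") for _ in range(200)))
               for t in (11, 12, 10)]
    lib = tmp_path / "lib.fa"
    write_fasta(lib, [(f"g{t}|kraken:taxid|{t}", s) for t, s in genomes])
    idx = build_index(deep_tree, [lib], k=K)
    assert idx.entries == brute_force_index(deep_tree, genomes, K)


def test_build_index_skips_ambiguous_and_is_order_invariant(deep_tree, tmp_path):
    seq_n = "ACGTNACGTACG"
    a = tmp_path / "a.fa"
    b = tmp_path / "b.fa"
    write_fasta(a, [("x|kraken:taxid|11", seq_n)])
    write_fasta(b, [("y|kraken:taxid|12", "TTTTTTTTTT")])
    idx_ab = build_index(deep_tree, [a, b], k=K)
    idx_ba = build_index(deep_tree, [b, a], k=K)
    assert idx_ab.entries == idx_ba.entries
    # no stored k-mer overlaps the N at position 4
    for i in range(len(seq_n) - K + 1):
        w = seq_n[i:i + K]
        if "N" in w:
            assert canonical_kmer(w.replace("N", "A")) != w  # sanity only
    assert all("N" not in k for k in idx_ab.entries)


def test_build_index_requires_taxid_header(deep_tree, tmp_path):
    lib = tmp_path / "lib.fa"
    write_fasta(lib, [("anonymous", "ACGTACGTAC")])
    with pytest.raises(KrakenFormatError, match="anonymous"):
        build_index(deep_tree, [lib], k=K)
    # sidecar map rescues the same file
    idx = build_index(deep_tree, [lib], k=K, seqid_map={"anonymous": 11})
    assert set(idx.entries.values()) == {11}


def make_index(deep_tree, tmp_path, entries):
    lib = tmp_path / "mklib.fa"
    write_fasta(lib, entries)
    return build_index(deep_tree, [lib], k=K)


def test_classify_uniform_read(deep_tree, tmp_path):
    rng = random.Random(1)
    genome = "".join(rng.choice("ACGT") for _ in range(100))
    idx = make_index(deep_tree, tmp_path, [("g|kraken:taxid|11", genome)])
    read = genome[10:40]
    rec = classify_read(idx, deep_tree, "r1", read)
    assert rec.status == "C" and rec.taxid == 11
    assert rec.kmer_string == f"11:{len(read) - K + 1}"


def test_classify_strand_invariance(deep_tree, tmp_path):
    rng = random.Random(2)
    genome = "".join(rng.choice("ACGT") for _ in range(100))
    idx = make_index(deep_tree, tmp_path, [("g|kraken:taxid|11", genome)])
    read = genome[5:45]
    fwd = classify_read(idx, deep_tree, "r", read)
    rev = classify_read(idx, deep_tree, "r", reverse_complement(read))
    assert fwd.taxid == rev.taxid == 11


def test_classify_max_count_and_tie_break(deep_tree):
    """Hand-built index: run-length string and LCA tie-break as specified."""
    from hgtscan.kmer_classifier import KmerIndex

    # find a 12-bp read whose 8 windows have pairwise distinct canonical
    # 5-mers, so each window can carry its own planted label
    rng = random.Random(0)
    while True:
        read = "".join(rng.choice("ACGT") for _ in range(12))
        canon = [canonical_kmer(read[i:i + K]) for i in range(8)]
        if len(set(canon)) == 8:
            break
    labels = [11, 11, 11, 10, 10, 0, 0, 0]
    idx = KmerIndex(k=K)
    for i, lab in enumerate(labels):
        if lab:
            idx.entries[canonical_kmer(read[i:i + K])] = lab
    rec = classify_read(idx, deep_tree, "r", read)
    assert rec.kmer_string == "11:3 10:2 0:3"
    assert rec.taxid == 11

    # tie 11 vs 12 (siblings under genus 10) -> LCA 10
    idx2 = KmerIndex(k=K)
    labels2 = [11, 11, 12, 12, 0, 0, 0, 0]
    for i, lab in enumerate(labels2):
        if lab:
            idx2.entries[canonical_kmer(read[i:i + K])] = lab
    rec2 = classify_read(idx2, deep_tree, "r", read)
    assert rec2.taxid == 10


def test_classify_short_and_unmatched_reads(deep_tree):
    from hgtscan.kmer_classifier import KmerIndex

    idx = KmerIndex(k=K)
    short = classify_read(idx, deep_tree, "r", "ACG")
    assert (short.status, short.taxid, short.kmer_string) == ("U", 0, "0:0")
    nomatch = classify_read(idx, deep_tree, "r", "ACGTACGTAC")
    assert nomatch.status == "U" and nomatch.kmer_string == "0:6"


def test_token_count_conservation(deep_tree, tmp_path):
    rng = random.Random(9)
    genome = "".join(rng.choice("ACGT") for _ in range(300))
    idx = make_index(deep_tree, tmp_path, [("g|kraken:taxid|11", genome)])
    for _ in range(50):
        L = rng.randrange(K, 60)
        start = rng.randrange(0, len(genome) - L)
        read = genome[start:start + L]
        if rng.random() < 0.3:  # inject ambiguity
            i = rng.randrange(L)
            read = read[:i] + "N" + read[i + 1:]
        rec = classify_read(idx, deep_tree, "r", read)
        total = sum(c for _, c in rec.tokens())
        assert total == L - K + 1


def random_record(rng, i):
    tokens = []
    for _ in range(rng.randrange(1, 6)):
        label = rng.choice(["0", "A", "11", "12", "10", "562"])
        tokens.append(f"{label}:{rng.randrange(1, 30)}")
    taxid = rng.choice([0, 11, 12, 562])
    status = "U" if taxid == 0 else "C"
    return ClassificationRecord(status, f"read{i}", taxid,
                                rng.randrange(36, 150), " ".join(tokens))


def test_write_parse_roundtrip(tmp_path):
    rng = random.Random(123)
    records = [random_record(rng, i) for i in range(100)]
    p = tmp_path / "out.kraken"
    with open(p, "wt") as fh:
        assert write_kraken_output(records, fh) == 100
    assert list(parse_kraken_output(p)) == records


def test_write_format_exact():
    rec = ClassificationRecord("C", "r1", 11, 50, "11:16")
    buf = io.StringIO()
    write_kraken_output([rec], buf)
    assert buf.getvalue() == "C\tr1\t11\t50\t11:16\n"


def test_parse_paired_line_splits(tmp_path):
    p = tmp_path / "pair.kraken"
    p.write_text("C\tr2\t562\t70|70\t562:30 0:6 |:| 562:20 561:16\n")
    a, b = list(parse_kraken_output(p))
    assert a.qname == b.qname == "r2"
    assert a.kmer_string == "562:30 0:6"
    assert b.kmer_string == "562:20 561:16"
    assert (a.read_length, b.read_length) == (70, 70)


def test_parse_malformed_token_names_line(tmp_path):
    p = tmp_path / "bad.kraken"
    p.write_text("C\tr1\t11\t50\t11:16\nC\tr2\t11\t50\tabc\n")
    with pytest.raises(KrakenFormatError, match="line 2"):
        list(parse_kraken_output(p))


def test_write_kraken_report(deep_tree):
    records = [ClassificationRecord("C", "a", 11, 50, "11:16"),
               ClassificationRecord("C", "b", 12, 50, "12:16"),
               ClassificationRecord("U", "c", 0, 50, "0:16")]
    buf = io.StringIO()
    write_kraken_report(records, deep_tree, buf)
    lines = buf.getvalue().splitlines()
    by_taxid = {line.split("\t")[4]: line.split("\t") for line in lines}
    assert by_taxid["0"][1] == "1"          # unclassified count
    assert by_taxid["10"][1] == "2"         # clade count at genus
    assert by_taxid["10"][2] == "0"         # no direct genus assignment
    assert by_taxid["11"][2] == "1"


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.tuples(
    st.sampled_from(["0", "A", "7", "11"]),
    st.integers(min_value=1, max_value=40)), min_size=1, max_size=8))
def test_roundtrip_property(tokens):
    kmer_string = " ".join(f"{lab}:{n}" for lab, n in tokens)
    rec = ClassificationRecord("C", "q", 11, 100, kmer_string)
    buf = io.StringIO()
    write_kraken_output([rec], buf)
    buf2 = io.StringIO(buf.getvalue())
    line = buf.getvalue().strip().split("\t")
    assert line[4] == kmer_string
    assert rec.tokens() == [(lab, n) for lab, n in tokens]
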