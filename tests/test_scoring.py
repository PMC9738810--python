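"""Per-read scores, host filtering, contaminant annotation, aggregation."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hgtscan.kmer_classifier import ClassificationRecord
from hgtscan.scoring import (
    DEFAULT_BIN_EDGES, annotate, score_record, stratify_by_score,
    summarize_sample,
)
from hgtscan.simulate import simulate_scored_mixture
from hgtscan.taxonomy import ContaminantList


def crec(kmer_string, taxid, qname="r1", length=70):
    status = "U" if taxid == 0 else "C"
    return ClassificationRecord(status, qname, taxid, length, kmer_string)


def test_worked_example():
    """562:10 561:5 0:3 A:2 assigned 562 -> tot 20, class 15, max 10."""
    sc = score_record(crec("562:10 561:5 0:3 A:2", 562))
    assert (sc.tot_kmers, sc.sum_class_kmers, sc.max_kmers) == (20, 15, 10)
    assert sc.taxid_score == pytest.approx(0.5)
    assert sc.alt_score == pytest.approx(10 / 15)


def test_uniform_and_unclassified_records():
    full = score_record(crec("1301:30", 1301))
    assert full.taxid_score == full.alt_score == 1.0
    un = score_record(crec("0:30", 0))
    assert (un.tot_kmers, un.sum_class_kmers, un.max_kmers) == (30, 0, 0)
    assert un.taxid_score == un.alt_score == 0.0


def test_foreign_assignment_gives_zero_max(caplog):
    sc = score_record(crec("561:10 0:5", 562))
    assert sc.max_kmers == 0 and sc.taxid_score == 0.0


def test_lineage_mode_counts_subtree(deep_tree):
    # assignment at genus 10; tokens at species 11 below it
    rec = crec("11:6 0:4", 10)
    strict = score_record(rec, tree=deep_tree)
    inclusive = score_record(rec, tree=deep_tree, lineage_mode=True)
    assert strict.max_kmers == 0
    assert inclusive.max_kmers == 6
    assert inclusive.taxid_score == pytest.approx(0.6)


@settings(max_examples=500, derandomize=True)
@given(st.lists(st.tuples(
    st.sampled_from(["0", "A", "11", "12", "562", "561"]),
    st.integers(min_value=1, max_value=50)), min_size=1, max_size=10),
    st.sampled_from([0, 11, 12, 562]))
def test_score_ordering_invariants(tokens, taxid):
    """max_kmers <= sum_class_kmers <= tot_kmers; score laws exact."""
    kmer_string = " ".join(f"{lab}:{n}" for lab, n in tokens)
    sc = score_record(crec(kmer_string, taxid))
    assert 0 <= sc.max_kmers <= sc.sum_class_kmers <= sc.tot_kmers
    if sc.tot_kmers:
        assert sc.taxid_score == sc.max_kmers / sc.tot_kmers
    if sc.sum_class_kmers:
        assert sc.alt_score == sc.max_kmers / sc.sum_class_kmers
        assert sc.taxid_score <= sc.alt_score


def contaminant_list(toy_tree):
    return ContaminantList({"Ralstonia": "blacklisted", "Escherichia": "flagged"})


def test_annotate_discards_host_and_unclassified(toy_tree):
    cl = contaminant_list(toy_tree)
    host = 9606
    assert annotate(score_record(crec("9606:10", 9606)), toy_tree, cl, host) is None
    assert annotate(score_record(crec("2759:10", 2759)), toy_tree, cl, host) is None
    assert annotate(score_record(crec("0:10", 0)), toy_tree, cl, host) is None


def test_annotate_genus_and_status(toy_tree):
    cl = contaminant_list(toy_tree)
    black = annotate(score_record(crec("329:10", 329)), toy_tree, cl, 9606)
    assert black.genus_name == "Ralstonia" and black.contaminant_status == "blacklisted"
    clean = annotate(score_record(crec("955:10", 955)), toy_tree, cl, 9606)
    assert clean.genus_name == "Wolbachia" and clean.contaminant_status is None
    # bacterial taxid with no genus on its lineage is kept, genus None
    nogenus = annotate(score_record(crec("2:10", 2)), toy_tree, cl, 9606)
    assert nogenus is not None and nogenus.genus is None


def test_annotate_unknown_taxid_errors(toy_tree):
    with pytest.raises(KeyError):
        annotate(score_record(crec("424242:5", 424242)), toy_tree,
                 contaminant_list(toy_tree), 9606)


def kept_read(toy_tree, taxid, qname):
    cl = contaminant_list(toy_tree)
    return annotate(score_record(crec(f"{taxid}:10", taxid, qname=qname)),
                    toy_tree, cl, 9606)


def test_summarize_sample_proportions(toy_tree):
    reads = [kept_read(toy_tree, 955, f"r{i}") for i in range(10)]
    s = summarize_sample("s1", 1_000_000, {"both_unmapped": reads})
    assert s.microbial_proportion["both_unmapped"] == pytest.approx(1e-5)
    empty = summarize_sample("s2", 100, {"both_unmapped": []})
    assert empty.microbial_proportion["both_unmapped"] == 0.0
    assert empty.genus_table == {}


def test_summarize_excludes_blacklisted_keeps_flagged(toy_tree):
    reads = ([kept_read(toy_tree, 955, f"c{i}") for i in range(6)]
             + [kept_read(toy_tree, 562, f"f{i}") for i in range(4)]
             + [kept_read(toy_tree, 329, f"b{i}") for i in range(5)])
    s = summarize_sample("s", 1000, {"both_unmapped": reads})
    assert s.kept_counts["both_unmapped"] == 10  # blacklisted removed
    assert s.genus_table["Wolbachia"][0] == 6
    assert s.genus_table["Escherichia"][0] == 4
    assert "Ralstonia" not in s.genus_table
    strict = summarize_sample("s", 1000, {"both_unmapped": reads},
                              drop_flagged=True)
    assert strict.kept_counts["both_unmapped"] == 6


def test_summarize_scale_invariance(toy_tree):
    reads = [kept_read(toy_tree, 955, f"r{i}") for i in range(8)]
    a = summarize_sample("s", 400, {"c": reads})
    b = summarize_sample("s", 800, {"c": reads + [
        kept_read(toy_tree, 955, f"d{i}") for i in range(8)]})
    assert a.microbial_proportion["c"] == b.microbial_proportion["c"]


def test_summarize_rejects_nonpositive_total(toy_tree):
    with pytest.raises(ValueError):
        summarize_sample("s", 0, {})


def test_stratify_binning_and_fractions(toy_tree):
    reads = [kept_read(toy_tree, 955, "a"),   # score 1.0 -> last bin
             kept_read(toy_tree, 329, "b")]
    half = annotate(score_record(crec("955:10 0:10", 955, qname="c")),
                    toy_tree, contaminant_list(toy_tree), 9606)
    rows = stratify_by_score(reads + [half], DEFAULT_BIN_EDGES)
    assert len(rows) == 5
    assert rows[-1]["total"] == 2          # the two 1.0-score reads
    assert rows[2]["none"] == 1            # score 0.5 in [0.4, 0.6)
    for row in rows:
        if row["total"]:
            assert (row["flagged_fraction"] + row["blacklisted_fraction"]
                    + row["none_fraction"]) == pytest.approx(1.0)


def test_stratify_rejects_bad_edges():
    with pytest.raises(ValueError):
        stratify_by_score([], [0.0, 0.0, 1.0])
    with pytest.raises(ValueError):
        stratify_by_score([], [-0.1, 1.0])


def test_planted_mixture_contamination_decreases_with_score():
    reads = simulate_scored_mixture(seed=5, n_reads=1500)
    rows = stratify_by_score(reads, DEFAULT_BIN_EDGES)
    fractions = [r["contaminant_fraction"] for r in rows if r["total"]]
    assert all(a >= b for a, b in zip(fractions, fractions[1:]))
    assert fractions[0] > fractions[-1]
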