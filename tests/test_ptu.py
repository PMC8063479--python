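"""Cistronic typing and PTU merging, checked against per-base containment
and transitive-closure oracles."""

import numpy as np
import pytest

from ptuscope.ptu import (assign_cistronic_type, classify_singletons,
                          enumerate_cistronic_types, merge_into_ptus,
                          ptu_report)

from _util import (annotation, brute_cistronic_types, brute_intact_genes,
                   brute_transitive_closure, gene, read)


@pytest.fixture
def three_genes():
    return annotation([
        gene("A", 100, 200, "+"),
        gene("B", 300, 400, "+"),
        gene("C", 500, 600, "-"),
    ], length=1000, seed=4)


def test_read_covering_no_gene_is_discarded(three_genes):
    assert assign_cistronic_type(read("r", [(600, 900)]), three_genes) is None
    # partial overlap does not count
    assert assign_cistronic_type(read("r", [(150, 350)]), three_genes) is None


def test_strand_rule_excludes_opposite_gene(three_genes):
    """A plus-strand read over A, B and C yields type (+, (A,B)); C lies on
    the other strand and cannot join the type."""
    r = read("r", [(90, 610)], strand="+")
    assert assign_cistronic_type(r, three_genes) == ("+", ("A", "B"))
    r2 = read("r2", [(90, 610)], strand="-")
    assert assign_cistronic_type(r2, three_genes) == ("-", ("C",))


def test_exon_level_rule_for_intron_containing_genes():
    """A read whose gap skips the intron still counts the gene as intact:
    coverage is judged exon by exon."""
    ann = annotation([gene("G", 0, 0, "+", exons=[(100, 200), (300, 400)])],
                     length=1000, seed=4)
    spliced = read("r", [(80, 200), (300, 420)])
    assert assign_cistronic_type(spliced, ann) == ("+", ("G",))
    # a read stopping inside exon 2 does not
    partial = read("r2", [(80, 200), (300, 390)])
    assert assign_cistronic_type(partial, ann) is None


def test_coverage_slack_allows_frayed_termini(three_genes):
    r = read("r", [(105, 195)])   # 5 bp short at both ends of A
    assert assign_cistronic_type(r, three_genes, coverage_slack=0) is None
    assert assign_cistronic_type(r, three_genes, coverage_slack=5) == ("+", ("A",))


def test_minus_strand_tuple_order():
    """Gene tuples follow the transcription direction: descending genome
    coordinate on the minus strand."""
    ann = annotation([gene("X", 100, 200, "-"), gene("Y", 300, 400, "-")],
                     length=1000, seed=4)
    r = read("r", [(50, 450)], strand="-")
    assert assign_cistronic_type(r, ann) == ("-", ("Y", "X"))


def test_enumerate_groups_and_conserves_support(three_genes):
    reads = [read(f"r{i}", [(90, 410)]) for i in range(5)]          # (A,B) x5
    reads += [read("r5", [(90, 210)]), read("r6", [(290, 410)])]     # (A), (B)
    reads += [read("r7", [(450, 650)], strand="-")]                  # (C)
    reads += [read("r8", [(700, 900)])]                              # none
    types = enumerate_cistronic_types(reads, three_genes)
    by_key = {(t.strand, t.gene_ids): t.support for t in types}
    assert by_key == {("+", ("A", "B")): 5, ("+", ("A",)): 1,
                      ("+", ("B",)): 1, ("-", ("C",)): 1}
    n_qualifying = sum(1 for r in reads
                       if brute_intact_genes(r, three_genes))
    assert sum(t.support for t in types) == n_qualifying == 8


def test_merge_chain_and_singleton(three_genes):
    """Types (A,B), (B,C'), (D) -> components {A,B,C'} and {D}."""
    ann = annotation([
        gene("A", 100, 200, "+"), gene("B", 300, 400, "+"),
        gene("C", 500, 600, "+"), gene("D", 700, 800, "+"),
    ], length=1000, seed=4)
    reads = [read("r1", [(90, 410)]), read("r2", [(290, 610)]),
             read("r3", [(690, 810)])]
    types = enumerate_cistronic_types(reads, ann)
    pm = merge_into_ptus(types, ann)
    partitions = {(p.strand, frozenset(p.gene_ids)) for p in pm.ptus}
    assert partitions == {("+", frozenset("ABC")), ("+", frozenset("D"))}
    # gene order within each PTU follows genome position
    assert [p.gene_ids for p in pm.ptus] == [["A", "B", "C"], ["D"]]


def test_merge_is_idempotent_and_maximal(three_genes):
    reads = [read("r1", [(90, 410)]), read("r2", [(90, 210)])]
    types = enumerate_cistronic_types(reads, three_genes)
    pm1 = merge_into_ptus(types, three_genes)
    # feeding each PTU's merged content back as one type changes nothing
    from ptuscope.ptu import CistronicType
    again = [CistronicType(p.strand, tuple(p.gene_ids), 1) for p in pm1.ptus]
    pm2 = merge_into_ptus(again, three_genes)
    assert [(p.strand, p.gene_ids) for p in pm1.ptus] == \
           [(p.strand, p.gene_ids) for p in pm2.ptus]
    # no two same-strand PTUs share a gene
    seen = {}
    for p in pm1.ptus:
        for g in p.gene_ids:
            assert (p.strand, g) not in seen
            seen[(p.strand, g)] = p.ptu_id


@pytest.mark.parametrize("seed", range(30))
def test_typing_and_merging_match_oracles(seed):
    """enumerate + merge equals per-base containment + naive transitive
    closure on random instances."""
    from _util import random_typing_instance

    ann, reads = random_typing_instance(seed)
    types = enumerate_cistronic_types(reads, ann)
    got_types = {(t.strand, t.gene_ids): t.support for t in types}
    assert got_types == brute_cistronic_types(reads, ann)
    pm = merge_into_ptus(types, ann)
    got = {(p.strand, frozenset(p.gene_ids)) for p in pm.ptus}
    expected = brute_transitive_closure(got_types.keys())
    assert got == expected


def test_singleton_reason_intronic_orfs():
    """A lone-gene PTU whose gene hosts intronic ORFs mirrors the rRNA-style
    single-gene operons."""
    ann = annotation([
        gene("rrn", 100, 700, "+", category="rRNA",
             exons=[(100, 300), (500, 700)]),
        gene("iorf1", 310, 460, "+", category="intronic_ORF", host_gene="rrn"),
    ], length=1000, seed=4)
    reads = [read(f"r{i}", [(90, 710)]) for i in range(3)]
    types = enumerate_cistronic_types(reads, ann)
    pm = classify_singletons(merge_into_ptus(types, ann), ann, reads)
    assert len(pm.ptus) == 1
    assert pm.ptus[0].singleton_reason == "intronic_orfs"


def test_singleton_reason_cleaved_vs_none():
    ann = annotation([gene("G", 100, 700, "+")], length=1000, seed=4)
    covering = [read(f"c{i}", [(90, 710)]) for i in range(3)]
    pm = classify_singletons(
        merge_into_ptus(enumerate_cistronic_types(covering, ann), ann),
        ann, covering)
    assert pm.ptus[0].singleton_reason == "none"
    # nested sub-reads in two distinct clusters -> cleavage evidence
    nested = [read("n1", [(120, 350)]), read("n2", [(121, 352)]),
              read("n3", [(420, 680)]), read("n4", [(418, 679)])]
    pm = classify_singletons(
        merge_into_ptus(enumerate_cistronic_types(covering, ann), ann),
        ann, covering + nested)
    assert pm.ptus[0].singleton_reason == "cleaved_cistrons"


def test_ptu_report_counts(tmp_path):
    ann = annotation([
        gene("p1", 100, 200, "+"), gene("o1", 250, 350, "+", category="ORF"),
        gene("t1", 400, 480, "+", category="tRNA"),
        gene("p2", 600, 700, "-"),
    ], length=1000, seed=4)
    reads = [read("r1", [(90, 490)]), read("r2", [(580, 710)], strand="-")]
    types = enumerate_cistronic_types(reads, ann)
    pm = merge_into_ptus(types, ann)
    tsv = tmp_path / "ptus.tsv"
    ptu_report(pm, ann, str(tsv), str(tmp_path / "ptus.gff3"))
    lines = [l.split("\t") for l in tsv.read_text().splitlines()]
    header, rows = lines[0], lines[1:]
    assert len(rows) == 2
    row1 = dict(zip(header, rows[0]))
    assert (row1["n_protein_coding"], row1["n_orf"], row1["n_trna"]) == ("1", "1", "1")
    row2 = dict(zip(header, rows[1]))
    assert row2["genes"] == "p2" and row2["n_protein_coding"] == "1"


def test_ptu_report_empty(tmp_path):
    ann = annotation([], length=100, seed=1)
    from ptuscope.ptu import PTUMap
    ptu_report(PTUMap([], 0, 0), ann, str(tmp_path / "e.tsv"))
    assert (tmp_path / "e.tsv").read_text().startswith("ptu_id\t")
    assert len((tmp_path / "e.tsv").read_text().splitlines()) == 1
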