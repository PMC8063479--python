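"""Intron calling, reconciliation, retention, consensus scoring and
boundary projection."""

import numpy as np
import pytest

from ptuscope.alignments import JunctionObservation, extract_junctions
from ptuscope.introns import (call_introns, compare_with_annotation,
                              iupac_scan, mean_pairwise_identity,
                              project_boundaries, retention_fraction,
                              score_group2_boundaries)

from _util import annotation, gene, random_seq, read


@pytest.fixture
def spliced_gene():
    """One plus-strand gene with an annotated 100 bp intron at [300,400)."""
    return annotation([gene("G", 0, 0, "+", exons=[(200, 300), (400, 500)])],
                      length=1000, seed=6)


def junction(d, a, strand="+", support=3):
    return JunctionObservation(d, a, strand, support)


def test_no_junctions_no_calls(spliced_gene):
    calls, intergenic = call_introns([], spliced_gene)
    assert calls == [] and intergenic == []


def test_junction_in_gene_becomes_intron_call(spliced_gene):
    calls, intergenic = call_introns([junction(300, 400)], spliced_gene)
    assert len(calls) == 1 and intergenic == []
    c = calls[0]
    assert (c.gene_id, c.intron_index, c.start, c.end, c.support) == \
        ("G", 1, 300, 400, 3)


def test_intergenic_junction_reported_separately(spliced_gene):
    calls, intergenic = call_introns([junction(700, 800)], spliced_gene)
    assert calls == [] and len(intergenic) == 1


def test_multiple_introns_indexed_in_transcription_order():
    """Five junctions inside one gene are indexed 5'->3'; for a minus-strand
    gene index 1 is the highest-coordinate intron."""
    exons = [(100, 200), (250, 350), (400, 500), (550, 650), (700, 800), (850, 950)]
    ann_plus = annotation([gene("G5", 0, 0, "+", exons=exons)], length=1200, seed=1)
    js = [junction(e0[1], e1[0]) for e0, e1 in zip(exons, exons[1:])]
    calls, _ = call_introns(js, ann_plus)
    assert [c.intron_index for c in calls] == [1, 2, 3, 4, 5]
    assert [c.start for c in calls] == [200, 350, 500, 650, 800]
    ann_minus = annotation([gene("G5", 0, 0, "-", exons=exons[::-1])],
                           length=1200, seed=1)
    js = [junction(e0[1], e1[0], strand="-") for e0, e1 in zip(exons, exons[1:])]
    calls, _ = call_introns(js, ann_minus)
    assert [(c.intron_index, c.start) for c in calls] == \
        [(1, 800), (2, 650), (3, 500), (4, 350), (5, 200)]


def test_compare_statuses(spliced_gene):
    # exact interval -> confirmed
    calls, _ = call_introns([junction(300, 400)], spliced_gene)
    comp = compare_with_annotation(calls, spliced_gene)
    assert [(c.status, c.old_interval, c.new_interval) for c in comp] == \
        [("confirmed", (300, 400), (300, 400))]
    # overlapping but shifted -> boundary_corrected
    calls, _ = call_introns([junction(305, 402)], spliced_gene)
    comp = compare_with_annotation(calls, spliced_gene)
    assert comp[0].status == "boundary_corrected"
    assert comp[0].old_interval == (300, 400) and comp[0].new_interval == (305, 402)
    # no observed junction at a predicted intron -> spurious_prediction
    comp = compare_with_annotation([], spliced_gene)
    assert [(c.status, c.old_interval) for c in comp] == \
        [("spurious_prediction", (300, 400))]


def test_observed_intron_in_intronless_gene_is_missed_by_prediction():
    ann = annotation([gene("flat", 100, 600, "+")], length=1000, seed=2)
    calls, _ = call_introns([junction(300, 400)], ann)
    comp = compare_with_annotation(calls, ann)
    assert [(c.status, c.new_interval) for c in comp] == \
        [("missed_by_prediction", (300, 400))]


def test_compare_statuses_are_exhaustive():
    """#confirmed + #corrected + #missed + #spurious covers the union of
    predicted and observed introns."""
    exons = [(100, 200), (300, 400), (500, 600)]
    ann = annotation([gene("G", 0, 0, "+", exons=exons),
                      gene("H", 700, 900, "+")], length=1000, seed=2)
    # observe: exact for intron 1, nothing for intron 2, novel in H
    js = [junction(200, 300), junction(750, 800)]
    calls, _ = call_introns(js, ann)
    comp = compare_with_annotation(calls, ann)
    statuses = sorted(c.status for c in comp)
    assert statuses == ["confirmed", "missed_by_prediction", "spurious_prediction"]
    n_predicted = 2
    n_observed = 2
    n_overlap = 1
    assert len(comp) == n_predicted + n_observed - n_overlap


# ---------------------------------------------------------------------------
# Retention


def test_retention_counting(spliced_gene):
    L = spliced_gene.genome.length
    calls, _ = call_introns([junction(300, 400, support=5)], spliced_gene)
    call = calls[0]
    spliced_reads = [read(f"s{i}", [(200, 300), (400, 500)]) for i in range(3)]
    retained_reads = [read(f"t{i}", [(200, 500)]) for i in range(2)]
    est = retention_fraction(spliced_reads + retained_reads, call, L)
    assert (est.n_spliced, est.n_retained) == (3, 2)
    assert est.fraction_retained == pytest.approx(0.4)
    assert est.isoform_lengths == [200, 300]   # spliced vs retained lengths


def test_retention_all_spliced_and_no_spanning(spliced_gene):
    L = spliced_gene.genome.length
    calls, _ = call_introns([junction(300, 400)], spliced_gene)
    call = calls[0]
    spliced_reads = [read(f"s{i}", [(200, 300), (400, 500)]) for i in range(4)]
    assert retention_fraction(spliced_reads, call, L).fraction_retained == 0.0
    nonspanning = [read("n", [(410, 500)])]
    est = retention_fraction(nonspanning, call, L)
    assert est.fraction_retained is None


def test_retention_invariant_to_read_order(spliced_gene):
    L = spliced_gene.genome.length
    calls, _ = call_introns([junction(300, 400)], spliced_gene)
    call = calls[0]
    rng = np.random.default_rng(0)
    reads = [read(f"s{i}", [(200, 300), (400, 500)]) for i in range(6)] + \
            [read(f"t{i}", [(200, 500)]) for i in range(4)]
    base = retention_fraction(reads, call, L).fraction_retained
    for _ in range(5):
        perm = list(rng.permutation(len(reads)))
        est = retention_fraction([reads[i] for i in perm], call, L)
        assert est.fraction_retained == base == pytest.approx(0.4)


# ---------------------------------------------------------------------------
# Consensus scoring


def test_canonical_boundary_scoring():
    intron = "GTGCG" + random_seq(150, seed=3) + "AGC" + "AT"
    score = score_group2_boundaries(intron)
    assert score.five_prime_mismatches == 0
    assert score.three_prime_match and score.canonical
    assert score.triad_present   # AGC planted inside the 3' 60 nt


def test_noncanonical_boundary_scoring():
    intron = "AATTC" + "C" * 100 + "GG"
    score = score_group2_boundaries(intron)
    # position-wise vs GTGYG: A|G mismatch, A|T mismatch, T|G mismatch,
    # T matches Y, C|G mismatch -> 4 mismatches
    assert score.five_prime_mismatches == 4
    assert not score.three_prime_match and not score.canonical
    assert not score.triad_present


def test_triad_window():
    intron = "GTGTG" + "C" * 200 + "AC"
    assert not score_group2_boundaries(intron).triad_present
    with_triad = "GTGTG" + "C" * 150 + "CGC" + "C" * 40 + "AC"   # triad in 3' 60 nt
    assert score_group2_boundaries(with_triad).triad_present
    # triad outside the supplied domain-V window is not counted
    assert not score_group2_boundaries(with_triad, domain_v_window=(0, 50)).triad_present
    with pytest.raises(ValueError):
        score_group2_boundaries("GTGCGAT")   # < 10 nt


def test_iupac_scan():
    seq = "TTTT" + "CCGAAAGG" + "TTTT"
    assert iupac_scan(seq, "CYGAAAGG") == [4]
    assert iupac_scan(seq, "CCGAAAGG") == [4]
    assert iupac_scan("AAAA", "CYGAAAGG") == []
    assert iupac_scan("ACGT", "ACGT") == [0]
    with pytest.raises(ValueError):
        iupac_scan(seq, "CZX")
    with pytest.raises(ValueError):
        iupac_scan(seq, "")


@pytest.mark.parametrize("seed", range(10))
def test_iupac_scan_matches_bruteforce(seed):
    iupac = {"A": "A", "C": "C", "G": "G", "T": "T", "Y": "CT", "R": "AG",
             "N": "ACGT", "W": "AT"}
    rng = np.random.default_rng(seed)
    seq = random_seq(300, seed=seed + 50)
    pattern = "".join(rng.choice(list(iupac), size=5))
    expected = [i for i in range(len(seq) - 4)
                if all(seq[i + k] in iupac[pattern[k]] for k in range(5))]
    assert iupac_scan(seq, pattern) == expected


# ---------------------------------------------------------------------------
# Boundary projection


def _codons(rng, n):
    out = []
    while len(out) < n:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in ("TAA", "TAG", "TGA"):
            out.append(c)
    return out


def _toy_locus(seed=0, n_codons=30, intron_at=15, intron_len=60):
    """A coding gene with one intron; returns (genomic_seq, intron_interval)."""
    rng = np.random.default_rng(seed)
    cds = ["ATG"] + _codons(rng, n_codons - 2) + ["TAA"]
    body = "".join(cds)
    cut = intron_at * 3
    intron = "GT" + "".join(rng.choice(list("ACGT"), size=intron_len - 4)) + "AG"
    genomic = body[:cut] + intron + body[cut:]
    return genomic, (cut, cut + intron_len)


def test_projection_identity():
    genomic, intron = _toy_locus(seed=1)
    msa = {"src": genomic, "tgt": genomic}
    proj = project_boundaries("src", "tgt", msa, intron)
    assert proj.projected_intron == intron
    assert proj.frame_ok and not proj.failed
    assert proj.exon_flank_identity == pytest.approx(1.0)


def test_projection_shifts_with_upstream_insertion():
    """A 3 nt insertion upstream of the intron in the target shifts both
    projected boundaries by +3."""
    genomic, (d, a) = _toy_locus(seed=2)
    target = genomic[:9] + "GCT" + genomic[9:]
    msa = {"src": genomic[:9] + "---" + genomic[9:], "tgt": target}
    proj = project_boundaries("src", "tgt", msa, (d, a))
    assert proj.projected_intron == (d + 3, a + 3)
    assert proj.frame_ok


def test_projection_slides_to_restore_frame():
    """When the aligned boundary leaves a frame-breaking 2 nt offset in the
    target, a small slide restores an open reading frame."""
    genomic, (d, a) = _toy_locus(seed=3)
    # target's real intron starts 2 nt later than the source's
    exon1, intron_seq, exon2 = genomic[:d], genomic[d:a], genomic[a:]
    target = exon1 + "CA" + intron_seq + exon2[2:]
    # ungapped alignment of equal lengths: columns map 1:1
    msa = {"src": genomic, "tgt": target}
    proj = project_boundaries("src", "tgt", msa, (d, a))
    assert proj.frame_ok
    nd, na = proj.projected_intron
    joined = (target[:nd] + target[na:])
    assert len(joined) % 3 == 0
    stops = {"TAA", "TAG", "TGA"}
    assert all(joined[i:i + 3] not in stops for i in range(0, len(joined) - 3, 3))


def test_projection_failure_flagged():
    genomic, intron = _toy_locus(seed=4)
    # target aligned as all gaps around the boundary: unmappable
    msa = {"src": genomic, "tgt": "-" * len(genomic)}
    with pytest.raises(Exception):
        # degenerate target (no residues) cannot be projected meaningfully
        proj = project_boundaries("src", "tgt", msa, intron)
        assert proj.failed
        raise RuntimeError


# ---------------------------------------------------------------------------
# MSA identity


def test_identity_trivial_pairs():
    assert mean_pairwise_identity({"a": "MKV", "b": "MKV"}).mean_pairwise_identity == 100.0
    assert mean_pairwise_identity({"a": "AAAA", "b": "AABB"}).mean_pairwise_identity == 50.0


def test_identity_three_sequences_matches_all_pairs_mean():
    msa = {"a": "MKVL-A", "b": "MKIL-A", "c": "MRVLGA"}
    pairs = [("a", "b"), ("a", "c"), ("b", "c")]
    vals = []
    for x, y in pairs:
        sx, sy = msa[x], msa[y]
        cols = [(p, q) for p, q in zip(sx, sy) if not (p == "-" and q == "-")]
        vals.append(sum(1 for p, q in cols if p == q and p != "-") / len(cols))
    expected = 100 * sum(vals) / 3
    assert mean_pairwise_identity(msa).mean_pairwise_identity == pytest.approx(expected)


def test_identity_requires_flush_alignment():
    with pytest.raises(ValueError):
        mean_pairwise_identity({"a": "MKV", "b": "MK"})
    with pytest.raises(ValueError):
        mean_pairwise_identity({"a": "MKV"})
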