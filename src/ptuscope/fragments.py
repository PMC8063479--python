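"""Transcription patterns of fragmented gene pairs, and the RNA-editing scan.

Several chloroplast genes in siphonous green algae are split by an internal
frameshift into two consecutive reading frames (a and b).  Whether the two
pieces travel on one mRNA is decided here from full-length read coverage,
with the same strict full-coverage rule used for cistronic typing.  The
editing scan asks whether any reproducible high-frequency mismatch exists
that could restore a continuous reading frame post-transcriptionally.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignments import MismatchRecord, ReadAlignment
from .annotation import GenomeAnnotation
from .ptu import genes_fully_covered

DEFAULT_MIN_READS = 5
DEFAULT_CO_RATIO = 0.5
DEFAULT_EDITING_MIN_FREQ = 0.5
DEFAULT_EDITING_MIN_DEPTH = 10

TRANSITIONS = {("C", "T"), ("T", "C"), ("A", "G"), ("G", "A")}


@dataclass
class CotranscriptionCall:
    pair: tuple[str, str]
    n_span_both: int
    n_only_a: int
    n_only_b: int
    verdict: str        # co_transcribed | separate | mixed | insufficient


@dataclass
class EditingSite:
    pos: int
    genome_base: str
    edited_base: str
    frequency: float
    depth: int


def classify_fragment_pair(
    alignments: list[ReadAlignment],
    annotation: GenomeAnnotation,
    pair: tuple[str, str],
    min_reads: int = DEFAULT_MIN_READS,
    co_ratio: float = DEFAULT_CO_RATIO,
    coverage_slack: int = 0,
) -> CotranscriptionCall:
    """Decide whether a declared fragment pair is co-transcribed.

    Reads fully covering both fragments (same full-coverage rule as cistronic
    typing) count as spanning; truncated reads fully covering exactly one
    fragment count as only-a / only-b.  Verdict:

    * co_transcribed — spanning / (spanning + singles) >= co_ratio
    * separate — no spanning read and singles >= min_reads
    * insufficient — fewer than min_reads informative reads
    * mixed — anything else
    """
    a_id, b_id = pair
    if pair not in annotation.fragment_pairs and (b_id, a_id) not in annotation.fragment_pairs:
        raise KeyError(f"pair {pair} not declared in annotation")
    n_both = n_a = n_b = 0
    for r in alignments:
        intact = {g.gene_id for g in genes_fully_covered(r, annotation, coverage_slack)}
        has_a, has_b = a_id in intact, b_id in intact
        if has_a and has_b:
            n_both += 1
        elif has_a:
            n_a += 1
        elif has_b:
            n_b += 1
    total = n_both + n_a + n_b
    if total < min_reads:
        verdict = "insufficient"
    elif n_both == 0 and (n_a + n_b) >= min_reads:
        verdict = "separate"
    elif n_both / total >= co_ratio:
        verdict = "co_transcribed"
    else:
        verdict = "mixed"
    return CotranscriptionCall(pair=pair, n_span_both=n_both,
                               n_only_a=n_a, n_only_b=n_b, verdict=verdict)


def scan_rna_editing(
    mismatch_records: list[MismatchRecord],
    annotation: GenomeAnnotation | None = None,
    regions: list[str] | None = None,
    editing_min_freq: float = DEFAULT_EDITING_MIN_FREQ,
    editing_min_depth: int = DEFAULT_EDITING_MIN_DEPTH,
    transitions_only: bool = False,
) -> list[EditingSite]:
    """Candidate RNA-editing sites from a mismatch pileup.

    A site qualifies when one alternative base reaches ``editing_min_freq``
    of the read depth at a position with depth >= ``editing_min_depth``,
    optionally restricted to C<->T / A<->G transitions and to the spans of
    the named genes.
    """
    spans = None
    if regions is not None:
        if annotation is None:
            raise ValueError("regions filter requires the annotation")
        spans = [annotation.gene(g).span() for g in regions]
    out: list[EditingSite] = []
    for rec in mismatch_records:
        if rec.depth < editing_min_depth:
            continue
        if spans is not None and not any(s <= rec.pos < e for s, e in spans):
            continue
        for alt, count in sorted(rec.read_base_counts.items()):
            if transitions_only and (rec.genome_base, alt) not in TRANSITIONS:
                continue
            freq = count / rec.depth
            if freq >= editing_min_freq:
                out.append(EditingSite(pos=rec.pos, genome_base=rec.genome_base,
                                       edited_base=alt, frequency=freq,
                                       depth=rec.depth))
    return out


def write_fragment_tsv(calls: list[CotranscriptionCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tn_span_both\tn_only_a\tn_only_b\tverdict\n")
        for c in calls:
            fh.write(f"{c.pair[0]}\t{c.pair[1]}\t{c.n_span_both}\t{c.n_only_a}\t"
                     f"{c.n_only_b}\t{c.verdict}\n")


def write_editing_tsv(sites: list[EditingSite], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("pos\tgenome_base\tedited_base\tfrequency\tdepth\n")
        for s in sites:
            fh.write(f"{s.pos}\t{s.genome_base}\t{s.edited_base}\t"
                     f"{s.frequency:.4f}\t{s.depth}\n")
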