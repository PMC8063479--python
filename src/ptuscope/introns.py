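"""Intron calling, annotation reconciliation, retention quantification,
group II consensus scoring, and cross-species boundary projection.

Junction evidence from spliced long reads is base-precise, so an annotated
intron only counts as *confirmed* when its interval matches an observed
junction exactly; any disagreement is a boundary correction.  Consensus
scoring follows the classic group II intron signature: 5'-GUGYG boundary,
AY 3' terminus, and the catalytic AGC/CGC triad near domain V towards the
intron 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .alignments import JunctionObservation, ReadAlignment
from .annotation import GenomeAnnotation

FIVE_PRIME_CONSENSUS = "GTGYG"
THREE_PRIME_CONSENSUS = "AY"
DEFAULT_RETENTION_FLANK = 20
DEFAULT_SLIDE_WINDOW = 9
DEFAULT_TRIAD_WINDOW = 60

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class IntronCall:
    gene_id: str
    intron_index: int          # 1-based, 5'→3' in transcription direction
    start: int
    end: int
    strand: str
    support: int
    retention_support: int = 0


@dataclass
class IntronComparison:
    gene_id: str
    status: str                # confirmed | boundary_corrected | missed_by_prediction | spurious_prediction
    old_interval: tuple[int, int] | None
    new_interval: tuple[int, int] | None


@dataclass
class RetentionEstimate:
    gene_id: str
    intron_index: int
    fraction_retained: float | None   # None when no spanning reads (flagged)
    n_spliced: int
    n_retained: int
    isoform_lengths: list[int]


@dataclass
class BoundaryConsensusScore:
    intron_id: str
    five_prime_seq: str
    three_prime_seq: str
    five_prime_mismatches: int
    three_prime_match: bool
    canonical: bool
    triad_present: bool


@dataclass
class BoundaryProjection:
    source_gene: str
    target_seq_id: str
    projected_intron: tuple[int, int] | None
    frame_ok: bool
    exon_flank_identity: float
    failed: bool = False


@dataclass
class MsaIdentityResult:
    n_seqs: int
    mean_pairwise_identity: float     # percent


# ---------------------------------------------------------------------------
# Calling & reconciliation


def call_introns(
    junctions: list[JunctionObservation],
    annotation: GenomeAnnotation,
    min_support: int = 1,
) -> tuple[list[IntronCall], list[JunctionObservation]]:
    """Assign supported junctions to same-strand genes as intron calls.

    A junction becomes an intron call of the gene whose genomic span contains
    it on the same strand; junctions in intergenic space are returned
    separately.  Calls are indexed 5'→3' along each gene's transcription
    direction.
    """
    per_gene: dict[str, list[IntronCall]] = {}
    intergenic: list[JunctionObservation] = []
    for j in junctions:
        if j.support < min_support:
            continue
        host = None
        for g in annotation.genes:
            if g.category == "intronic_ORF" or g.strand != j.strand:
                continue
            gs, ge = g.span()
            if gs <= j.donor and j.acceptor <= ge:
                host = g
                break
        if host is None:
            intergenic.append(j)
            continue
        per_gene.setdefault(host.gene_id, []).append(IntronCall(
            gene_id=host.gene_id, intron_index=0,
            start=j.donor, end=j.acceptor, strand=j.strand, support=j.support,
        ))
    calls: list[IntronCall] = []
    for gid in sorted(per_gene):
        g = annotation.gene(gid)
        ordered = sorted(per_gene[gid], key=lambda c: c.start,
                         reverse=(g.strand == "-"))
        for i, c in enumerate(ordered, 1):
            c.intron_index = i
        calls.extend(ordered)
    return calls, intergenic


def compare_with_annotation(
    calls: list[IntronCall],
    annotation: GenomeAnnotation,
) -> list[IntronComparison]:
    """Reconcile observed intron calls with annotation-predicted introns.

    Per gene, predicted introns (gaps between annotated exons) are matched to
    observed calls by interval overlap: equal intervals are confirmed,
    overlapping-but-unequal are boundary corrections, observed-only introns
    were missed by prediction, and predicted-only introns are spurious
    (callers should supply calls derived from reads that do cover the gene,
    so absence of splicing evidence means the reads ran through the
    interval continuously).
    """
    by_gene: dict[str, list[IntronCall]] = {}
    for c in calls:
        by_gene.setdefault(c.gene_id, []).append(c)
    out: list[IntronComparison] = []
    for g in annotation.genes:
        if g.category == "intronic_ORF":
            continue
        predicted = g.introns()
        observed = [(c.start, c.end) for c in by_gene.get(g.gene_id, [])]
        if not predicted and not observed:
            continue
        used_obs: set[tuple[int, int]] = set()
        for p in predicted:
            match = None
            for o in observed:
                if o in used_obs:
                    continue
                if o == p:
                    match = ("confirmed", o)
                    break
                if o[0] < p[1] and p[0] < o[1]:
                    match = ("boundary_corrected", o)
                    break
            if match is None:
                out.append(IntronComparison(g.gene_id, "spurious_prediction", p, None))
            else:
                status, o = match
                used_obs.add(o)
                out.append(IntronComparison(g.gene_id, status, p, o))
        for o in observed:
            if o not in used_obs:
                out.append(IntronComparison(g.gene_id, "missed_by_prediction", None, o))
    return out


# ---------------------------------------------------------------------------
# Retention


def retention_fraction(
    alignments: list[ReadAlignment],
    call: IntronCall,
    genome_len: int,
    flank: int = DEFAULT_RETENTION_FLANK,
) -> RetentionEstimate:
    """Classify reads fully spanning [start-flank, end+flank) as spliced
    (block gap matching the intron exactly) versus retained (continuous
    alignment across the interval); report the retained fraction and the
    distinct spliced-read lengths (isoforms)."""
    lo, hi = call.start - flank, call.end + flank
    n_spliced = n_retained = 0
    lengths: set[int] = set()
    for r in alignments:
        cov = r.coverage_mask(genome_len)
        left = cov[max(lo, 0):call.start].all() and call.start - max(lo, 0) > 0
        right = cov[call.end:min(hi, genome_len)].all() and min(hi, genome_len) - call.end > 0
        if not (left and right):
            continue
        has_gap = any(d == call.start and a == call.end for d, a, _ in r.gaps(genome_len))
        if has_gap:
            n_spliced += 1
            lengths.add(r.aligned_length)
        elif cov[call.start:call.end].all():
            n_retained += 1
            lengths.add(r.aligned_length)
    total = n_spliced + n_retained
    frac = (n_retained / total) if total else None
    return RetentionEstimate(
        gene_id=call.gene_id, intron_index=call.intron_index,
        fraction_retained=frac, n_spliced=n_spliced, n_retained=n_retained,
        isoform_lengths=sorted(lengths),
    )


# ---------------------------------------------------------------------------
# Consensus scoring


def _iupac_match(base: str, code: str) -> bool:
    try:
        return base in IUPAC[code]
    except KeyError:
        raise ValueError(f"invalid IUPAC code {code!r}") from None


def score_group2_boundaries(
    intron_seq: str,
    intron_id: str = "intron",
    domain_v_window: tuple[int, int] | None = None,
) -> BoundaryConsensusScore:
    """Score an intron sequence against the group II boundary consensus.

    The first 5 nt are compared position-wise to GTGYG and the last 2 nt to
    AY (IUPAC Y = C/T); ``canonical`` requires a perfect match at both ends.
    The catalytic triad (AGC, or CGC in some introns) is searched within
    ``domain_v_window`` (intron-local coordinates), defaulting to the 3'-most
    60 nt where domain V sits.
    """
    seq = intron_seq.upper().replace("U", "T")
    if len(seq) < 10:
        raise ValueError("intron sequence shorter than 10 nt")
    five = seq[:5]
    three = seq[-2:]
    five_mm = sum(0 if _iupac_match(b, c) else 1
                  for b, c in zip(five, FIVE_PRIME_CONSENSUS))
    three_ok = all(_iupac_match(b, c) for b, c in zip(three, THREE_PRIME_CONSENSUS))
    if domain_v_window is None:
        window_seq = seq[-DEFAULT_TRIAD_WINDOW:]
    else:
        ws, we = domain_v_window
        window_seq = seq[ws:we]
    triad = any(window_seq[i:i + 3] in ("AGC", "CGC")
                for i in range(max(len(window_seq) - 2, 0)))
    return BoundaryConsensusScore(
        intron_id=intron_id,
        five_prime_seq=five,
        three_prime_seq=three,
        five_prime_mismatches=five_mm,
        three_prime_match=three_ok,
        canonical=(five_mm == 0 and three_ok),
        triad_present=triad,
    )


def iupac_scan(seq: str, pattern: str, both_strands: bool = False) -> list[int]:
    """All start positions where `seq` matches the IUPAC `pattern`
    (e.g. the CYGAAAGG element upstream of domain V)."""
    if not pattern:
        raise ValueError("empty pattern")
    seq = seq.upper().replace("U", "T")
    pattern = pattern.upper().replace("U", "T")
    for c in pattern:
        if c not in IUPAC:
            raise ValueError(f"invalid IUPAC code {c!r}")
    hits = [i for i in range(len(seq) - len(pattern) + 1)
            if all(_iupac_match(seq[i + k], pattern[k]) for k in range(len(pattern)))]
    if both_strands:
        rc = str(Seq(pattern).reverse_complement())
        hits += [i for i in range(len(seq) - len(rc) + 1)
                 if all(_iupac_match(seq[i + k], rc[k]) for k in range(len(rc)))
                 and i not in hits]
        hits = sorted(set(hits))
    return hits


# ---------------------------------------------------------------------------
# Boundary projection through an MSA


def _ungapped_to_column(aligned: str) -> list[int]:
    """column index of each ungapped position"""
    return [i for i, c in enumerate(aligned) if c != "-"]


def _column_to_ungapped(aligned: str) -> dict[int, int]:
    out, k = {}, 0
    for i, c in enumerate(aligned):
        if c != "-":
            out[i] = k
            k += 1
    return out


def project_boundaries(
    source_id: str,
    target_id: str,
    msa: dict[str, str],
    intron: tuple[int, int],
    source_gene: str = "",
    slide_window: int = DEFAULT_SLIDE_WINDOW,
    flank_columns: int = 15,
) -> BoundaryProjection:
    """Project a confirmed intron interval from a source genomic sequence to a
    homolog through a (multiple) sequence alignment.

    The donor/acceptor positions (ungapped source coordinates) are mapped
    through alignment columns to target coordinates, then slid up to
    ``slide_window`` nt to the nearest offsets where the joined target exons
    keep an open reading frame (length a multiple of 3, no internal stop).
    ``exon_flank_identity`` is the source/target identity over ±flank_columns
    alignment columns around both boundaries.
    """
    if source_id not in msa or target_id not in msa:
        raise KeyError("source or target missing from alignment")
    src_aln, tgt_aln = msa[source_id].upper(), msa[target_id].upper()
    if len(src_aln) != len(tgt_aln):
        raise ValueError("ragged alignment")
    src_cols = _ungapped_to_column(src_aln)
    tgt_by_col = _column_to_ungapped(tgt_aln)
    tgt_seq = tgt_aln.replace("-", "")

    def map_pos(src_pos: int) -> int | None:
        """Map an ungapped source position to an ungapped target position,
        sliding right past target gap columns up to slide_window."""
        if src_pos >= len(src_cols):
            return None
        col = src_cols[src_pos]
        for d in range(slide_window + 1):
            for c in (col + d, col - d):
                if c in tgt_by_col and 0 <= c < len(src_aln):
                    return tgt_by_col[c]
        return None

    donor, acceptor = intron
    t_donor, t_acceptor = map_pos(donor), map_pos(acceptor)
    flank_id = _flank_identity(src_aln, tgt_aln,
                               [src_cols[min(donor, len(src_cols) - 1)],
                                src_cols[min(acceptor, len(src_cols) - 1)]],
                               flank_columns)
    if t_donor is None or t_acceptor is None or t_acceptor <= t_donor:
        return BoundaryProjection(source_gene or source_id, target_id, None,
                                  False, flank_id, failed=True)

    best = None
    for total in range(0, 2 * slide_window + 1):
        for dd in range(-min(total, slide_window), min(total, slide_window) + 1):
            da_mag = total - abs(dd)
            if da_mag > slide_window:
                continue
            for da in ({0} if da_mag == 0 else {da_mag, -da_mag}):
                nd, na = t_donor + dd, t_acceptor + da
                if not (0 < nd < na <= len(tgt_seq)):
                    continue
                joined = tgt_seq[:nd] + tgt_seq[na:]
                if _orf_open(joined):
                    best = (nd, na)
                    break
            if best:
                break
        if best:
            break
    if best is None:
        return BoundaryProjection(source_gene or source_id, target_id,
                                  (t_donor, t_acceptor), False, flank_id)
    return BoundaryProjection(source_gene or source_id, target_id, best,
                              True, flank_id)


def _orf_open(seq: str) -> bool:
    if len(seq) % 3 != 0:
        return False
    stops = {"TAA", "TAG", "TGA"}
    for i in range(0, len(seq) - 3, 3):   # internal codons only
        if seq[i:i + 3] in stops:
            return False
    return True


def _flank_identity(src_aln: str, tgt_aln: str, cols: list[int], flank: int) -> float:
    match = total = 0
    seen: set[int] = set()
    for col in cols:
        for c in range(max(col - flank, 0), min(col + flank + 1, len(src_aln))):
            if c in seen:
                continue
            seen.add(c)
            a, b = src_aln[c], tgt_aln[c]
            if a == "-" and b == "-":
                continue
            total += 1
            if a == b:
                match += 1
    return match / total if total else 0.0


# ---------------------------------------------------------------------------
# MSA identity


def mean_pairwise_identity(msa: dict[str, str]) -> MsaIdentityResult:
    """Mean pairwise percent identity of an alignment (protein or DNA).

    Per pair: matches / columns where not both sequences are gapped.
    """
    ids = list(msa)
    if len(ids) < 2:
        raise ValueError("need >= 2 sequences")
    length = len(msa[ids[0]])
    for k in ids:
        if len(msa[k]) != length:
            raise ValueError("ragged alignment")
    idents = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = msa[ids[i]].upper(), msa[ids[j]].upper()
            total = match = 0
            for x, y in zip(a, b):
                if x == "-" and y == "-":
                    continue
                total += 1
                if x == y and x != "-":
                    match += 1
            idents.append(match / total if total else 0.0)
    return MsaIdentityResult(n_seqs=len(ids),
                             mean_pairwise_identity=100.0 * sum(idents) / len(idents))


def translate_spliced(genomic: str, intron: tuple[int, int]) -> str:
    """Protein from the joined exons of a single-intron gene; a spliced
    length that is not a multiple of 3 (a frameshifting misannotation) is
    truncated to whole codons before translation."""
    joined = genomic[:intron[0]] + genomic[intron[1]:]
    joined = joined[: 3 * (len(joined) // 3)]
    return str(Seq(joined).translate())


def read_aligned_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_introns_tsv(calls: list[IntronCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tintron_index\tstart\tend\tstrand\tsupport\tretention_support\n")
        for c in calls:
            fh.write(f"{c.gene_id}\t{c.intron_index}\t{c.start}\t{c.end}\t"
                     f"{c.strand}\t{c.support}\t{c.retention_support}\n")


def write_comparison_tsv(comparisons: list[IntronComparison], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tstatus\told_start\told_end\tnew_start\tnew_end\n")
        for c in comparisons:
            old = c.old_interval or (".", ".")
            new = c.new_interval or (".", ".")
            fh.write(f"{c.gene_id}\t{c.status}\t{old[0]}\t{old[1]}\t{new[0]}\t{new[1]}\n")
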