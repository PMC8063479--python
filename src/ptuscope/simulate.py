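"""Synthetic circular plastomes with operon-structured transcription and
FLNC-style spliced long reads, with full ground truth.

The generator emulates the features of full-length non-chimeric cDNA data
over a circular chloroplast genome: polycistronic transcripts spanning
operons (PTUs), independent 5'/3' truncation of each read, intron splicing
with optional retention, strand-specific reads, substitution-type sequencing
mismatches, fragmented gene pairs transcribed either together or separately,
and planted RNA-editing sites.  Every run is fully deterministic given the
seed (integer RNG streams; no float-order dependence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam
from Bio.Seq import Seq

from .alignments import AlignedBlock, ReadAlignment, write_block_table
from .annotation import GeneModel, GenomeAnnotation, GenomeSequence

BASES = np.array(list("ACGT"))
STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic run.

    Defaults mirror a ~130 kb circular plastome with 16 operon blocks of up
    to 9 genes, geometric per-end read truncation, ~1% substitution noise and
    occasional intron retention.
    """

    seed: int = 0
    genome_len: int = 130_000
    n_ptus: int = 16
    genes_per_ptu: tuple[int, int] = (1, 9)
    strand_flip_prob: float = 0.5
    introns_per_gene: tuple[int, int] = (0, 2)
    intron_len_range: tuple[int, int] = (300, 900)
    retention_prob: float = 0.1
    truncation: float = 0.2              # per-end geometric parameter t; P(remove k)=(1-t)t^k
    reads_per_ptu: tuple[int, int] = (20, 50)
    mismatch_rate: float = 0.01
    fragment_pairs_spec: list[str] = field(default_factory=list)   # "co" | "separate"
    editing_sites_spec: list[tuple[int, int, str, float]] = field(default_factory=list)
    # (gene_index, offset_within_gene_span, alt_base, frequency)
    gene_len_range: tuple[int, int] = (300, 1200)
    intergenic_within: tuple[int, int] = (60, 200)
    intergenic_between: tuple[int, int] = (400, 900)
    canonical_intron_ends: bool = True
    min_read_len: int = 50
    categories: tuple[str, ...] = ("protein_coding", "protein_coding",
                                   "protein_coding", "ORF", "tRNA")

    def __post_init__(self):
        for p in (self.strand_flip_prob, self.retention_prob, self.truncation,
                  self.mismatch_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0,1]")
        if self.truncation >= 1.0:
            raise ValueError("truncation parameter must be < 1")


@dataclass
class GroundTruth:
    true_ptus: list[tuple[str, tuple[str, ...]]]       # (strand, genes in tx order)
    true_introns: dict[str, list[tuple[int, int]]]     # per gene, genome intervals
    true_editing: list[tuple[int, str, str, float]]    # (pos, ref, alt, freq)
    true_fragment_verdicts: dict[tuple[str, str], str]


@dataclass
class TranscriptRecord:
    read_id: str
    ptu_id: str
    strand: str
    blocks: list[tuple[int, int]]          # genomic segments, ascending
    retained_introns: list[tuple[int, int]]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.blocks)


# ---------------------------------------------------------------------------
# Genome generation


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons-2) non-stop codons + stop."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_dna(rng, 3)
        if c not in STOPS:
            codons.append(c)
    codons.append(["TAA", "TAG", "TGA"][int(rng.integers(0, 3))])
    return "".join(codons)


def _intron_seq(rng: np.random.Generator, length: int, canonical: bool) -> str:
    body = _random_dna(rng, length)
    if not canonical:
        return body
    y1 = "CT"[int(rng.integers(0, 2))]
    y2 = "CT"[int(rng.integers(0, 2))]
    seq = "GTG" + y1 + "G" + body[5:-2] + "A" + y2
    # plant the domain-V catalytic triad inside the 3'-most 60 nt
    triad_at = length - 2 - int(rng.integers(10, 50))
    seq = seq[:triad_at] + "AGC" + seq[triad_at + 3:]
    return seq[:length]


def simulate_genome(config: SimulationConfig) -> tuple[GenomeAnnotation, GroundTruth]:
    """Generate a circular genome + annotation with known operon structure.

    Genes are laid out left to right without same-strand overlap, grouped
    into PTU blocks separated by long intergenic gaps; declared introns are
    inserted into gene bodies (with group II consensus ends when
    ``canonical_intron_ends``); fragment pairs are built by splitting a CDS
    with a 1 nt frameshift into adjacent a/b models.
    """
    rng = np.random.default_rng([config.seed, 0])
    pieces: list[str] = []
    cursor = 0
    genes: list[GeneModel] = []
    true_ptus: list[tuple[str, tuple[str, ...]]] = []
    true_introns: dict[str, list[tuple[int, int]]] = {}
    frag_verdicts: dict[tuple[str, str], str] = {}
    gene_counter = 0

    def emit_gap(lo: int, hi: int):
        nonlocal cursor
        n = int(rng.integers(lo, hi + 1))
        pieces.append(_random_dna(rng, n))
        cursor += n

    def emit_gene(name: str, category: str, strand: str, n_introns: int,
                  fragment_of: str | None = None, frameshift: bool = False) -> GeneModel:
        nonlocal cursor
        if category == "tRNA":
            body = _random_dna(rng, int(rng.integers(72, 91)))
        else:
            n_codons = int(rng.integers(config.gene_len_range[0] // 3,
                                        config.gene_len_range[1] // 3 + 1))
            body = _random_cds(rng, n_codons)
            if frameshift:
                body = body + _random_dna(rng, 1)   # 1 nt frameshift tail
        # insert introns at interior positions (genomic sense)
        if n_introns > 0 and len(body) >= 120:
            cut_points = sorted(
                int(p) for p in rng.choice(np.arange(30, len(body) - 30),
                                           size=n_introns, replace=False)
            )
        else:
            cut_points = []
        exon_pieces: list[str] = []
        intron_pieces: list[str] = []
        prev = 0
        for cp in cut_points:
            exon_pieces.append(body[prev:cp])
            ilen = int(rng.integers(config.intron_len_range[0],
                                    config.intron_len_range[1] + 1))
            iseq = _intron_seq(rng, ilen, config.canonical_intron_ends)
            if strand == "-":
                # genome stores the forward strand; the transcribed intron
                # must carry the consensus in transcript orientation
                iseq = str(Seq(iseq).reverse_complement())
            intron_pieces.append(iseq)
            prev = cp
        exon_pieces.append(body[prev:])
        exons: list[tuple[int, int]] = []
        introns: list[tuple[int, int]] = []
        pos = cursor
        for i, ep in enumerate(exon_pieces):
            pieces.append(ep)
            exons.append((pos, pos + len(ep)))
            pos += len(ep)
            if i < len(intron_pieces):
                pieces.append(intron_pieces[i])
                introns.append((pos, pos + len(intron_pieces[i])))
                pos += len(intron_pieces[i])
        cursor = pos
        if strand == "-":
            tx_exons = list(reversed(exons))
        else:
            tx_exons = exons
        g = GeneModel(gene_id=name, name=name, category=category, strand=strand,
                      exons=tx_exons, fragment_of=fragment_of)
        genes.append(g)
        true_introns[name] = introns
        return g

    emit_gap(*config.intergenic_between)
    # regular PTUs
    for _p in range(config.n_ptus):
        strand = "-" if rng.random() < config.strand_flip_prob else "+"
        n_genes = int(rng.integers(config.genes_per_ptu[0], config.genes_per_ptu[1] + 1))
        members: list[str] = []
        for gi in range(n_genes):
            gene_counter += 1
            name = f"g{gene_counter:03d}"
            category = config.categories[int(rng.integers(0, len(config.categories)))]
            n_introns = (int(rng.integers(config.introns_per_gene[0],
                                          config.introns_per_gene[1] + 1))
                         if category != "tRNA" else 0)
            emit_gene(name, category, strand, n_introns)
            members.append(name)
            if gi < n_genes - 1:
                emit_gap(*config.intergenic_within)
        ordered = tuple(members if strand == "+" else list(reversed(members)))
        true_ptus.append((strand, ordered))
        emit_gap(*config.intergenic_between)
    # fragment pairs, each in a dedicated block
    for fi, pattern in enumerate(config.fragment_pairs_spec, 1):
        if pattern not in ("co", "separate"):
            raise ValueError(f"fragment pattern {pattern!r} must be co|separate")
        strand = "+"
        parent = f"frag{fi}"
        a = emit_gene(f"{parent}a", "protein_coding", strand, 0,
                      fragment_of=parent, frameshift=True)
        emit_gap(*config.intergenic_within)
        b = emit_gene(f"{parent}b", "protein_coding", strand, 0, fragment_of=parent)
        if pattern == "co":
            true_ptus.append((strand, (a.gene_id, b.gene_id)))
            frag_verdicts[(a.gene_id, b.gene_id)] = "co_transcribed"
        else:
            true_ptus.append((strand, (a.gene_id,)))
            true_ptus.append((strand, (b.gene_id,)))
            frag_verdicts[(a.gene_id, b.gene_id)] = "separate"
        emit_gap(*config.intergenic_between)

    if cursor > config.genome_len:
        raise ValueError(
            f"annotation needs {cursor} bp but genome_len is {config.genome_len}; "
            "increase genome_len"
        )
    pieces.append(_random_dna(rng, config.genome_len - cursor))
    seq = "".join(pieces)

    # resolve planted editing sites (force the genomic base away from alt)
    true_editing: list[tuple[int, str, str, float]] = []
    seq_list = list(seq)
    all_genes = genes
    for gene_index, offset, alt, freq in config.editing_sites_spec:
        g = all_genes[gene_index]
        pos = g.span()[0] + offset
        if seq_list[pos] == alt:
            seq_list[pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[alt]
        true_editing.append((pos, seq_list[pos], alt, freq))
    seq = "".join(seq_list)

    genome = GenomeSequence(id=f"synth_plastome_seed{config.seed}", seq=seq, circular=True)
    annotation = GenomeAnnotation(genome=genome, genes=genes)
    truth = GroundTruth(true_ptus=true_ptus, true_introns=true_introns,
                        true_editing=true_editing,
                        true_fragment_verdicts=frag_verdicts)
    return annotation, truth


# ---------------------------------------------------------------------------
# Transcript simulation


def simulate_transcripts(
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    config: SimulationConfig,
) -> list[TranscriptRecord]:
    """Emit per-PTU transcripts: full PTU span, independently truncated at
    both ends (geometric overhang removal in transcript coordinates), each
    intron spliced with probability 1 - retention_prob."""
    rng = np.random.default_rng([config.seed, 1])
    out: list[TranscriptRecord] = []
    read_no = 0
    # "separate" fragment pairs are already encoded as two single-gene units
    # in truth.true_ptus, so their reads never span both fragments
    for unit_index, (strand, gene_ids) in enumerate(truth.true_ptus):
        span = _unit_span(annotation, gene_ids)
        introns = [iv for g in gene_ids for iv in truth.true_introns.get(g, [])]
        n_reads = int(rng.integers(config.reads_per_ptu[0], config.reads_per_ptu[1] + 1))
        for _ in range(n_reads):
            read_no += 1
            spliced = [iv for iv in sorted(introns)
                       if rng.random() >= config.retention_prob]
            blocks = _subtract(span, spliced)
            blocks = _truncate(blocks, strand, config.truncation, rng)
            if sum(e - s for s, e in blocks) < config.min_read_len:
                continue
            retained = [iv for iv in introns if iv not in spliced]
            out.append(TranscriptRecord(
                read_id=f"read{read_no:06d}",
                ptu_id=f"unit{unit_index + 1:03d}",
                strand=strand,
                blocks=blocks,
                retained_introns=retained,
            ))
    return out


def _unit_span(annotation: GenomeAnnotation, gene_ids: tuple[str, ...]) -> tuple[int, int]:
    starts = [annotation.gene(g).span()[0] for g in gene_ids]
    ends = [annotation.gene(g).span()[1] for g in gene_ids]
    return min(starts), max(ends)


def _subtract(span: tuple[int, int], introns: list[tuple[int, int]]) -> list[tuple[int, int]]:
    blocks = []
    pos = span[0]
    for s, e in introns:
        if s >= pos:
            if s > pos:
                blocks.append((pos, s))
            pos = e
    if pos < span[1]:
        blocks.append((pos, span[1]))
    return blocks


def _truncate(blocks: list[tuple[int, int]], strand: str, t: float,
              rng: np.random.Generator) -> list[tuple[int, int]]:
    # one geometric draw per transcript end; t=0 removes nothing
    r_left = int(rng.geometric(1.0 - t)) - 1
    r_right = int(rng.geometric(1.0 - t)) - 1
    if strand == "-":                # 5' of the transcript is the right end
        r_left, r_right = r_right, r_left
    return _trim(blocks, r_left, r_right)


def _trim(blocks: list[tuple[int, int]], left: int, right: int) -> list[tuple[int, int]]:
    out = [list(b) for b in blocks]
    while left > 0 and out:
        take = min(left, out[0][1] - out[0][0])
        out[0][0] += take
        left -= take
        if out[0][0] >= out[0][1]:
            out.pop(0)
    while right > 0 and out:
        take = min(right, out[-1][1] - out[-1][0])
        out[-1][1] -= take
        right -= take
        if out[-1][0] >= out[-1][1]:
            out.pop()
    return [tuple(b) for b in out]


# ---------------------------------------------------------------------------
# Emission


def _planted_mismatches(
    transcripts: list[TranscriptRecord],
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    config: SimulationConfig,
) -> dict[str, list[tuple[int, str, str]]]:
    """Deterministic per-read substitution lists: background noise at
    mismatch_rate plus the planted editing sites at their frequencies.
    Fresh RNG per call, so every emitter sees identical mismatches."""
    rng = np.random.default_rng([config.seed, 2])
    genome = annotation.genome
    out: dict[str, list[tuple[int, str, str]]] = {}
    for tr in transcripts:
        mism: list[tuple[int, str, str]] = []
        if config.mismatch_rate > 0:
            for s, e in tr.blocks:
                n = rng.binomial(e - s, config.mismatch_rate)
                if n == 0:
                    continue
                pos = np.sort(rng.choice(e - s, size=n, replace=False)) + s
                for p in pos:
                    ref = genome.seq[int(p)]
                    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                    mism.append((int(p), ref, alt))
        for pos, ref, alt, freq in truth.true_editing:
            if any(s <= pos < e for s, e in tr.blocks):
                if rng.random() < freq:
                    mism = [m for m in mism if m[0] != pos]
                    mism.append((pos, ref, alt))
        mism.sort()
        out[tr.read_id] = mism
    return out


def to_read_alignments(
    transcripts: list[TranscriptRecord],
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    config: SimulationConfig,
) -> list[ReadAlignment]:
    """The in-memory equivalent of emitting + reloading alignments."""
    mm = _planted_mismatches(transcripts, annotation, truth, config)
    return [
        ReadAlignment(
            read_id=tr.read_id, strand=tr.strand,
            blocks=[AlignedBlock(s, e) for s, e in tr.blocks],
            mismatches=mm[tr.read_id],
        )
        for tr in transcripts
    ]


def emit_alignments(
    transcripts: list[TranscriptRecord],
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    config: SimulationConfig,
    path: str,
    fmt: str = "block",
) -> None:
    """Write alignments as a block-table TSV (fmt="block") or SAM (fmt="sam").

    Both emissions load back (via :func:`ptuscope.alignments.load_alignments`)
    to identical ReadAlignment lists.
    """
    reads = to_read_alignments(transcripts, annotation, truth, config)
    if fmt == "block":
        write_block_table(reads, path)
        return
    if fmt != "sam":
        raise ValueError(f"unknown format {fmt!r}")
    genome = annotation.genome
    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": genome.id, "LN": genome.length}]}
    with pysam.AlignmentFile(path, "wh", header=header) as fh:
        for r in reads:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = r.read_id
            seg.flag = 16 if r.strand == "-" else 0
            seg.reference_id = 0
            seg.reference_start = r.blocks[0].start
            seg.mapping_quality = 60
            cigar = []
            for i, b in enumerate(r.blocks):
                if i > 0:
                    cigar.append((3, b.start - r.blocks[i - 1].end))   # N
                cigar.append((0, len(b)))                               # M
            seg.cigartuples = cigar
            mm = {p: alt for p, _ref, alt in (r.mismatches or [])}
            seq_parts = []
            for b in r.blocks:
                piece = list(genome.fetch(b.start, b.end))
                for p, alt in mm.items():
                    if b.start <= p < b.end:
                        piece[p - b.start] = alt
                seq_parts.append("".join(piece))
            seg.query_sequence = "".join(seq_parts)
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(seg.query_sequence))
            seg.set_tag("MD", _md_tag(r, genome, mm))
            seg.set_tag("NM", len(mm))
            fh.write(seg)


def _md_tag(r: ReadAlignment, genome: GenomeSequence, mm: dict[int, str]) -> str:
    parts = []
    run = 0
    for b in r.blocks:
        for p in range(b.start, b.end):
            if p in mm:
                parts.append(str(run))
                parts.append(genome.seq[p])
                run = 0
            else:
                run += 1
    parts.append(str(run))
    return "".join(parts)


def emit_reads_fasta(
    transcripts: list[TranscriptRecord],
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    config: SimulationConfig,
    path: str,
) -> None:
    """Spliced, strand-oriented read sequences (for running a real aligner)."""
    mm_by_read = _planted_mismatches(transcripts, annotation, truth, config)
    genome = annotation.genome
    with open(path, "w") as fh:
        for tr in transcripts:
            mm = {p: alt for p, _ref, alt in mm_by_read[tr.read_id]}
            parts = []
            for s, e in tr.blocks:
                piece = list(genome.fetch(s, e))
                for p, alt in mm.items():
                    if s <= p < e:
                        piece[p - s] = alt
                parts.append("".join(piece))
            seq = "".join(parts)
            if tr.strand == "-":
                seq = str(Seq(seq).reverse_complement())
            fh.write(f">{tr.read_id} unit={tr.ptu_id} strand={tr.strand}\n{seq}\n")


@dataclass
class HomologFamily:
    """A cross-species set of homologs of one intron-containing gene.

    All sequences share the intron at the same (conserved) position and the
    same length, so the genomic alignment is trivially gap-free: ``msa`` maps
    species id -> aligned (here: ungapped) genomic sequence.  ``misannotated``
    gives per-species intron intervals whose donor is shifted off the true
    boundary by a non-multiple of 3, breaking the downstream reading frame —
    the situation produced by automated annotation transferring boundaries
    poorly across species.
    """

    msa: dict[str, str]
    intron: tuple[int, int]
    misannotated: dict[str, tuple[int, int]]


def simulate_homolog_family(
    seed: int,
    n_species: int = 6,
    n_codons: int = 60,
    intron_len: int = 90,
    substitution_rate: float = 0.08,
    max_shift: int = 5,
) -> HomologFamily:
    """Homologs of a coding gene diverged by point substitutions, all
    carrying one intron at a conserved codon boundary."""
    rng = np.random.default_rng([seed, 7])
    base = _random_cds(rng, n_codons)
    cut = 3 * (n_codons // 2)
    msa: dict[str, str] = {}
    mis: dict[str, tuple[int, int]] = {}
    for si in range(n_species):
        cds = _mutate_cds(rng, base, substitution_rate)
        intron = _intron_seq(rng, intron_len, canonical=False)
        msa[f"sp{si}"] = cds[:cut] + intron + cds[cut:]
        shift = int(rng.integers(1, max_shift + 1))
        if shift % 3 == 0:
            shift += 1
        mis[f"sp{si}"] = (cut + shift, cut + intron_len)
    mis["sp0"] = (cut, cut + intron_len)   # the reference species is curated
    return HomologFamily(msa=msa, intron=(cut, cut + intron_len),
                         misannotated=mis)


def _mutate_cds(rng: np.random.Generator, cds: str, rate: float) -> str:
    out = list(cds)
    n = rng.binomial(len(cds) - 6, rate)
    positions = rng.choice(np.arange(3, len(cds) - 3), size=n, replace=False)
    for p in positions:
        out[int(p)] = str(rng.choice([b for b in "ACGT" if b != out[int(p)]]))
    # re-draw any codon the mutations turned into a stop
    for i in range(3, len(out) - 3, 3):
        while "".join(out[i:i + 3]) in STOPS:
            out[i + 2] = str(rng.choice(list("AC")))
    return "".join(out)


def write_ground_truth(truth: GroundTruth, prefix: str) -> None:
    with open(f"{prefix}_ptus.tsv", "w") as fh:
        fh.write("strand\tgenes\n")
        for strand, genes in truth.true_ptus:
            fh.write(f"{strand}\t{','.join(genes)}\n")
    with open(f"{prefix}_introns.tsv", "w") as fh:
        fh.write("gene_id\tstart\tend\n")
        for gid in sorted(truth.true_introns):
            for s, e in truth.true_introns[gid]:
                fh.write(f"{gid}\t{s}\t{e}\n")
    with open(f"{prefix}_editing.tsv", "w") as fh:
        fh.write("pos\tref\talt\tfreq\n")
        for pos, ref, alt, freq in truth.true_editing:
            fh.write(f"{pos}\t{ref}\t{alt}\t{freq}\n")
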