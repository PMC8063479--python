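"""Genome + annotation I/O for circular organellar genomes.

Reads GFF3 (via :mod:`gffutils`) or GenBank flat files (via Biopython) together
with a FASTA genome, converts everything to a single internal convention
(0-based half-open coordinates, exon chains in transcription order), and
provides ORF scanning and gene-sequence extraction.  Genes that wrap past the
origin of a circular genome are represented as exon chains whose pieces are
normalized into [0, L).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

from ._coords import Interval, chain_length, split_interval

GENE_CATEGORIES = ("protein_coding", "tRNA", "rRNA", "ORF", "intronic_ORF")
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class GenomeSequence:
    """A (usually circular) DNA molecule."""

    id: str
    seq: str
    circular: bool = True

    def __post_init__(self):
        object.__setattr__(self, "seq", self.seq.upper())
        if len(self.seq) == 0:
            raise ValueError("empty genome sequence")
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(f"non-DNA characters in genome: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, end: int) -> str:
        """Substring [start, end), wrapping across the origin if circular."""
        L = self.length
        pieces = split_interval(start, end, L)
        if len(pieces) > 1 and not self.circular:
            raise ValueError("interval wraps origin of a linear genome")
        return "".join(self.seq[s:e] for s, e in pieces)


@dataclass
class GeneModel:
    """One gene: ordered exon chain on the genome plus bookkeeping fields.

    ``exons`` are 0-based half-open intervals in *transcription order* (for a
    minus-strand gene the first exon is the one with the highest coordinates).
    """

    gene_id: str
    name: str
    category: str
    strand: str
    exons: list[Interval]
    fragment_of: str | None = None
    host_gene: str | None = None

    def __post_init__(self):
        if self.category not in GENE_CATEGORIES:
            raise ValueError(f"{self.gene_id}: unknown category {self.category!r}")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: no exons")
        for s, e in self.exons:
            if not 0 <= s < e:
                raise ValueError(f"{self.gene_id}: bad exon [{s},{e})")

    @property
    def exons_genomic(self) -> list[Interval]:
        """Exons sorted by genome coordinate (ignoring transcription order)."""
        return sorted(self.exons)

    @property
    def spliced_length(self) -> int:
        return chain_length(self.exons)

    def spans_origin(self, genome_len: int) -> bool:
        from ._coords import smallest_covering_arc

        _, arc_end = smallest_covering_arc(self.exons, genome_len)
        return arc_end > genome_len

    @property
    def tx_start(self) -> int:
        """Genome coordinate of the transcript 5' end."""
        s, e = self.exons[0]
        return s if self.strand == "+" else e - 1

    def span(self) -> Interval:
        ex = self.exons_genomic
        return ex[0][0], ex[-1][1]

    def introns(self) -> list[Interval]:
        """Gaps between consecutive exons, in genome-coordinate order."""
        ex = self.exons_genomic
        return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1) if ex[i][1] < ex[i + 1][0]]


@dataclass
class GenomeAnnotation:
    genome: GenomeSequence
    genes: list[GeneModel]
    fragment_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            for s, e in g.exons:
                if e > self.genome.length:
                    raise ValueError(
                        f"{g.gene_id}: exon [{s},{e}) outside genome of "
                        f"length {self.genome.length}"
                    )
        self._by_id = {g.gene_id: g for g in self.genes}
        if not self.fragment_pairs:
            self.fragment_pairs = _infer_fragment_pairs(self.genes)

    def gene(self, gene_id: str) -> GeneModel:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene_id {gene_id!r}") from None

    def genes_on_strand(self, strand: str) -> list[GeneModel]:
        return [g for g in self.genes if g.strand == strand]

    def intronic_orfs_of(self, gene_id: str) -> list[GeneModel]:
        return [g for g in self.genes if g.category == "intronic_ORF" and g.host_gene == gene_id]


def _infer_fragment_pairs(genes: list[GeneModel]) -> list[tuple[str, str]]:
    by_parent: dict[str, list[GeneModel]] = {}
    for g in genes:
        if g.fragment_of:
            by_parent.setdefault(g.fragment_of, []).append(g)
    pairs = []
    for parent, members in sorted(by_parent.items()):
        if len(members) == 2:
            a, b = sorted(members, key=lambda g: g.span()[0])
            pairs.append((a.gene_id, b.gene_id))
    return pairs


# ---------------------------------------------------------------------------
# Reading

_CATEGORY_ALIASES = {
    "mrna": "protein_coding",
    "cds": "protein_coding",
    "protein_coding": "protein_coding",
    "trna": "tRNA",
    "rrna": "rRNA",
    "orf": "ORF",
    "intronic_orf": "intronic_ORF",
}


def read_annotation(annotation_path: str, fasta_path: str, circular: bool = True) -> GenomeAnnotation:
    """Load a genome (FASTA) + gene models (GFF3 or GenBank flat file).

    GFF3 coordinates (1-based inclusive) are converted to the internal 0-based
    half-open convention.  Multi-exon genes are reconstructed from exon child
    features; two exon lines sharing a Parent whose second piece restarts at
    coordinate 0 encode an origin-spanning gene on a circular genome.
    """
    record = SeqIO.read(fasta_path, "fasta")
    genome = GenomeSequence(id=record.id, seq=str(record.seq), circular=circular)
    lower = os.path.basename(annotation_path).lower()
    if lower.endswith((".gb", ".gbk", ".gbff", ".genbank")):
        genes = _read_genbank_genes(annotation_path, genome.length)
    else:
        genes = _read_gff3_genes(annotation_path, genome.length)
    return GenomeAnnotation(genome=genome, genes=genes)


def _read_gff3_genes(path: str, genome_len: int) -> list[GeneModel]:
    try:
        db = gffutils.create_db(
            path, dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by="start"):
        exon_feats = list(db.children(feat.id, featuretype="exon", order_by="start"))
        if exon_feats:
            exons = [(f.start - 1, f.end) for f in exon_feats]
        else:
            exons = [(feat.start - 1, feat.end)]
        strand = feat.strand
        if strand not in "+-":
            raise ValueError(f"feature {feat.id}: missing strand")
        for s, e in exons:
            if not 0 <= s < e <= genome_len:
                raise ValueError(
                    f"feature {feat.id}: coordinates [{s + 1},{e}] outside "
                    f"genome of length {genome_len}"
                )
        exons = _transcription_order(exons, strand, genome_len)
        attrs = feat.attributes
        category = _CATEGORY_ALIASES.get(
            attrs.get("gene_category", ["protein_coding"])[0].lower(), None
        )
        if category is None:
            raise ValueError(f"feature {feat.id}: unknown gene_category")
        genes.append(
            GeneModel(
                gene_id=feat.id,
                name=attrs.get("Name", [feat.id])[0],
                category=category,
                strand=strand,
                exons=exons,
                fragment_of=attrs.get("fragment_of", [None])[0],
                host_gene=attrs.get("host_gene", [None])[0],
            )
        )
    return genes


def _transcription_order(exons_sorted: list[Interval], strand: str,
                         genome_len: int) -> list[Interval]:
    """Order a coordinate-sorted exon chain in transcription order.

    The chain occupies a circular arc; exons are ordered by their offset from
    the arc start (so an origin-spanning gene's wrapped [0,x) pieces come
    last on the plus strand), then reversed for minus-strand genes.
    """
    from ._coords import smallest_covering_arc

    s0, _ = smallest_covering_arc(exons_sorted, genome_len)
    ex = sorted(exons_sorted, key=lambda iv: (iv[0] - s0) % genome_len)
    if strand == "-":
        ex = list(reversed(ex))
    return ex


def _read_genbank_genes(path: str, genome_len: int) -> list[GeneModel]:
    record = SeqIO.read(path, "genbank")
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in record.features:
        if feat.type not in ("CDS", "tRNA", "rRNA"):
            continue
        quals = feat.qualifiers
        name = quals.get("gene", quals.get("locus_tag", ["?"]))[0]
        gene_id = name
        i = 2
        while gene_id in seen:
            gene_id = f"{name}_{i}"
            i += 1
        seen.add(gene_id)
        strand = "+" if feat.location.strand != -1 else "-"
        exons = sorted((int(p.start), int(p.end)) for p in feat.location.parts)
        category = {"CDS": "protein_coding", "tRNA": "tRNA", "rRNA": "rRNA"}[feat.type]
        if category == "protein_coding" and name.lower().startswith("orf"):
            category = "ORF"
        genes.append(
            GeneModel(
                gene_id=gene_id, name=name, category=category, strand=strand,
                exons=_transcription_order(exons, strand, genome_len),
            )
        )
    return genes


# ---------------------------------------------------------------------------
# Writing


def write_gff3(annotation: GenomeAnnotation, path: str) -> None:
    """Write the annotation as GFF3 (1-based inclusive coordinates).

    Round-trips through :func:`read_annotation` up to field ordering.  An
    origin-spanning gene is emitted as multiple exon lines sharing a Parent.
    """
    lines = ["##gff-version 3",
             f"##sequence-region {annotation.genome.id} 1 {annotation.genome.length}"]
    for g in annotation.genes:
        ex = g.exons_genomic
        attrs = [f"ID={g.gene_id}", f"Name={g.name}", f"gene_category={g.category}"]
        if g.fragment_of:
            attrs.append(f"fragment_of={g.fragment_of}")
        if g.host_gene:
            attrs.append(f"host_gene={g.host_gene}")
        lines.append("\t".join([
            annotation.genome.id, "ptuscope", "gene",
            str(ex[0][0] + 1), str(ex[-1][1]), ".", g.strand, ".",
            ";".join(attrs),
        ]))
        for i, (s, e) in enumerate(ex, 1):
            lines.append("\t".join([
                annotation.genome.id, "ptuscope", "exon",
                str(s + 1), str(e), ".", g.strand, ".",
                f"ID={g.gene_id}.exon{i};Parent={g.gene_id}",
            ]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_fasta(genome: GenomeSequence, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, genome.length, 70):
            fh.write(genome.seq[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# Sequence extraction


def extract_gene_sequence(annotation: GenomeAnnotation, gene_id: str, spliced: bool = True) -> str:
    """Transcript-oriented sequence of a gene.

    spliced=True: exon sequences concatenated in transcription order
    (reverse-complemented for minus-strand genes).  spliced=False: the full
    genomic span, still transcript-oriented.
    """
    g = annotation.gene(gene_id)
    genome = annotation.genome
    if spliced:
        parts = []
        for s, e in g.exons:
            piece = genome.fetch(s, e)
            parts.append(str(Seq(piece).reverse_complement()) if g.strand == "-" else piece)
        return "".join(parts)
    s, e = g.span()
    piece = genome.fetch(s, e)
    return str(Seq(piece).reverse_complement()) if g.strand == "-" else piece


# ---------------------------------------------------------------------------
# ORF scanning


def orf_scan(
    genome: GenomeSequence,
    min_len: int = 300,
    region: Interval | None = None,
    all_starts: bool = False,
) -> list[GeneModel]:
    """Scan both strands for ATG-initiated ORFs of length >= min_len.

    The stop codon is counted in the length.  On a circular genome the scan
    continues across the origin (ORF length capped at the genome length).  By
    default only the longest ORF per stop codon is reported (outermost ATG);
    ``all_starts=True`` also reports nested in-frame starts.
    """
    if min_len < 30:
        raise ValueError("min_len must be >= 30")
    L = genome.length
    if region is not None:
        rs, re_ = region
        if not (0 <= rs < re_ <= L):
            raise ValueError(f"region {region} outside genome of length {L}")
    hits: list[GeneModel] = []
    for strand in "+-":
        fwd = genome.seq if strand == "+" else str(Seq(genome.seq).reverse_complement())
        scan_seq = fwd + fwd if genome.circular else fwd
        for s, e in _orf_intervals(scan_seq, min_len, L if genome.circular else None,
                                   all_starts):
            # map back to genome coordinates on the forward strand
            if strand == "+":
                gs = s
            else:
                gs = L - e  # may be negative for wrapped hits; split handles it
            exons = split_interval(gs, gs + (e - s), L)
            if strand == "-":
                exons = list(reversed(exons))
            if region is not None and not _within(exons, region):
                continue
            gid = f"orf_{strand}_{gs % L}_{(e - s)}"
            hits.append(GeneModel(gene_id=gid, name=gid, category="ORF",
                                  strand=strand, exons=exons))
    hits.sort(key=lambda g: (g.exons_genomic[0][0], g.strand, -g.spliced_length))
    return hits


def _orf_intervals(seq: str, min_len: int, wrap_len: int | None, all_starts: bool):
    """Yield (start, end) ORF intervals on `seq` (end exclusive, includes stop).

    When wrap_len is set, `seq` is a doubled circular sequence: only starts in
    [0, wrap_len) are reported and ORF length is capped at wrap_len.
    """
    n = len(seq)
    limit = wrap_len if wrap_len is not None else n
    out = []
    for frame in range(3):
        starts: list[int] = []
        i = frame
        while i + 3 <= n:
            codon = seq[i:i + 3]
            if codon == "ATG" and i < limit:
                starts.append(i)
            elif codon in STOP_CODONS:
                for s in starts:
                    length = i + 3 - s
                    if length >= min_len and (wrap_len is None or length <= wrap_len):
                        out.append((s, i + 3))
                        if not all_starts:
                            break
                starts = []
            i += 3
    if all_starts:
        # dedupe identical ORFs reported from two copies of the doubled seq
        seen = set()
        uniq = []
        for s, e in out:
            key = (s % limit, (e - s))
            if key not in seen:
                seen.add(key)
                uniq.append((s, e))
        return uniq
    # one ORF per genomic stop codon: keep the longest (outermost ATG),
    # which on a circular genome may be the origin-wrapping candidate
    by_stop: dict[int, tuple[int, int]] = {}
    for s, e in out:
        key = (e - 3) % limit
        if key not in by_stop or (e - s) > (by_stop[key][1] - by_stop[key][0]):
            by_stop[key] = (s, e)
    return list(by_stop.values())


def _within(exons: list[Interval], region: Interval) -> bool:
    rs, re_ = region
    return all(rs <= s and e <= re_ for s, e in sorted(exons))


def rotate_annotation(annotation: GenomeAnnotation, k: int) -> GenomeAnnotation:
    """Rotate a circular genome by k bp (new origin at old coordinate k).

    Useful for checking that extraction is invariant to the arbitrary choice
    of origin on a circular molecule.
    """
    L = annotation.genome.length
    k %= L
    genome = GenomeSequence(
        id=annotation.genome.id,
        seq=annotation.genome.seq[k:] + annotation.genome.seq[:k],
        circular=annotation.genome.circular,
    )
    genes = []
    for g in annotation.genes:
        new_exons = []
        for s, e in g.exons:
            ns = (s - k) % L
            pieces = split_interval(ns, ns + (e - s), L)
            if g.strand == "-":
                # a split exon's wrapped piece comes first in transcription order
                pieces = list(reversed(pieces))
            new_exons.extend(pieces)
        genes.append(replace(g, exons=new_exons))
    return GenomeAnnotation(genome=genome, genes=genes,
                            fragment_pairs=list(annotation.fragment_pairs))
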