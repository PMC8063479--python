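"""Cistronic-type assignment and polycistronic transcriptional unit (PTU)
inference from full-length spliced read alignments.

A gene is part of a read's *cistronic type* only when every one of its exons
is completely covered by the read's aligned blocks and the gene lies on the
read's transcriptional strand.  Distinct (strand, ordered gene tuple) keys
are the cistronic types; types sharing at least one gene are concatenated
into PTUs (maximal connected components under the share-a-gene relation,
computed with a deterministic union-find).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from ._coords import smallest_covering_arc
from .alignments import ReadAlignment
from .annotation import GeneModel, GenomeAnnotation

DEFAULT_COVERAGE_SLACK = 0


@dataclass
class CistronicType:
    strand: str
    gene_ids: tuple[str, ...]
    support: int
    read_ids: list[str] = field(default_factory=list)


@dataclass
class PTUnit:
    ptu_id: str
    strand: str
    gene_ids: list[str]
    member_types: list[CistronicType]
    span: tuple[int, int]                    # circular arc; end may exceed L
    singleton_reason: str | None = None      # intronic_orfs | cleaved_cistrons | none

    @property
    def support(self) -> int:
        return sum(t.support for t in self.member_types)


@dataclass
class PTUMap:
    ptus: list[PTUnit]
    n_qualifying_reads: int
    n_types: int


# ---------------------------------------------------------------------------
# Typing


def genes_fully_covered(
    read: ReadAlignment,
    annotation: GenomeAnnotation,
    coverage_slack: int = DEFAULT_COVERAGE_SLACK,
    require_strand: bool = True,
    exclude_categories: tuple[str, ...] = ("intronic_ORF",),
) -> list[GeneModel]:
    """Genes whose every exon is contained in the read's aligned blocks.

    ``coverage_slack`` bases may be uncovered at each exon terminus (0 by
    default: the strict criterion).  Intronic ORFs are nested inside their
    host gene's reads and are never counted as independent cistron members.
    """
    L = annotation.genome.length
    cov = read.coverage_mask(L)
    intact = []
    for g in annotation.genes:
        if g.category in exclude_categories:
            continue
        if require_strand and g.strand != read.strand:
            continue
        ok = True
        for s, e in g.exons_genomic:
            lo, hi = s + coverage_slack, e - coverage_slack
            if lo >= hi:                       # exon shorter than 2*slack
                lo, hi = (s + e) // 2, (s + e) // 2 + 1
            if not cov[lo:hi].all():
                ok = False
                break
        if ok:
            intact.append(g)
    return intact


def _transcription_sort(genes: list[GeneModel], read: ReadAlignment, L: int) -> list[GeneModel]:
    """Order genes along the read's transcription direction, robust to reads
    that wrap the circular origin."""
    if read.strand == "+":
        anchor = read.blocks[0].start
        return sorted(genes, key=lambda g: (g.exons_genomic[0][0] - anchor) % L)
    anchor = max(b.end for b in read.blocks)
    return sorted(genes, key=lambda g: (anchor - g.exons_genomic[-1][1]) % L)


def assign_cistronic_type(
    read: ReadAlignment,
    annotation: GenomeAnnotation,
    coverage_slack: int = DEFAULT_COVERAGE_SLACK,
) -> tuple[str, tuple[str, ...]] | None:
    """The read's (strand, ordered gene tuple) key, or None when the read
    covers no gene completely (such reads drop out of the PTU analysis)."""
    intact = genes_fully_covered(read, annotation, coverage_slack)
    if not intact:
        return None
    ordered = _transcription_sort(intact, read, annotation.genome.length)
    return read.strand, tuple(g.gene_id for g in ordered)


def enumerate_cistronic_types(
    alignments: list[ReadAlignment],
    annotation: GenomeAnnotation,
    coverage_slack: int = DEFAULT_COVERAGE_SLACK,
) -> list[CistronicType]:
    """Group qualifying reads by their (strand, gene tuple) key.

    The sum of type supports equals the number of reads covering at least one
    intact same-strand gene.
    """
    groups: dict[tuple[str, tuple[str, ...]], list[str]] = defaultdict(list)
    for read in alignments:
        key = assign_cistronic_type(read, annotation, coverage_slack)
        if key is not None:
            groups[key].append(read.read_id)
    types = [
        CistronicType(strand=strand, gene_ids=genes, support=len(rids), read_ids=rids)
        for (strand, genes), rids in groups.items()
    ]
    types.sort(key=lambda t: (_type_start(t, annotation), t.strand, t.gene_ids))
    return types


def _type_start(t: CistronicType, annotation: GenomeAnnotation) -> int:
    return min(annotation.gene(g).exons_genomic[0][0] for g in t.gene_ids)


# ---------------------------------------------------------------------------
# Merging


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller key becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def merge_into_ptus(
    types: list[CistronicType],
    annotation: GenomeAnnotation,
    merge_adjacent: bool = False,
) -> PTUMap:
    """Concatenate overlapping cistronic types into PTUs.

    Two same-strand types connect when they share >= 1 gene.  With
    ``merge_adjacent=True`` types whose gene sets are consecutive in
    same-strand genome order (no annotated same-strand gene between them)
    also connect; this is off by default — a read's UTR brushing a neighbour
    without covering it is not co-transcription evidence.
    """
    L = annotation.genome.length
    ptus: list[PTUnit] = []
    for strand in "+-":
        st = [t for t in types if t.strand == strand]
        if not st:
            continue
        uf = _UnionFind(range(len(st)))
        gene_to_types: dict[str, list[int]] = defaultdict(list)
        for i, t in enumerate(st):
            for g in t.gene_ids:
                gene_to_types[g].append(i)
        for idxs in gene_to_types.values():
            for j in idxs[1:]:
                uf.union(idxs[0], j)
        if merge_adjacent:
            _merge_adjacent_sets(st, uf, annotation, strand)
        comps: dict[int, list[int]] = defaultdict(list)
        for i in range(len(st)):
            comps[uf.find(i)].append(i)
        for root in sorted(comps):
            members = [st[i] for i in comps[root]]
            gene_ids = sorted({g for t in members for g in t.gene_ids})
            gene_models = [annotation.gene(g) for g in gene_ids]
            intervals = [iv for g in gene_models for iv in g.exons_genomic]
            span = smallest_covering_arc(intervals, L)
            ordered = _strand_order(gene_models, strand, span, L)
            ptus.append(PTUnit(
                ptu_id="",  # assigned after global sort
                strand=strand,
                gene_ids=[g.gene_id for g in ordered],
                member_types=sorted(members, key=lambda t: (t.gene_ids,)),
                span=span,
            ))
    ptus.sort(key=lambda p: (p.span[0] % L, p.strand))
    for i, p in enumerate(ptus, 1):
        p.ptu_id = f"PTU{i:03d}"
    n_reads = sum(t.support for t in types)
    return PTUMap(ptus=ptus, n_qualifying_reads=n_reads, n_types=len(types))


def _strand_order(genes: list[GeneModel], strand: str,
                  span: tuple[int, int], L: int) -> list[GeneModel]:
    """Physical genome order along the strand's transcription direction,
    unwrapped relative to the PTU's arc start."""
    s0 = span[0]
    ordered = sorted(genes, key=lambda g: (g.exons_genomic[0][0] - s0) % L)
    return ordered if strand == "+" else list(reversed(ordered))


def _merge_adjacent_sets(st, uf, annotation: GenomeAnnotation, strand: str) -> None:
    strand_genes = sorted(annotation.genes_on_strand(strand),
                          key=lambda g: g.exons_genomic[0][0])
    rank = {g.gene_id: i for i, g in enumerate(strand_genes)
            if g.category != "intronic_ORF"}
    # re-rank after dropping intronic ORFs so "no gene between" is well defined
    ordered_ids = sorted(rank, key=rank.get)
    rank = {gid: i for i, gid in enumerate(ordered_ids)}
    for i, a in enumerate(st):
        for j in range(i + 1, len(st)):
            b = st[j]
            ra = [rank[g] for g in a.gene_ids if g in rank]
            rb = [rank[g] for g in b.gene_ids if g in rank]
            if not ra or not rb:
                continue
            if max(ra) + 1 == min(rb) or max(rb) + 1 == min(ra):
                uf.union(i, j)


# ---------------------------------------------------------------------------
# Singleton classification


def classify_singletons(
    ptumap: PTUMap,
    annotation: GenomeAnnotation,
    alignments: list[ReadAlignment] | None = None,
) -> PTUMap:
    """Annotate single-gene PTUs with a reason for standing alone.

    ``intronic_orfs``: the gene hosts at least one intronic ORF (the long
    rRNA/psbA-style operons whose content is mostly intron-encoded).
    ``cleaved_cistrons``: read spans cluster into >= 2 distinct groups
    strictly nested inside the gene span (the cistron appears processed into
    smaller RNAs); requires ``alignments``.  Otherwise ``none`` (retained but
    flagged).
    """
    L = annotation.genome.length
    for p in ptumap.ptus:
        if len(p.gene_ids) != 1:
            p.singleton_reason = None
            continue
        gid = p.gene_ids[0]
        if annotation.intronic_orfs_of(gid):
            p.singleton_reason = "intronic_orfs"
        elif alignments is not None and _has_cleavage_evidence(
            gid, annotation, alignments, L
        ):
            p.singleton_reason = "cleaved_cistrons"
        else:
            p.singleton_reason = "none"
    return ptumap


def _has_cleavage_evidence(gene_id: str, annotation: GenomeAnnotation,
                           alignments: list[ReadAlignment], L: int) -> bool:
    g = annotation.gene(gene_id)
    gs, ge = g.span()
    nested_spans = set()
    for r in alignments:
        if r.strand != g.strand:
            continue
        rs = min(b.start for b in r.blocks)
        re_ = max(b.end for b in r.blocks)
        if gs < rs and re_ < ge:               # strictly inside the gene span
            nested_spans.add((rs, re_))
    if len(nested_spans) < 2:
        return False
    spans = sorted(nested_spans)
    # at least two clearly distinct span groups (not terminus jitter)
    return any(abs(a[0] - b[0]) > 20 or abs(a[1] - b[1]) > 20
               for a in spans for b in spans)


# ---------------------------------------------------------------------------
# Reporting


def ptu_report(ptumap: PTUMap, annotation: GenomeAnnotation,
               tsv_path: str, gff3_path: str | None = None) -> None:
    """One row per PTU with gene-category content counts, plus an optional
    GFF3 track of PTU spans."""
    L = annotation.genome.length
    with open(tsv_path, "w") as fh:
        fh.write("ptu_id\tstrand\tstart\tend\tgenes\tn_protein_coding\tn_orf\t"
                 "n_trna\tn_rrna\tn_intronic_orf\tsupport\tsingleton_reason\n")
        for p in ptumap.ptus:
            cats = _content_counts(p, annotation)
            genes = ",".join(p.gene_ids)
            fh.write(
                f"{p.ptu_id}\t{p.strand}\t{p.span[0] % L}\t{p.span[1]}\t{genes}\t"
                f"{cats['protein_coding']}\t{cats['ORF']}\t{cats['tRNA']}\t"
                f"{cats['rRNA']}\t{cats['intronic_ORF']}\t{p.support}\t"
                f"{p.singleton_reason or '.'}\n"
            )
    if gff3_path:
        with open(gff3_path, "w") as fh:
            fh.write("##gff-version 3\n")
            for p in ptumap.ptus:
                fh.write("\t".join([
                    annotation.genome.id, "ptuscope", "transcriptional_unit",
                    str(p.span[0] % L + 1), str(min(p.span[1], L)), ".",
                    p.strand, ".",
                    f"ID={p.ptu_id};genes={','.join(p.gene_ids)}",
                ]) + "\n")


def _content_counts(p: PTUnit, annotation: GenomeAnnotation) -> dict[str, int]:
    counts = {c: 0 for c in ("protein_coding", "ORF", "tRNA", "rRNA", "intronic_ORF")}
    for gid in p.gene_ids:
        counts[annotation.gene(gid).category] += 1
    # intronic ORFs are PTU *content*, not members: count those hosted by members
    for gid in p.gene_ids:
        counts["intronic_ORF"] += len(annotation.intronic_orfs_of(gid))
    return counts


def write_types_tsv(types: list[CistronicType], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("strand\tgenes\tsupport\n")
        for t in types:
            fh.write(f"{t.strand}\t{','.join(t.gene_ids)}\t{t.support}\n")
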