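"""Shared builders and independent brute-force oracles for the test suite.

The oracles here deliberately re-derive results from first principles
(per-base set arithmetic, exhaustive codon walks, naive transitive closure)
so they stay independent of the package's implementations.
"""

import numpy as np

from ptuscope.alignments import AlignedBlock, ReadAlignment
from ptuscope.annotation import GeneModel, GenomeAnnotation, GenomeSequence

STOPS = {"TAA", "TAG", "TGA"}
COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(COMP)[::-1]


def random_seq(length: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def make_genome(length: int = 1000, seed: int = 0, circular: bool = True,
                seq: str | None = None) -> GenomeSequence:
    return GenomeSequence(id="toy", seq=seq or random_seq(length, seed),
                          circular=circular)


def gene(gid: str, start: int, end: int, strand: str = "+",
         category: str = "protein_coding", exons=None, **kw) -> GeneModel:
    if exons is None:
        exons = [(start, end)]
        # single-exon models have a trivial transcription order; multi-exon
        # callers pass the chain already in transcription order
    return GeneModel(gene_id=gid, name=gid, category=category, strand=strand,
                     exons=exons, **kw)


def annotation(genes, length: int = 1000, seed: int = 0, seq: str | None = None,
               circular: bool = True) -> GenomeAnnotation:
    return GenomeAnnotation(genome=make_genome(length, seed, circular, seq),
                            genes=list(genes))


def read(rid: str, blocks, strand: str = "+", mism=None) -> ReadAlignment:
    return ReadAlignment(read_id=rid, strand=strand,
                         blocks=[AlignedBlock(s, e) for s, e in blocks],
                         mismatches=mism)


# ---------------------------------------------------------------------------
# Oracles


def covered_positions(blocks, L):
    pos = set()
    for s, e in blocks:
        for p in range(s, e):
            pos.add(p % L)
    return pos


def brute_coverage_fraction(reads, L):
    pos = set()
    for r in reads:
        pos |= covered_positions([(b.start, b.end) for b in r.blocks], L)
    return len(pos) / L


def brute_intact_genes(r, ann, slack=0):
    """Per-base containment check: every exon base covered (up to `slack`
    uncovered bases at each exon terminus), same strand."""
    L = ann.genome.length
    cov = covered_positions([(b.start, b.end) for b in r.blocks], L)
    out = []
    for g in ann.genes:
        if g.category == "intronic_ORF" or g.strand != r.strand:
            continue
        ok = True
        for s, e in sorted(g.exons):
            core = range(s + slack, e - slack) if s + slack < e - slack \
                else range((s + e) // 2, (s + e) // 2 + 1)
            if any(p % L not in cov for p in core):
                ok = False
                break
        if ok:
            out.append(g.gene_id)
    return out


def brute_cistronic_types(reads, ann, slack=0):
    """(strand, ordered gene tuple) -> support, ordering genes by position
    along the transcription direction."""
    types = {}
    for r in reads:
        intact = brute_intact_genes(r, ann, slack)
        if not intact:
            continue
        genes = sorted(intact, key=lambda gid: min(s for s, _ in ann.gene(gid).exons))
        if r.strand == "-":
            genes = genes[::-1]
        key = (r.strand, tuple(genes))
        types[key] = types.get(key, 0) + 1
    return types


def brute_transitive_closure(type_keys):
    """Merge same-strand gene sets sharing >= 1 gene until fixpoint; returns
    the set of (strand, frozenset) components."""
    groups = [(strand, set(genes)) for strand, genes in type_keys]
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                si, gi = groups[i]
                sj, gj = groups[j]
                if si == sj and gi & gj:
                    groups[i] = (si, gi | gj)
                    del groups[j]
                    changed = True
                    break
            if changed:
                break
    return {(s, frozenset(g)) for s, g in groups}


def random_typing_instance(seed: int, L: int = 2000, max_genes: int = 20,
                           max_reads: int = 200):
    """A random annotation + read set for oracle-equivalence checks."""
    rng = np.random.default_rng(seed)
    genes, strand_cursor = [], {"+": 50, "-": 50}
    n_genes = int(rng.integers(3, max_genes + 1))
    for i in range(n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        start = strand_cursor[strand] + int(rng.integers(0, 60))
        length = int(rng.integers(40, 160))
        if start + length > L - 10:
            break
        genes.append(gene(f"g{i}", start, start + length, strand))
        strand_cursor[strand] = start + length + 1
    ann = annotation(genes, length=L, seed=seed)
    reads = []
    n_reads = int(rng.integers(10, max_reads + 1))
    for i in range(n_reads):
        strand = "+" if rng.random() < 0.5 else "-"
        s = int(rng.integers(0, L - 100))
        e = min(s + int(rng.integers(50, 600)), L)
        if rng.random() < 0.3 and e - s > 200:
            mid = s + (e - s) // 2
            gap = int(rng.integers(45, 80))
            blocks = [(a, b) for a, b in
                      [(s, mid), (min(mid + gap, e - 1), e)] if a < b]
        else:
            blocks = [(s, e)]
        reads.append(read(f"r{i}", blocks, strand=strand))
    return ann, reads


def brute_orfs(seq: str, min_len: int, circular: bool = True):
    """Exhaustive six-frame ATG->stop enumeration; per (strand, stop) only the
    longest ORF with length <= genome length.  Returns a set of
    (strand, forward_start, length)."""
    L = len(seq)
    found = {}
    for strand, s2 in (("+", seq), ("-", revcomp(seq))):
        src = s2 + s2 if circular else s2
        for start in range(L if circular else len(s2) - 2):
            if src[start:start + 3] != "ATG":
                continue
            i = start + 3
            while i + 3 <= len(src) and (i + 3 - start) <= L:
                if src[i:i + 3] in STOPS:
                    length = i + 3 - start
                    if length >= min_len:
                        stop_key = (strand, i % L if circular else i)
                        if stop_key not in found or found[stop_key][2] < length:
                            if strand == "+":
                                fstart = start % L
                            else:
                                fstart = (L - (start + length)) % L
                            found[stop_key] = (strand, fstart, length)
                    break
                i += 3
    return set(found.values())
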