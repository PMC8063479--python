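"""Spliced long-read alignments as block chains.

Consumes SAM (via pysam; spliced gaps must be encoded as N/skip operations)
or the package's plain block-table TSV, and derives the quantities the
downstream analyses need: genome coverage, splice junctions, and per-position
mismatch pileups.  Reads are assumed to be orientation-preserving full-length
cDNA (FLNC), so transcriptional strand is taken from alignment orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pysam

from ._coords import add_depth, gap_between, mark
from .annotation import GenomeAnnotation, GenomeSequence

log = logging.getLogger(__name__)

DEFAULT_MIN_IDENTITY = 0.8
DEFAULT_MIN_ALIGNED_LEN = 200
DEFAULT_MIN_INTRON_LEN = 40
DEFAULT_MIN_JUNCTION_SUPPORT = 2


@dataclass(frozen=True)
class AlignedBlock:
    start: int
    end: int

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"bad block [{self.start},{self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ReadAlignment:
    """One read's ordered aligned block chain on the genome.

    Blocks are in read order (5'→3' along the genome for the alignment;
    a circular read wrapping the origin has a later block restarting near 0).
    Mismatches are (genome_pos, genome_base, read_base) triples when known.
    """

    read_id: str
    strand: str
    blocks: list[AlignedBlock]
    mismatches: list[tuple[int, str, str]] | None = None
    full_length: bool = True

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.read_id}: bad strand {self.strand!r}")
        if not self.blocks:
            raise ValueError(f"{self.read_id}: no blocks")

    @property
    def aligned_length(self) -> int:
        return sum(len(b) for b in self.blocks)

    def coverage_mask(self, genome_len: int) -> np.ndarray:
        cov = np.zeros(genome_len, dtype=bool)
        for b in self.blocks:
            mark(cov, b.start, b.end)
        return cov

    def gaps(self, genome_len: int) -> list[tuple[int, int, int]]:
        """(donor, acceptor, gap_length) for each inter-block gap, circular-aware."""
        out = []
        for a, b in zip(self.blocks, self.blocks[1:]):
            g = gap_between(a.end, b.start, genome_len)
            out.append((a.end, b.start, g))
        return out

    def identity(self) -> float:
        if self.mismatches is None:
            return 1.0
        return 1.0 - len(self.mismatches) / max(self.aligned_length, 1)


@dataclass(frozen=True)
class JunctionObservation:
    donor: int      # end of the upstream aligned block (exclusive coordinate)
    acceptor: int   # start of the downstream block
    strand: str
    support: int


@dataclass
class CoverageProfile:
    depth: np.ndarray
    covered_fraction: float


@dataclass
class MismatchRecord:
    pos: int
    genome_base: str
    read_base_counts: dict[str, int]
    depth: int


# ---------------------------------------------------------------------------
# Loading


def load_alignments(
    path: str,
    annotation: GenomeAnnotation,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_aligned_len: int = DEFAULT_MIN_ALIGNED_LEN,
) -> list[ReadAlignment]:
    """Load spliced alignments from SAM or block-table TSV, with read filters.

    Secondary/supplementary SAM records are dropped; reads failing the
    identity or aligned-length filters are dropped (counts are logged).
    """
    if path.endswith((".sam", ".bam")):
        reads = _load_sam(path, annotation)
    else:
        reads = _load_block_table(path)
    kept, n_id, n_len = [], 0, 0
    for r in reads:
        if r.aligned_length < min_aligned_len:
            n_len += 1
        elif r.identity() < min_identity:
            n_id += 1
        else:
            kept.append(r)
    log.info("loaded %d alignments (%d failed identity<%.2f, %d failed length<%d)",
             len(kept), n_id, min_identity, n_len, min_aligned_len)
    return kept


def _load_sam(path: str, annotation: GenomeAnnotation) -> list[ReadAlignment]:
    out = []
    n_skipped = 0
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.reference_name != annotation.genome.id:
                raise ValueError(
                    f"alignment reference {rec.reference_name!r} does not match "
                    f"genome {annotation.genome.id!r}"
                )
            try:
                blocks = _blocks_from_cigar(rec)
                mism = _mismatches_from_record(rec)
            except Exception:  # noqa: BLE001 - malformed record, skip with count
                n_skipped += 1
                continue
            out.append(ReadAlignment(
                read_id=rec.query_name,
                strand="-" if rec.is_reverse else "+",
                blocks=blocks,
                mismatches=mism,
            ))
    if n_skipped:
        log.warning("skipped %d unparsable SAM records", n_skipped)
    return out


def _blocks_from_cigar(rec: pysam.AlignedSegment) -> list[AlignedBlock]:
    blocks = []
    pos = rec.reference_start
    cur_start = pos
    open_block = False
    for op, length in rec.cigartuples:
        if op in (0, 7, 8):         # M / = / X : consume both
            if not open_block:
                cur_start = pos
                open_block = True
            pos += length
        elif op == 2:               # D : consume ref, stays in block
            if not open_block:
                cur_start = pos
                open_block = True
            pos += length
        elif op == 3:               # N : skip opens a new block
            if open_block:
                blocks.append(AlignedBlock(cur_start, pos))
                open_block = False
            pos += length
        elif op in (1, 4, 5, 6):    # I / S / H / P : no ref consumption
            continue
        else:
            raise ValueError(f"unsupported CIGAR op {op}")
    if open_block:
        blocks.append(AlignedBlock(cur_start, pos))
    return blocks


def _mismatches_from_record(rec) -> list[tuple[int, str, str]] | None:
    if not rec.has_tag("MD"):
        return None
    mism = []
    for qpos, rpos, ref_base in rec.get_aligned_pairs(matches_only=True, with_seq=True):
        if ref_base.islower():
            mism.append((rpos, ref_base.upper(), rec.query_sequence[qpos].upper()))
    return mism


def _load_block_table(path: str) -> list[ReadAlignment]:
    """Read the block-table TSV dialect.

    Columns: read_id, strand, block_index, start, end, mismatches
    (``pos:ref>alt;...`` or ``.``).  One row per block, blocks of a read on
    consecutive rows in read order.
    """
    by_read: dict[str, ReadAlignment] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("read_id\t"):
                continue
            read_id, strand, _idx, start, end, mm = line.split("\t")
            block = AlignedBlock(int(start), int(end))
            mism = []
            if mm and mm != ".":
                for item in mm.split(";"):
                    p, rest = item.split(":")
                    ref, alt = rest.split(">")
                    mism.append((int(p), ref, alt))
            if read_id not in by_read:
                by_read[read_id] = ReadAlignment(read_id=read_id, strand=strand,
                                                 blocks=[block], mismatches=mism)
                order.append(read_id)
            else:
                r = by_read[read_id]
                r.blocks.append(block)
                r.mismatches.extend(mism)
    return [by_read[k] for k in order]


def write_block_table(reads: list[ReadAlignment], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tstrand\tblock_index\tstart\tend\tmismatches\n")
        for r in reads:
            mm_by_block = _assign_mismatches_to_blocks(r)
            for i, b in enumerate(r.blocks):
                mm = mm_by_block[i]
                mm_str = ";".join(f"{p}:{ref}>{alt}" for p, ref, alt in mm) or "."
                fh.write(f"{r.read_id}\t{r.strand}\t{i}\t{b.start}\t{b.end}\t{mm_str}\n")


def _assign_mismatches_to_blocks(r: ReadAlignment) -> list[list[tuple[int, str, str]]]:
    out: list[list[tuple[int, str, str]]] = [[] for _ in r.blocks]
    for mm in (r.mismatches or []):
        for i, b in enumerate(r.blocks):
            if b.start <= mm[0] < b.end:
                out[i].append(mm)
                break
    return out


# ---------------------------------------------------------------------------
# Derived features


def genome_coverage_fraction(
    alignments: list[ReadAlignment], genome_len: int, circular: bool = True
) -> CoverageProfile:
    """Per-base depth over the union of aligned blocks and the fraction of
    genome positions covered at least once."""
    depth = np.zeros(genome_len, dtype=np.int64)
    for r in alignments:
        for b in r.blocks:
            add_depth(depth, b.start, b.end)
    covered = float(np.count_nonzero(depth)) / genome_len
    return CoverageProfile(depth=depth, covered_fraction=covered)


def extract_junctions(
    alignments: list[ReadAlignment],
    genome_len: int,
    min_intron_len: int = DEFAULT_MIN_INTRON_LEN,
    min_support: int = DEFAULT_MIN_JUNCTION_SUPPORT,
) -> list[JunctionObservation]:
    """Collapse inter-block gaps >= min_intron_len into supported junctions.

    Identical (donor, acceptor, strand) observations are merged with summed
    support; junctions below min_support are discarded.  Gaps shorter than
    min_intron_len are treated as alignment artifacts (deletions), not introns.
    """
    counts: dict[tuple[int, int, str], int] = {}
    for r in alignments:
        for donor, acceptor, gap in r.gaps(genome_len):
            if gap >= min_intron_len:
                key = (donor, acceptor, r.strand)
                counts[key] = counts.get(key, 0) + 1
    out = [JunctionObservation(d, a, s, n)
           for (d, a, s), n in counts.items() if n >= min_support]
    out.sort(key=lambda j: (j.donor, j.acceptor, j.strand))
    return out


def pileup_mismatches(
    alignments: list[ReadAlignment],
    genome: GenomeSequence,
    min_depth: int = 1,
) -> list[MismatchRecord]:
    """Per-position mismatch pileup from the reads' mismatch lists.

    Returns one record per genome position carrying >= 1 mismatch with total
    read depth >= min_depth.  Raises if alignments carry no mismatch
    information at all (supply MD-tagged SAM or a block table with mismatch
    columns).
    """
    if all(r.mismatches is None for r in alignments) and alignments:
        raise ValueError(
            "alignments carry no mismatch information; load MD-tagged SAM or "
            "a block table with mismatch columns"
        )
    depth = np.zeros(genome.length, dtype=np.int64)
    for r in alignments:
        for b in r.blocks:
            add_depth(depth, b.start, b.end)
    counts: dict[int, dict[str, int]] = {}
    for r in alignments:
        for pos, _ref, alt in (r.mismatches or []):
            counts.setdefault(pos, {}).setdefault(alt, 0)
            counts[pos][alt] += 1
    out = []
    for pos in sorted(counts):
        if depth[pos] >= min_depth:
            out.append(MismatchRecord(
                pos=pos,
                genome_base=genome.seq[pos],
                read_base_counts=dict(sorted(counts[pos].items())),
                depth=int(depth[pos]),
            ))
    return out


def write_junction_bed(junctions: list[JunctionObservation], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("donor\tacceptor\tstrand\tsupport\n")
        for j in junctions:
            fh.write(f"{j.donor}\t{j.acceptor}\t{j.strand}\t{j.support}\n")


def write_coverage_bedgraph(profile: CoverageProfile, genome_id: str, path: str) -> None:
    depth = profile.depth
    with open(path, "w") as fh:
        i = 0
        n = depth.shape[0]
        while i < n:
            j = i
            while j < n and depth[j] == depth[i]:
                j += 1
            fh.write(f"{genome_id}\t{i}\t{j}\t{int(depth[i])}\n")
            i = j
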