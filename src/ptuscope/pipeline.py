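"""End-to-end orchestration: load → coverage → typing → PTUs → introns →
fragments → editing → reports, driven by one declarative config.

All genomic TSV outputs are 0-based half-open; GFF3 outputs are 1-based
inclusive.  Output files are written atomically (tmp file + rename) and every
effective parameter is recorded in the summary header.
"""

from __future__ import annotations

import dataclasses
import logging
import os
import tempfile
from dataclasses import dataclass, field

import yaml

from . import alignments as aln
from . import fragments as frag
from . import introns as intr
from . import ptu as ptumod
from .annotation import read_annotation

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    annotation: str
    fasta: str
    alignments: str
    out_dir: str
    msa: str | None = None
    circular: bool = True
    seed: int = 0
    min_identity: float = aln.DEFAULT_MIN_IDENTITY
    min_aligned_len: int = aln.DEFAULT_MIN_ALIGNED_LEN
    min_intron_len: int = aln.DEFAULT_MIN_INTRON_LEN
    min_junction_support: int = aln.DEFAULT_MIN_JUNCTION_SUPPORT
    coverage_slack: int = ptumod.DEFAULT_COVERAGE_SLACK
    merge_adjacent: bool = False
    retention_flank: int = intr.DEFAULT_RETENTION_FLANK
    fragment_min_reads: int = frag.DEFAULT_MIN_READS
    fragment_co_ratio: float = frag.DEFAULT_CO_RATIO
    editing_min_freq: float = frag.DEFAULT_EDITING_MIN_FREQ
    editing_min_depth: int = frag.DEFAULT_EDITING_MIN_DEPTH
    editing_transitions_only: bool = False

    @classmethod
    def from_yaml(cls, path: str, **overrides):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        missing = [k for k in ("annotation", "fasta", "alignments", "out_dir")
                   if k not in data]
        if missing:
            raise ValueError(f"missing required config fields: {missing}")
        return cls(**data)

    def validate(self):
        for name in ("annotation", "fasta", "alignments"):
            p = getattr(self, name)
            if not os.path.exists(p):
                raise FileNotFoundError(f"config field {name!r}: no such file {p!r}")
        if self.msa and not os.path.exists(self.msa):
            raise FileNotFoundError(f"config field 'msa': no such file {self.msa!r}")


@dataclass
class PipelineResult:
    annotation: object
    reads: list
    coverage: aln.CoverageProfile
    types: list
    ptumap: ptumod.PTUMap
    intron_calls: list
    intergenic_junctions: list
    comparisons: list
    retention: list
    fragment_calls: list
    editing_sites: list
    outputs: dict[str, str] = field(default_factory=dict)


def _atomic_write(path: str, writer) -> None:
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    except Exception:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every analysis stage and write the standard output files."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    out = lambda name: os.path.join(config.out_dir, name)  # noqa: E731

    annotation = read_annotation(config.annotation, config.fasta, config.circular)
    L = annotation.genome.length
    reads = aln.load_alignments(config.alignments, annotation,
                                min_identity=config.min_identity,
                                min_aligned_len=config.min_aligned_len)
    coverage = aln.genome_coverage_fraction(reads, L, config.circular)

    types = ptumod.enumerate_cistronic_types(reads, annotation, config.coverage_slack)
    ptumap = ptumod.merge_into_ptus(types, annotation, config.merge_adjacent)
    ptumap = ptumod.classify_singletons(ptumap, annotation, reads)

    junctions = aln.extract_junctions(reads, L, config.min_intron_len,
                                      config.min_junction_support)
    calls, intergenic = intr.call_introns(junctions, annotation)
    retention = []
    for c in calls:
        est = intr.retention_fraction(reads, c, L, config.retention_flank)
        c.retention_support = est.n_retained
        retention.append(est)
    comparisons = intr.compare_with_annotation(calls, annotation)

    fragment_calls = [
        frag.classify_fragment_pair(reads, annotation, pair,
                                    config.fragment_min_reads,
                                    config.fragment_co_ratio,
                                    config.coverage_slack)
        for pair in annotation.fragment_pairs
    ]
    try:
        pileup = aln.pileup_mismatches(reads, annotation.genome)
    except ValueError:
        log.warning("no mismatch information in alignments; editing scan skipped")
        pileup = []
    editing_sites = frag.scan_rna_editing(
        pileup,
        editing_min_freq=config.editing_min_freq,
        editing_min_depth=config.editing_min_depth,
        transitions_only=config.editing_transitions_only,
    )

    result = PipelineResult(
        annotation=annotation, reads=reads, coverage=coverage, types=types,
        ptumap=ptumap, intron_calls=calls, intergenic_junctions=intergenic,
        comparisons=comparisons, retention=retention,
        fragment_calls=fragment_calls, editing_sites=editing_sites,
    )

    _atomic_write(out("cistronic_types.tsv"), lambda p: ptumod.write_types_tsv(types, p))
    _atomic_write(out("ptus.tsv"),
                  lambda p: ptumod.ptu_report(ptumap, annotation, p, None))
    _atomic_write(out("ptus.gff3"),
                  lambda p: ptumod.ptu_report(ptumap, annotation, os.devnull, p))
    _atomic_write(out("introns.tsv"), lambda p: intr.write_introns_tsv(calls, p))
    _atomic_write(out("intron_comparison.tsv"),
                  lambda p: intr.write_comparison_tsv(comparisons, p))
    _atomic_write(out("fragment_pairs.tsv"),
                  lambda p: frag.write_fragment_tsv(fragment_calls, p))
    _atomic_write(out("editing_sites.tsv"),
                  lambda p: frag.write_editing_tsv(editing_sites, p))
    _atomic_write(out("junctions.tsv"),
                  lambda p: aln.write_junction_bed(junctions, p))
    _atomic_write(out("coverage.bedgraph"),
                  lambda p: aln.write_coverage_bedgraph(coverage, annotation.genome.id, p))
    _atomic_write(out("summary.txt"),
                  lambda p: _write_summary(p, config, result))
    result.outputs = {
        name: out(name) for name in (
            "cistronic_types.tsv", "ptus.tsv", "ptus.gff3", "introns.tsv",
            "intron_comparison.tsv", "fragment_pairs.tsv", "editing_sites.tsv",
            "junctions.tsv", "coverage.bedgraph", "summary.txt",
        )
    }
    return result


def _write_summary(path: str, config: RunConfig, res: PipelineResult) -> None:
    """Text summary: parameters, per-gene intron counts (observed vs
    annotated), PTU table, fragment verdicts, editing count, coverage."""
    ann = res.annotation
    lines = ["# ptuscope run summary", "## parameters"]
    for f in dataclasses.fields(config):
        lines.append(f"{f.name} = {getattr(config, f.name)}")
    lines.append("## totals")
    lines.append(f"reads_loaded = {len(res.reads)}")
    lines.append(f"genome_coverage_fraction = {res.coverage.covered_fraction:.4f}")
    lines.append(f"qualifying_reads = {res.ptumap.n_qualifying_reads}")
    lines.append(f"cistronic_types = {res.ptumap.n_types}")
    lines.append(f"ptus = {len(res.ptumap.ptus)}")
    lines.append(f"editing_sites = {len(res.editing_sites)}")
    lines.append("## intron counts per gene (observed vs annotated)")
    obs: dict[str, int] = {}
    for c in res.intron_calls:
        obs[c.gene_id] = obs.get(c.gene_id, 0) + 1
    for g in ann.genes:
        n_pred = len(g.introns())
        n_obs = obs.get(g.gene_id, 0)
        if n_pred or n_obs:
            lines.append(f"{g.gene_id}\tobserved={n_obs}\tannotated={n_pred}")
    lines.append("## PTUs")
    for p in res.ptumap.ptus:
        lines.append(f"{p.ptu_id}\t{p.strand}\t{','.join(p.gene_ids)}\t"
                     f"support={p.support}\tsingleton={p.singleton_reason or '.'}")
    lines.append("## fragment pairs")
    for c in res.fragment_calls:
        lines.append(f"{c.pair[0]}~{c.pair[1]}\tboth={c.n_span_both}\t"
                     f"only_a={c.n_only_a}\tonly_b={c.n_only_b}\t{c.verdict}")
    lines.append(f"## editing: {len(res.editing_sites)} editing sites")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def summary_report(result: PipelineResult, config: RunConfig, path: str) -> None:
    _atomic_write(path, lambda p: _write_summary(p, config, result))
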