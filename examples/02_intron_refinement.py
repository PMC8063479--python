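"""Call introns from spliced-read junctions, reconcile them with a
(deliberately corrupted) annotation, quantify intron retention, and score
group II boundary consensus features.

Run:  python examples/02_intron_refinement.py
"""

import dataclasses

from ptuscope.alignments import extract_junctions
from ptuscope.annotation import GenomeAnnotation
from ptuscope.introns import (call_introns, compare_with_annotation,
                              retention_fraction, score_group2_boundaries)
from ptuscope.simulate import (SimulationConfig, simulate_genome,
                               simulate_transcripts, to_read_alignments)

cfg = SimulationConfig(seed=11, genome_len=30_000, n_ptus=4, genes_per_ptu=(2, 3),
                       introns_per_gene=(1, 1), intron_len_range=(120, 250),
                       retention_prob=0.3, truncation=0.1,
                       reads_per_ptu=(20, 30))
annotation, truth = simulate_genome(cfg)
reads = to_read_alignments(simulate_transcripts(annotation, truth, cfg),
                           annotation, truth, cfg)

junctions = extract_junctions(reads, annotation.genome.length,
                              min_intron_len=40, min_support=2)
calls, intergenic = call_introns(junctions, annotation)
print(f"{len(junctions)} supported junctions -> {len(calls)} intron calls "
      f"({len(intergenic)} intergenic)")

# corrupt the annotation: drop one real intron, shift another's donor by 6 bp
genes = []
for g in annotation.genes:
    ex = g.exons_genomic
    if len(ex) == 2 and not genes:
        genes.append(dataclasses.replace(g, exons=[(ex[0][0], ex[1][1])]))
    elif len(ex) == 2 and len(genes) == 1:
        genes.append(dataclasses.replace(g, exons=[(ex[0][0], ex[0][1] + 6), ex[1]]))
    else:
        genes.append(g)
corrupted = GenomeAnnotation(genome=annotation.genome, genes=genes)

statuses = {}
for c in compare_with_annotation(calls, corrupted):
    statuses[c.status] = statuses.get(c.status, 0) + 1
print("reconciliation vs corrupted annotation:", statuses)
# confirmed = annotated interval matches the reads exactly;
# boundary_corrected = reads move an exon-intron boundary;
# missed_by_prediction = reads splice where no intron was annotated.

first = calls[0]
est = retention_fraction(reads, first, annotation.genome.length)
print(f"intron {first.gene_id}#{first.intron_index}: retention fraction "
      f"{est.fraction_retained:.2f} over {est.n_spliced + est.n_retained} "
      f"spanning reads, isoform lengths {est.isoform_lengths}")

seq = annotation.genome.seq[first.start:first.end]
if annotation.gene(first.gene_id).strand == "-":
    from Bio.Seq import Seq
    seq = str(Seq(seq).reverse_complement())
score = score_group2_boundaries(seq)
print(f"boundary consensus: 5' {score.five_prime_seq} (mismatches vs GTGYG: "
      f"{score.five_prime_mismatches}), 3' {score.three_prime_seq}, "
      f"canonical={score.canonical}, domain-V triad present={score.triad_present}")
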