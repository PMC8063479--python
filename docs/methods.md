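# Methods

## Scope and model

`ptuscope` analyses transcription of a circular organellar genome from
spliced, orientation-preserving full-length cDNA alignments. The central
assumption is that each read is a single transcript molecule (full-length,
non-chimeric), so the set of genes a read covers completely *is* direct
evidence of co-transcription, and block gaps in its alignment *are* splicing
events. The package consumes alignments; running the aligner, assembling
genomes, and automated gene prediction are out of scope.

### Coordinates and circularity

All internal coordinates are 0-based half-open in `[0, L)`. Features and
reads that wrap the origin are chains of in-range intervals; interval
arithmetic conceptually doubles the genome and normalizes mod `L`
(`ptuscope._coords`). Gene exon chains are stored in transcription order;
rotation of the circular origin is a no-op for every extraction (tested).

### Cistronic typing and PTU merging

A gene is *intact in a read* iff every exon is contained in the union of the
read's aligned blocks, allowing `coverage_slack` uncovered bases at each exon
terminus, and gene strand equals read strand. `coverage_slack` defaults to
0 bp — the strict criterion; real alignments fray at termini, so it is
exposed. The read's cistronic type is the tuple of intact genes ordered along
the transcription direction (anchored at the read's 5′ end, so ordering is
correct even for origin-wrapping reads). Intronic ORFs are nested inside
their host gene's transcripts and are never typed as independent members;
they are reported as PTU *content*.

PTUs are connected components of same-strand types under the share-≥1-gene
relation, computed by a deterministic union-find and verified against a
brute-force transitive closure in the tests. Adjacency without a shared gene
does not merge by default: a transcript's UTR extending over a neighbouring
gene without covering it completely is not treated as co-transcription
evidence. PTU ids are assigned in order of smallest normalized start
coordinate, making output ordering deterministic.

Single-gene PTUs are annotated with a reason: `intronic_orfs` when the gene
hosts intronic ORFs (the long rRNA-style operons); `cleaved_cistrons` when
reads overlapping the gene form ≥ 2 clearly distinct span groups strictly
nested inside it (> 20 bp apart at either end, to ignore terminus jitter) —
the signature of a cistron processed into smaller RNAs. Because the
full-coverage rule makes all member types of a singleton identical, cleavage
evidence is taken from read spans, not from types; this requires passing the
alignments to `classify_singletons`.

### Introns

Junctions are inter-block gaps ≥ `min_intron_len` (default 40 bp — below
that, gaps are treated as alignment deletions; the choice separates the two
regimes cleanly for organellar introns, which are hundreds of bases long),
merged by identical (donor, acceptor, strand) and filtered at `min_support`
(default 2 reads; one spliced read is too weak to call a boundary).
Junction-to-gene assignment requires containment in a same-strand gene span;
intron indices count 5′→3′ along transcription.

Reconciliation statuses are exhaustive per gene: annotated introns matching
an observed junction exactly are `confirmed` (long-read junctions are
base-precise, so any disagreement is a correction, not noise); overlapping
but unequal intervals are `boundary_corrected`; observed-only are
`missed_by_prediction`; annotation-only are `spurious_prediction` (callers
should derive calls from reads that cover the gene, so absent splicing
evidence means continuous alignment through the interval).

Retention of a call uses reads spanning `[start-f, end+f)` with flank
`f = 20 bp` (enough to rule out terminus artifacts without discarding many
reads): a read is *spliced* when one of its gaps equals the intron interval
exactly, *retained* when it aligns continuously across the interval. The
estimate is retained/(retained+spliced); the distinct aligned lengths of the
spanning reads are reported as isoform lengths.

Group II consensus scoring compares the first 5 nt to GUGYG and the last 2 nt
to AY under IUPAC codes; `canonical` requires a perfect match at both ends.
The catalytic triad (AGC, or CGC in some introns) is searched inside a
domain-V window supplied by the caller, defaulting to the 3′-most 60 nt,
where domain V lies; secondary-structure prediction is out of scope, so the
window is an input, not an inference.

Boundary projection maps ungapped source coordinates through alignment
columns to a homolog, sliding up to `slide_window = 9 nt` (three codons —
larger windows risk jumping to a spurious frame) to the nearest offsets where
the joined target exons keep an open reading frame (length ≡ 0 mod 3, no
internal stop). Flank identity is measured over ±15 alignment columns around
both boundaries. Mean pairwise identity of an alignment is
matches / columns-not-both-gapped per pair, averaged over all pairs, in
percent; whether to exclude doubly gapped columns is a genuine choice and
this definition is declared rather than assumed universal.

### Fragmented genes and RNA editing

Fragment pairs are declared in the annotation (`fragment_of` naming), not
auto-detected — identifying them requires cross-species homology, which is
out of scope. Verdicts use the same full-coverage rule as typing: with
`n_both` spanning reads and `n_a`/`n_b` single-fragment reads,
`co_transcribed` iff `n_both / (n_both+n_a+n_b) ≥ co_ratio` (0.5),
`separate` iff `n_both == 0` and singles ≥ `min_reads` (5), `insufficient`
below `min_reads`, else `mixed`. The thresholds are this package's own; the
underlying wet-lab comparison is qualitative (band strengths), so no
published cut-off exists to adopt.

Editing sites are pileup positions where one alternative base reaches
`editing_min_freq = 0.5` at depth ≥ `editing_min_depth = 10`. A transitions
only filter (C↔U / A↔G) exists but is off by default, since editing in green
algal chloroplasts is not established and the scan is used as a negative
control. With ~1% substitution noise, a false site needs half the reads to
err identically at one position — binomially negligible at depth ≥ 10, which
the tests confirm empirically across 100 seeds.

## The synthetic-data generator

`simulate_genome` lays genes left-to-right into PTU blocks (no same-strand
overlap by construction), separated by 400–900 bp intergenic gaps between
units and 60–200 bp within; defaults emulate a ~130 kb plastome with 16
units of 1–9 genes, gene bodies of 300–1200 bp (ATG…stop, no internal stop),
tRNAs of 72–90 bp, 0–2 introns of 300–900 bp per coding gene. Introns carry
the GUGYG…AY termini and an AGC triad in the 3′ 60 nt when
`canonical_intron_ends` is on (inserted reverse-complemented for minus-strand
genes so the transcript orientation carries the consensus). Fragment pairs
are built by splitting a CDS with a 1 nt frameshift into adjacent a/b models;
"co" pairs form one transcription unit, "separate" pairs two single-gene
units, which is exactly how their ground-truth verdicts are encoded.

`simulate_transcripts` emits per-unit reads spanning the full unit, each
intron spliced with probability `1 - retention_prob`, then truncated
independently at both ends: the overhang removed per end is geometric in
transcript coordinates, `P(remove k) = (1-t)·t^k`. Transcripts start exactly
at the unit boundaries (no UTR margin), so `t = 0` yields full-span reads,
moderate `t` leaves edge genes covered by some read at realistic depth, and
heavy `t` with thin depth (e.g. `t = 0.95`, 3 reads/unit) loses unit edges —
the documented negative control for PTU recovery. Mismatches are
substitutions only (indels are omitted so block arithmetic stays exact);
planted editing sites are specified as (gene_index, offset, alt, freq) and
resolved to genome positions at build time, forcing the genomic base away
from the alt allele. Emission to SAM (via pysam, `N` gaps, `MD`/`NM` tags)
and to a block-table TSV derive mismatches from the same seeded stream, so
both load back to identical in-memory alignments. Everything is deterministic
given the seed (integer RNG streams; no float-order dependence).

What the generator does **not** emulate: realistic PacBio error profiles
(indels, quality-dependent errors), polyA-capture abundance bias, chimeric
reads, heteroplasmy, and transcription start/stop heterogeneity beyond the
geometric truncation. Passing tests therefore demonstrate correctness of the
*inference logic* under idealized FLNC properties, not robustness to every
artifact of real libraries — on real data the `coverage_slack`,
`min_identity` and `min_support` knobs absorb part of that gap.

`simulate_homolog_family` generates the cross-species reannotation scenario:
homologs of one coding gene diverged by ~8% point substitutions, all carrying
an equal-length intron at a conserved codon boundary (so the genomic
alignment is trivially gap-free), with per-species misannotated donors
shifted by a non-multiple of 3 — the frameshifting boundary errors that
boundary projection is meant to fix.

## Verification problem sizes

The test suite and `scripts/acceptance.py` use reduced problem sizes chosen
to make the statistics decisive while keeping runs quick: 100 random
instances (≤ 20 genes, ≤ 200 reads) for oracle equivalence; 10 genomes of
5 units at 20–50 reads/unit for PTU recovery (the probability that a unit
edge is never covered at `t = 0.5` is `2^-20` per end, so exact recovery is
the overwhelmingly likely outcome, and its failure diagnostic); ≥ 200
planted introns for boundary exactness; 1000 spanning reads for the
retention estimate (binomial SE ≈ 0.015, well inside the ±0.05 band); 100
seeds each for the editing scan and fragment verdicts, with planted editing
frequencies of 0.9 at depth ≥ 15 so the detection probability is effectively
1 per site. Fragment-verdict runs use light truncation (`t = 0.05`) and
20–30 reads per unit so the co/separate patterns are statistically
unambiguous at the default `co_ratio`.

## Known limitations

- PTU spans are reported as the smallest covering arc of member genes; a PTU
  whose members wrap the origin is handled, but reads wrapping the origin
  cannot be represented in SAM output (the block table supports them).
- `compare_with_annotation` has no "insufficient data" status; a predicted
  intron in an uncovered gene would be labelled spurious. Run it on calls
  from reads that cover the genes of interest.
- Boundary projection assumes the supplied alignment is sensible around the
  boundaries; it reports flank identity so callers can judge.
- The GenBank reader covers CDS/tRNA/rRNA features with simple or compound
  locations; exotic location operators are not supported.
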