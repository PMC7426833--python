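# Methods

This note documents the models, parameter choices and numerical decisions
behind retropap, and what the synthetic benchmarks do and do not show
about real data.

## Seed-and-chain alignment

Genome-to-genome comparison uses exact-match k-mer anchors (default
k = 15) merged into maximal shared runs, chained by sparse dynamic
programming into colinear local alignments on both strands.  Design
points:

- **Exact seeds, no mismatch tolerance.**  A substitution simply breaks a
  run; chaining across broken anchors recovers the alignment.  This is
  adequate up to a few percent divergence (anchors stay dense: at 0.5%
  SNPs the expected clean-run length is ~200 bp) and keeps the aligner
  small and exactly testable against a brute-force shared-k-mer oracle.
  It is *not* suitable for diverged sequence (> ~5%), protein alignment,
  or base-level gap placement.
- **Chaining.**  Score = aligned bp − 0.01/bp gap penalty, gaps capped at
  20 kb per join, so a chain happily spans a multi-kb deletion (that is
  the signal being genotyped).  Anchors may overlap a predecessor by up to
  k bp (chance run extension across a breakpoint); the overlap is trimmed
  from the downstream block so emitted chains are strictly colinear and
  non-overlapping.  k-mers occurring more than 16 times in a target
  sequence are skipped (repeat masking); chains aligning fewer than 50 bp
  in total are dropped.
- **Best-matching region** returns the top-scoring chain's target interval
  padded by 1 kb, with deterministic tie-breaks (score, aligned length,
  sequence id, start).  Queries with no chain scoring ≥ 100 matched bp
  return nothing — that is a value ("missing"/no hit), not an error.
  Where the original protocol applies long-near-exact-hit search
  thresholds, they are realized as a minimum chain score of 1000 matched
  bp.

## PAP genotyping

For each element, the reference flank window (default ±50 kb; windows
beyond 100 kb are rejected as no longer "local") is located genome-wide in
the target, then re-aligned against the located region, and the alignment
ratio is measured **over the element span only** — the only denominator
for which 1.0 unambiguously means "the element is completely present".
The flanks serve purely to anchor the locus, which also makes the ratio
invariant to flank-only mutation (property-tested).

Call thresholds: present ≥ 0.8, absent ≤ 0.2, ambiguous between.  The
endpoints (1.0 = present, 0 = absent) are principled; the 0.8/0.2 band is
a pragmatic choice to handle partially eroded insertions honestly, and
both bounds are configurable.

Accession clustering operates on the numeric ratio matrix (not binarized
calls) with complete linkage on Euclidean distances — the defaults of R's
`hclust` — with rows entered in lexicographic accession order for
determinism, and missing ratios imputed by the per-element mean across
accessions (calls stay `missing`; imputation is for clustering only).

## Orthology and CNV/PAP classification

Sequence similarity is shared-k-mer containment |shared| / |query k-mers|
(DNA 15-mers on transcripts, amino-acid 4-mers on proteins), a desk-scale
stand-in for bidirectional search scores with the same best-hit /
reciprocal-best-hit structure.  Minimum containments: 0.3 cross-genome,
0.5 for within-genome homologue search — needed to bound random k-mer
noise, exposed in the API.  The transcript-to-genome confirmation
(best-matching region of the query transcript must overlap the partner's
locus by ≥ 1 bp) plays the role of a spliced-alignment check.

"Tandem" is defined as best within-genome homologue on the same sequence
within 100 kb and at most 5 intervening genes; both knobs are exposed, as
the notion is not standardized.  Identical duplicate copies tie in the
similarity channel; the deterministic tie-break (containment, subject
length, lexicographic id) pairs the query with one copy and leaves the
other for CNV classification, so a duplication costs at most the
classification of the extra copy, never the orthologue pair.  Genes whose
transcript finds no genomic hit at all in the partner genome are PAP
candidates (`non_tandem_cnv_pap` with `no_genomic_hit` evidence); the
distinction between non-tandem CNV and PAP is kept as evidence labels
inside one category rather than split into two calls.

## Expression analysis

- Non-expressed features are removed at FPKM ≥ 0.1; the default keeps a
  feature expressed in *at least one* sample (`mode="any"`), matching the
  way expressed-gene counts are usually quoted; `mode="all"` implements
  the stricter reading (below threshold in any sample ⇒ removed).
- Ripening classification is a pure argmax with ties excluded: the
  ripening-group mean must strictly exceed every other group mean
  (`min_fold` can demand a margin; default 1.0).
- Neighbour co-expression pairs each query with the nearest annotated gene
  on each side within 50 kb (edge-to-edge).  The window is a deliberate
  superset of promoter-scale distances at which an inserted element can
  plausibly rewire regulation.  Pearson r is computed on raw FPKM vectors
  across all samples (not log scale, not group means); fractions are
  reported per neighbour pair with the denominator restricted to pairs
  with defined r (constant vectors give NaN and are excluded).
- Fisher enrichment excludes the foreground from the background cells by
  default (`bg_includes_fg` switches the convention).  Multiple testing is
  Benjamini–Hochberg; BH with π₀ = 1 is a deterministic, conservative
  upper bound on density-estimated q-values and avoids π₀ estimation on
  the short p-value lists typical here.

## Assembly-editing rules

`split_low_depth` cuts contigs wherever per-bp read depth < 4 (strictly;
depth 4 survives) and keeps maximal runs ≥ 100 bp.  The minimum-run length
is not dictated by any external protocol; 100 bp removes fragments too
short to place while conserving everything alignable, and is configurable.

`hint_join` aligns both terminal 50 kb windows of each hint sequence to
the primary assembly; a join requires both ends to hit two *distinct*
scaffolds with chains of identity ≥ 0.99, aligned length ≥ 5 kb and score
≥ 1000.  Joins are applied greedily by descending combined score, each
scaffold end used at most once (conflicts are logged and skipped), with a
fixed 100-N gap — gap sizing is not knowable from the hint, so a constant
sentinel keeps outputs deterministic.  Orientation follows the hint: a
minus-strand end hit means the scaffold is reverse-complemented so its
aligned end faces the junction.

## The synthetic data generator

The generator *defines the study conditions*; its defaults are the
conditions every recovery statistic is quoted under:

| parameter | default | meaning |
|---|---|---|
| chromosomes | 2 × 1 Mb | reference genome size |
| genes | 200 | random multi-exon ORFs, 300–1500 bp CDS, 0–2 introns |
| elements | 40 | Gag-like spans, 2–7 kb uniform |
| accessions | 10 (incl. reference) | leaves of the accession tree |
| flip prob / branch | 0.15 | element presence flip per unit branch length |
| SNP rate | 0.005 / bp | per accession, independent |
| small indels | 0.0005 / bp, 1–10 bp | intergenic only |
| tandem dup / loss | 0.02 / 0.02 per gene | per accession |
| contig N50 target | 200 kb | fragmentation stage |
| tissue groups | 8 × 3 samples | incl. `ripening_fruit` |
| p(ripening-inducible) | 0.386 | element-level Bernoulli |
| p(neighbour co-expressed) | 0.594 | per flanking gene of a ripening element |
| expression noise | 0.25 log-SD | group- and sample-level jitter |

Design decisions worth recording:

- **Tree.**  The default 10-leaf tree places the reference and two short
  sister branches (length 0.5) in one trio — emulating cultivars of shared
  recent origin — and the remaining seven accessions on a caterpillar
  behind a long (length 3) stem.  Flip probability per branch is
  1 − (1 − p)^length.  The reference leaf sits at distance 0 from the
  root: presence is *measured relative to the reference*, so its lineage
  is the measuring stick and carries no changes; the generator enforces
  this.  Branch lengths were chosen a priori so that the trio's internal
  presence distances are well below its distance to any outsider, giving
  the clustering-recovery benchmark a known answer.
- **Exact-span excision by default.**  Element deletions remove exactly
  the annotated span, so truth coordinates stay exact.  The
  `ragged_breakpoints` option perturbs each deletion breakpoint by ±200 bp
  (leaving element stubs or eating flank), exercising the partial-presence
  regime of the ratio.
- **Guard zones and purifying selection.**  SNPs avoid ±50 bp around every
  feature boundary, indels are intergenic-only, and coding SNPs that would
  create premature stop codons are reverted.  This is testability over
  realism: it keeps truth coordinates exact and protein channels
  informative, at the cost of slightly optimistic orthology conditions.
- **Tandem duplications and losses** are drawn once per accession (not per
  branch), keeping the realized per-accession event rate at the configured
  2%; the duplicate copy is inserted immediately after its parent and is
  sequence-identical to it within that accession.
- **Expression model.**  Per-feature per-group log-means are N(2,1);
  samples add N(0, 0.25); FPKM = max(exp(x) − 0.01, 0).  A
  ripening-inducible element's ripening mean is set to
  max(other groups) + Δ (Δ = 3), and a non-inducible element whose random
  maximum happened to land in the ripening group has that value swapped
  away.  This enforcement makes the Bernoulli truth label and the realized
  profile agree — without it a noticeable minority of "inducible" draws
  would not actually peak in ripening fruit and no classifier could score
  against the label.  Co-expressed neighbours copy their element's
  group-mean profile plus N(0, 0.25) per group; all other features are
  independent.
- **Determinism.**  One integer seed drives fixed per-stage substreams
  (`default_rng([seed, stage])`); identical seeds reproduce identical
  files.

**What the benchmarks do not show.**  Synthetic genomes are i.i.d. random
DNA: there are no repeat families, no segmental duplications, no nested or
truncated element copies, no target-site duplications, and divergence is
uniform.  Real assemblies violate all of these, so the measured recovery
rates are upper bounds — the benchmarks validate the *machinery*
(coordinates, chaining, thresholds, bookkeeping), not expected field
performance.  Likewise the expression model has no count noise,
library-size effects or batch structure; recovering the configured
fractions shows the estimator is unbiased under the model, not that FPKM
correlation is a good co-expression measure.

## Benchmark problem sizes

Recovery statistics are measured at the default scale above: one clean and
one ragged simulation for PAP concordance (400 element × accession cells
each), one pairwise comparison against the most distant accession for
orthologue recall (~195 pairs), 100 constructed deletion pairs for the
alignment-ratio error, 50 simulated expression datasets (2000 elements,
~1500 neighbour pairs pooled) for the fraction recovery, 50 genotype
matrices for clade recovery, and all 135,750 2×2 tables with total ≤ 40
for the exact-test sweep.  These sizes make the whole benchmark run in a
few minutes on one CPU while keeping every binomial comparison
well-powered.

## Known limitations

- The aligner's ratio is coverage by *exact* blocks, so high SNP density
  inside an element lowers the ratio toward the ambiguous band; at ≥ 2–3%
  divergence present elements would start to genotype as ambiguous.
- Orthology is similarity-plus-position only; no synteny chains, paralogy
  trees or Ka/Ks, so ancient duplications with diverged copies can be
  mis-binned.
- hclust on ratio matrices is a phenetic summary, not a phylogeny; the
  clade-recovery benchmark asks only for monophyly of the planted trio.
- The enrichment module does not propagate term hierarchies (no true-path
  rule) and does not correct gene-length bias.
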