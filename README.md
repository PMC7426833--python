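# retropap

Assembly-based genotyping of **presence/absence polymorphisms (PAPs)** of
retrotransposon Gag-like elements across related genome assemblies,
cross-genome **gene-partner classification** (orthologues, homologues,
CNVs, PAPs), and the link between element PAPs and **fruit-ripening-inducible
expression** of their neighbouring genes.

The package targets the comparative-genomics situation found in crop
species such as melon: one high-quality reference genome annotated with
protein-coding genes and LTR-retrotransposon Gag-domain sequences
(InterPro IPR005162), plus several contig-level assemblies of related
accessions.  Because every genome is assembled, structural presence/absence
can be read directly from genome-to-genome alignment instead of from read
mapping.  All pipeline stages are exercised end-to-end on synthetic genomes
with known ground truth, so every recovered quantity can be scored.

## The core statistics

**Alignment ratio.**  For an element *e* with reference locus
`[s, e)` a flank window of ±50 kb is excised and used as query against a
target assembly.  The best-matching region is located genome-wide
(seed-and-chain alignment with exact 15-mer anchors and sparse-DP
chaining), the query is re-aligned to that region, and

```
ratio(e, target) = |union of aligned blocks ∩ element span| / |element span|
```

so 1.0 means the element is completely present in the target and 0 that it
is absent; calls are `present` (ratio ≥ 0.8), `absent` (≤ 0.2),
`ambiguous` in between, and `missing` when even the flank finds no region.
Accessions are then clustered on the ratio matrix (complete linkage,
Euclidean — R `hclust` defaults).

**One-to-one orthology.**  Genes of two genomes are paired when they are
reciprocal best hits in *both* the transcript (DNA 15-mer containment) and
the protein (4-mer containment) channel *and* the query transcript's best
genomic alignment in the partner genome overlaps the partner's locus.
Genes without a one-to-one partner are classified `tandem_dup_cnv`,
`non_tandem_cnv_pap`, or `unanchored`; one-to-one genes receive consensus
IDs (`<partner_id>.jh1`).

**Expression.**  Features with max FPKM ≥ 0.1 are kept; a feature is
*ripening-inducible* when its mean FPKM in the post-harvest ripening group
is the strict maximum over tissue groups; each element is paired with its
nearest annotated gene on each side (≤ 50 kb) and co-expression is Pearson
*r* > 0.8 on raw FPKM vectors.  Term enrichment of CNV/PAP candidates uses
two-sided Fisher exact tests with Benjamini–Hochberg adjustment.

## Worked example

```bash
retropap run --config sim.json --seed 7 --outdir demo
```

with `sim.json` scaling the simulation down to 2 × 200 kb chromosomes,
40 genes, 10 elements and 6 accessions prints:

```
retropap end-to-end run (seed 7)

orthology (ACC05 vs REF):
  one-to-one recall: 40/40 (100.0%)
  false one-to-one pairs: 0
  categories: {'one_to_one': 40, 'tandem_dup_cnv': 1}

pap genotyping:
  call/truth concordance: 60/60 (100.00%)
  present<->absent sign errors: 0
  planted clade recovered: False

expression:
  ripening-inducible elements: 3/10 (30.0%; simulated p=0.386)
  neighbour co-expression (r > 0.8): all_genes=0.079 (n=76), other_elements=0.000 (n=12), ripening_elements=1.000 (n=5)  [simulated p=0.594]

enrichment (PAP/CNV candidates vs genome):
  foreground size: 3
  top term: IPR005162 (p=0.00612, q=0.178); Gag-domain term is top-ranked
```

Reading this: all 40 simulated orthologue pairs were recovered and the one
simulated tandem duplication was classified as such; all 60 element ×
accession presence states were genotyped correctly with no present/absent
sign error; 3 of 10 elements were ripening-inducible (a draw from the
configured 38.6% rate at n = 10) and all 5 neighbours of those elements
exceeded r = 0.8 while the control sets sat at background; the Gag-domain
term IPR005162 topped the enrichment of the PAP candidates.  At this toy
scale the 10-element genotype matrix is too small to resolve the planted
accession trio — the dendrogram check is meaningful at the default scale
(40 elements), where `scripts/acceptance.py` measures ≥ 90% recovery.

The run directory contains every stage table (`pap_ratio.tsv`,
`pap_call.tsv`, `partner_calls.tsv`, `ripening_calls.tsv`,
`neighbor_pairs.tsv`, `enrichment.tsv`), the dendrogram
(`pap_dendrogram.nwk`), the simulated genomes with truth tables
(`simulated/`), and a `manifest.json` echoing every parameter.  Re-running
with the same seed reproduces the directory byte for byte.

Library use mirrors the CLI:

```python
from retropap.synthetic import SimConfig, simulate_dataset
from retropap.pap import build_pap_matrix, cluster_accessions

ds = simulate_dataset(SimConfig(seed=1))
targets = {a: d.assembly for a, d in ds.accessions.items() if a != "REF"}
matrix = build_pap_matrix(ds.elements, ds.reference, targets)
tree = cluster_accessions(matrix)
```

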