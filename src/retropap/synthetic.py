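"""Synthetic genomes with known element presence/absence ground truth.

Generates a chromosome-level reference genome carrying protein-coding
genes and retrotransposon Gag-like elements, derives related accession
genomes along a fixed tree (element presence flips per branch, plus
per-accession SNPs, small indels, tandem gene duplications and gene
losses), optionally fragments assemblies into contigs, and simulates a
tissue-wide FPKM matrix with controlled ripening-inducible and
neighbour co-expression structure.  Every stage records its events in
truth tables so each pipeline stage can be scored against ground truth.

Determinism: one integer seed drives fixed per-stage substreams; the same
seed reproduces the dataset byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .expression import nearest_flanking_genes
from .genome_model import (
    GAG_TERM,
    ExpressionMatrix,
    GagElement,
    GeneModel,
    GenomeAssembly,
    GenomicInterval,
    read_newick,
    revcomp,
    write_bed_elements,
    write_expression_tsv,
    write_fasta,
    write_gff3,
)

REFERENCE_ID = "REF"

#: Default accession tree (Newick, branch lengths scale flip/unit rates).
#: The reference sits at the root with two very close sister accessions —
#: the analog of a cultivar trio of shared origin — while the remaining
#: seven accessions hang off a long stem as a caterpillar.
DEFAULT_TREE = (
    "((REF:0.0,ACC01:0.5,ACC02:0.5):0.0,"
    "(ACC03:1,(ACC04:1,(ACC05:1,(ACC06:1,(ACC07:1,(ACC08:1,ACC09:1):1):1):1):1):1):3);"
)

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SENSE_CODONS = [c for c in _CODONS if c not in _STOPS and c != "ATG"]
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """All simulation parameters; defaults define the study conditions."""

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length_bp: int = 1_000_000
    n_genes: int = 200
    n_elements: int = 40
    element_length_range: tuple[int, int] = (2_000, 7_000)
    accession_tree: str = DEFAULT_TREE
    pap_flip_prob_per_branch: float = 0.15
    snp_rate: float = 0.005
    small_indel_rate: float = 0.0005
    assembly_n50_target_bp: int = 200_000
    tandem_dup_prob: float = 0.02
    gene_loss_prob: float = 0.02
    tissue_groups: tuple[str, ...] = (
        "root", "leaf", "stem", "flower", "young_fruit", "mature_fruit",
        "seed", "ripening_fruit")
    ripening_group: str = "ripening_fruit"
    samples_per_group: int = 3
    p_ripening_inducible: float = 0.386
    p_neighbor_coexpressed: float = 0.594
    expression_noise_sd: float = 0.25
    ripening_delta: float = 3.0
    neighbor_window_bp: int = 50_000
    guard_bp: int = 50
    ragged_breakpoints: bool = False
    ragged_max_bp: int = 200
    min_gap_bp: int = 200

    def __post_init__(self) -> None:
        probs = [self.pap_flip_prob_per_branch, self.snp_rate,
                 self.small_indel_rate, self.tandem_dup_prob,
                 self.gene_loss_prob, self.p_ripening_inducible,
                 self.p_neighbor_coexpressed]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0,1]")
        if self.tandem_dup_prob + self.gene_loss_prob > 1.0:
            raise ValueError("tandem_dup_prob + gene_loss_prob > 1")
        for v in (self.n_chromosomes, self.chromosome_length_bp,
                  self.samples_per_group):
            if v <= 0:
                raise ValueError("counts and lengths must be positive")
        if self.n_genes < 0 or self.n_elements < 0:
            raise ValueError("feature counts must be >= 0")
        if self.element_length_range[0] > self.element_length_range[1]:
            raise ValueError("bad element_length_range")
        if self.ripening_group not in self.tissue_groups:
            raise ValueError("ripening_group missing from tissue_groups")

    def leaf_names(self) -> list[str]:
        tree = read_newick(self.accession_tree)
        return [t.name for t in tree.tips()]


@dataclass
class TruthTables:
    """Ground-truth record of every simulated event."""

    element_presence: pd.DataFrame = field(default_factory=pd.DataFrame)
    branch_flips: pd.DataFrame = field(default_factory=pd.DataFrame)
    element_ripening: pd.Series = field(default_factory=lambda: pd.Series(dtype=bool))
    neighbor_coexpressed: pd.DataFrame = field(default_factory=pd.DataFrame)
    ortho: pd.DataFrame = field(default_factory=pd.DataFrame)
    fragmentation: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class AccessionData:
    assembly: GenomeAssembly
    genes: list[GeneModel]
    elements_present: pd.Series  # bool per reference element id


@dataclass
class SimDataset:
    config: SimConfig
    reference: GenomeAssembly
    genes: list[GeneModel]
    elements: list[GagElement]
    accessions: dict[str, AccessionData]
    truth: TruthTables
    expression: ExpressionMatrix | None = None


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stage])


def _rand_dna_arr(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _arr_to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Reference simulation
# ---------------------------------------------------------------------------

def _make_gene(rng: np.random.Generator):
    """Random gene: valid ORF split into 1-3 exons with short introns.

    Returns (genomic_seq, strand, exon_offsets, cds_len) where exon offsets
    are (start, end) relative to the gene span in genomic orientation.
    """
    n_codons = int(rng.integers(100, 500))
    body = rng.choice(len(_SENSE_CODONS), size=n_codons)
    cds = "ATG" + "".join(_SENSE_CODONS[i] for i in body) + "TAA"
    n_exons = int(rng.integers(1, 4))
    cuts = sorted(rng.choice(np.arange(3, len(cds) - 3, 3), size=n_exons - 1,
                             replace=False)) if n_exons > 1 else []
    bounds = [0, *map(int, cuts), len(cds)]
    exon_seqs = [cds[a:b] for a, b in zip(bounds, bounds[1:])]
    introns = ["" if i == len(exon_seqs) - 1 else
               _arr_to_str(_rand_dna_arr(rng, int(rng.integers(100, 401))))
               for i in range(len(exon_seqs))]
    genomic = "".join(e + i for e, i in zip(exon_seqs, introns))
    offsets_fwd = []
    pos = 0
    for e, i in zip(exon_seqs, introns):
        offsets_fwd.append((pos, pos + len(e)))
        pos += len(e) + len(i)
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        glen = len(genomic)
        genomic = revcomp(genomic)
        offsets = sorted((glen - b, glen - a) for a, b in offsets_fwd)
    else:
        offsets = offsets_fwd
    return genomic, strand, offsets, len(cds)


def _transcript_from_assembly(assembly: GenomeAssembly, exons, strand) -> str:
    parts = [assembly.fetch(e) for e in sorted(exons, key=lambda e: e.start)]
    seq = "".join(parts)
    return revcomp(seq) if strand == "-" else seq


def simulate_reference(config: SimConfig,
                       rng: np.random.Generator | None = None
                       ) -> tuple[GenomeAssembly, list[GeneModel],
                                  list[GagElement], TruthTables]:
    """Build the reference genome with placed genes and Gag-like elements.

    Features are placed without overlap with at least ``min_gap_bp``
    between them; every element is guaranteed a gene within the neighbour
    window on at least one side.  Deterministic for a fixed seed.
    """
    rng = rng if rng is not None else _stage_rng(config.seed, 0)
    n_chrom = config.n_chromosomes

    # allocate feature counts per chromosome as evenly as possible
    genes_per = [config.n_genes // n_chrom + (1 if i < config.n_genes % n_chrom
                                              else 0) for i in range(n_chrom)]
    elems_per = [config.n_elements // n_chrom
                 + (1 if i < config.n_elements % n_chrom else 0)
                 for i in range(n_chrom)]

    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    elements: list[GagElement] = []
    gi = ei = 0
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        feats: list[tuple[str, object]] = []
        for _ in range(genes_per[ci]):
            feats.append(("gene", _make_gene(rng)))
        lo, hi = config.element_length_range
        for _ in range(elems_per[ci]):
            elen = int(rng.integers(lo, hi + 1))
            feats.append(("element", _arr_to_str(_rand_dna_arr(rng, elen))))
        rng.shuffle(feats)
        total_feat = sum(len(f[1][0]) if f[0] == "gene" else len(f[1])
                         for f in feats)
        n_gaps = len(feats) + 1
        slack = config.chromosome_length_bp - total_feat - n_gaps * config.min_gap_bp
        if slack < 0:
            raise ValueError(
                f"infeasible packing on {chrom}: features need "
                f"{total_feat + n_gaps * config.min_gap_bp} bp but chromosome is "
                f"{config.chromosome_length_bp} bp; reduce n_genes/n_elements "
                f"or increase chromosome_length_bp")
        gaps = config.min_gap_bp + rng.multinomial(slack, np.full(n_gaps, 1 / n_gaps))
        parts: list[str] = []
        pos = 0
        for gap, (kind, payload) in zip(gaps, feats):
            parts.append(_arr_to_str(_rand_dna_arr(rng, int(gap))))
            pos += int(gap)
            if kind == "gene":
                genomic, strand, offsets, _cds_len = payload
                gid = f"REFG{gi + 1:05d}"
                gi += 1
                exons = [GenomicInterval(chrom, pos + a, pos + b, strand)
                         for a, b in offsets]
                locus = GenomicInterval(chrom, pos, pos + len(genomic), strand)
                parts.append(genomic)
                transcript = "".join(
                    genomic[a:b] for a, b in offsets)
                if strand == "-":
                    transcript = revcomp(transcript)
                protein = str(Seq(transcript).translate()).rstrip("*")
                genes.append(GeneModel(gene_id=gid, locus=locus, exons=exons,
                                       cds=exons, transcript_seq=transcript,
                                       protein_seq=protein))
                pos += len(genomic)
            else:
                eid = f"GAG{ei + 1:04d}"
                ei += 1
                locus = GenomicInterval(chrom, pos, pos + len(payload), "+")
                parts.append(payload)
                elements.append(GagElement(element_id=eid, locus=locus,
                                           term_ids={GAG_TERM}))
                pos += len(payload)
        parts.append(_arr_to_str(_rand_dna_arr(rng, int(gaps[-1]))))
        sequences[chrom] = "".join(parts)

    assembly = GenomeAssembly(accession_id=REFERENCE_ID, sequences=sequences)
    for el in elements:
        if not nearest_flanking_genes(el.locus, genes, config.neighbor_window_bp):
            raise ValueError(f"{el.element_id} has no gene within the "
                             f"neighbour window; increase gene density")
    truth = TruthTables()
    if elements:
        truth.element_presence = pd.DataFrame(
            True, index=[e.element_id for e in elements], columns=[REFERENCE_ID])
    else:
        truth.element_presence = pd.DataFrame(index=pd.Index([], dtype=object),
                                              columns=[REFERENCE_ID])
    return assembly, genes, elements, truth


# ---------------------------------------------------------------------------
# Accession derivation
# ---------------------------------------------------------------------------

def _presence_by_leaf(config: SimConfig, element_ids: list[str],
                      rng: np.random.Generator
                      ) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Evolve element presence along the accession tree.

    The reference leaf must sit at total distance 0 from the root (its
    lineage is the measuring stick); every branch flips each element with
    probability 1-(1-p)^length.
    """
    tree = read_newick(config.accession_tree)
    n = len(element_ids)
    p = config.pap_flip_prob_per_branch
    leaves: dict[str, np.ndarray] = {}
    flip_rows = []

    def walk(node, state: np.ndarray, depth_to_ref: float) -> None:
        for child in node.children:
            length = child.length or 0.0
            p_branch = 1.0 - (1.0 - p) ** length
            flips = rng.random(n) < p_branch
            label = child.name or f"node@{id(child)}"
            flip_rows.append((label, length, p_branch, int(flips.sum()), n))
            child_state = state ^ flips
            if child.is_tip():
                leaves[child.name] = child_state
            else:
                walk(child, child_state, depth_to_ref)

    root_state = np.ones(n, dtype=bool)
    walk(tree, root_state, 0.0)
    if REFERENCE_ID in leaves and n and not leaves[REFERENCE_ID].all():
        raise ValueError(
            f"the {REFERENCE_ID} leaf must have total branch length 0 from "
            f"the root (it defines the reference state)")
    flips_df = pd.DataFrame(flip_rows, columns=["branch", "length",
                                                "p_branch", "n_flips",
                                                "n_elements"])
    return leaves, flips_df


def _allowed_positions(chrom_len: int, genes: list[GeneModel],
                       elements: list[GagElement], chrom: str, guard: int,
                       intergenic_only: bool) -> np.ndarray:
    """Boolean mask of positions where mutations may be placed."""
    ok = np.ones(chrom_len, dtype=bool)
    for g in genes:
        if g.locus.sequence_id != chrom:
            continue
        if intergenic_only:
            ok[max(0, g.locus.start - guard):g.locus.end + guard] = False
        else:
            bounds = [g.locus.start, g.locus.end]
            for e in g.exons:
                bounds += [e.start, e.end]
            for b in bounds:
                ok[max(0, b - guard):b + guard] = False
    for e in elements:
        if e.locus.sequence_id != chrom:
            continue
        if intergenic_only:
            ok[max(0, e.locus.start - guard):e.locus.end + guard] = False
        else:
            for b in (e.locus.start, e.locus.end):
                ok[max(0, b - guard):b + guard] = False
    return ok


def _repair_premature_stops(arr: np.ndarray, gene: GeneModel,
                            offset: int) -> None:
    """Revert SNPs that created internal stop codons in *gene*'s CDS.

    *arr* holds the mutated chromosome; *offset* is the chromosome start in
    arr coordinates (0 here, kept for clarity).  Models purifying selection
    on coding sequence.
    """
    exons = sorted(gene.exons, key=lambda e: e.start)
    idx = np.concatenate([np.arange(e.start, e.end) for e in exons]) + offset
    if gene.locus.strand == "-":
        idx = idx[::-1]
        tr = bytes(_COMP_TABLE[arr[idx]]).decode()
    else:
        tr = arr[idx].tobytes().decode()
    ref_tr = gene.transcript_seq
    for c in range(0, len(tr) - 3, 3):  # exclude the terminal stop
        if tr[c:c + 3] in _STOPS:
            ref_codon = ref_tr[c:c + 3]
            for j in range(3):
                pos = idx[c + j]
                want = ref_codon[j]
                arr[pos] = (ord(revcomp(want)) if gene.locus.strand == "-"
                            else ord(want))


_COMP_TABLE = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP_TABLE[_a] = _b

_BASE_LUT = np.zeros(256, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _BASE_LUT[_b] = _i


def derive_accessions(reference: GenomeAssembly, genes: list[GeneModel],
                      elements: list[GagElement], config: SimConfig,
                      truth: TruthTables,
                      rng: np.random.Generator | None = None
                      ) -> dict[str, AccessionData]:
    """Derive accession genomes from the reference along the tree.

    Element presence flips per branch; each non-reference accession then
    receives independent SNPs and small indels (outside 50 bp feature-edge
    guard zones; coding SNPs never create premature stops, indels are
    intergenic only), tandem gene duplications and gene losses.  Truth
    tables are updated in place.
    """
    rng = rng if rng is not None else _stage_rng(config.seed, 1)
    element_ids = [e.element_id for e in elements]
    el_by_id = {e.element_id: e for e in elements}
    leaves, flips_df = _presence_by_leaf(config, element_ids, rng)
    truth.branch_flips = flips_df

    presence = pd.DataFrame(
        {leaf: pd.Series(state, index=element_ids, dtype=bool)
         for leaf, state in leaves.items()})
    if REFERENCE_ID not in presence.columns:
        presence[REFERENCE_ID] = True
    cols = [REFERENCE_ID] + [c for c in presence.columns if c != REFERENCE_ID]
    truth.element_presence = presence[cols]

    accessions: dict[str, AccessionData] = {}
    ortho_rows = []
    for leaf in presence.columns:
        if leaf == REFERENCE_ID:
            accessions[leaf] = AccessionData(
                assembly=reference, genes=genes,
                elements_present=presence[leaf].copy())
            continue
        acc = _materialize_accession(leaf, reference, genes, elements, el_by_id,
                                     presence[leaf], config, rng, ortho_rows)
        accessions[leaf] = acc
    truth.ortho = pd.DataFrame(
        ortho_rows, columns=["accession", "ref_gene", "acc_gene", "event"])
    return accessions


def _materialize_accession(leaf: str, reference: GenomeAssembly,
                           genes: list[GeneModel], elements: list[GagElement],
                           el_by_id: dict[str, GagElement],
                           presence: pd.Series, config: SimConfig,
                           rng: np.random.Generator,
                           ortho_rows: list) -> AccessionData:
    dup_p, loss_p = config.tandem_dup_prob, config.gene_loss_prob
    gene_events: dict[str, str] = {}
    for g in genes:
        u = rng.random()
        if u < dup_p:
            gene_events[g.gene_id] = "tandem_dup"
        elif u < dup_p + loss_p:
            gene_events[g.gene_id] = "lost"

    sequences: dict[str, str] = {}
    new_gene_models: list[GeneModel] = []
    gene_counter = 0

    for chrom, seq in reference.sequences.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        clen = len(arr)
        chrom_genes = [g for g in genes if g.locus.sequence_id == chrom]
        chrom_elems = [e for e in elements if e.locus.sequence_id == chrom]

        # SNPs anywhere except feature-edge guard zones
        snp_ok = _allowed_positions(clen, chrom_genes, chrom_elems, chrom,
                                    config.guard_bp, intergenic_only=False)
        snp_sites = np.flatnonzero(snp_ok)
        n_snp = rng.binomial(len(snp_sites), config.snp_rate)
        if n_snp:
            pos = rng.choice(snp_sites, size=n_snp, replace=False)
            shift = rng.integers(1, 4, size=n_snp)
            arr[pos] = _BASES[(_BASE_LUT[arr[pos]] + shift) % 4]
        for g in chrom_genes:
            if gene_events.get(g.gene_id) != "lost":
                _repair_premature_stops(arr, g, 0)

        # small indels, intergenic only
        ind_ok = _allowed_positions(clen, chrom_genes, chrom_elems, chrom,
                                    config.guard_bp, intergenic_only=True)
        ind_sites = np.flatnonzero(ind_ok)
        n_ind = rng.binomial(len(ind_sites), config.small_indel_rate)
        indel_ops = []
        if n_ind:
            ipos = np.sort(rng.choice(ind_sites, size=n_ind, replace=False))
            for p in ipos:
                length = int(rng.integers(1, 11))
                if rng.random() < 0.5:
                    indel_ops.append((int(p), int(p) + length, "del", None))
                else:
                    ins = _arr_to_str(_rand_dna_arr(rng, length))
                    indel_ops.append((int(p), int(p), "ins", ins))

        # structural ops: element excisions, gene losses, tandem dups
        ops = list(indel_ops)
        for e in chrom_elems:
            if not presence[e.element_id]:
                s, t = e.locus.start, e.locus.end
                if config.ragged_breakpoints:
                    s += int(rng.integers(-config.ragged_max_bp,
                                          config.ragged_max_bp + 1))
                    t += int(rng.integers(-config.ragged_max_bp,
                                          config.ragged_max_bp + 1))
                    s = max(0, min(s, e.locus.end - 1))
                    t = max(s + 1, min(t, clen))
                ops.append((s, t, "del", None))
        for g in chrom_genes:
            ev = gene_events.get(g.gene_id)
            if ev == "lost":
                ops.append((g.locus.start, g.locus.end, "del", None))
            elif ev == "tandem_dup":
                copy = arr[g.locus.start:g.locus.end].tobytes().decode()
                ops.append((g.locus.end, g.locus.end, "dup", (g, copy)))
        ops.sort(key=lambda o: (o[0], o[1]))

        # sweep: rebuild sequence, track kept segments for coordinate lifting
        segments: list[tuple[int, int, int]] = []  # (ref_s, ref_e, new_s)
        chunks: list[np.ndarray | bytes] = []
        dup_intervals: dict[int, tuple[GeneModel, int]] = {}
        cur = 0
        new = 0
        for (s, t, kind, payload) in ops:
            if s < cur:  # overlapping op (rare indel collision): skip
                continue
            if s > cur:
                segments.append((cur, s, new))
                chunks.append(arr[cur:s])
                new += s - cur
            if kind == "del":
                cur = t
            elif kind == "ins":
                chunks.append(payload.encode())
                new += len(payload)
                cur = t
            else:  # dup
                g, copy = payload
                dup_intervals[new] = (g, len(copy))
                chunks.append(copy.encode())
                new += len(copy)
                cur = t
        if cur < clen:
            segments.append((cur, clen, new))
            chunks.append(arr[cur:clen])
        out = b"".join(c.tobytes() if isinstance(c, np.ndarray) else c
                       for c in chunks)
        sequences[chrom] = out.decode()

        seg_starts = np.array([s for s, _, _ in segments])
        seg_ends = np.array([e for _, e, _ in segments])
        seg_new = np.array([n for _, _, n in segments])

        def lift(pos: int) -> int | None:
            i = np.searchsorted(seg_starts, pos, "right") - 1
            if i < 0 or pos >= seg_ends[i]:
                return None
            return int(seg_new[i] + (pos - seg_starts[i]))

        def lift_iv(iv: GenomicInterval) -> GenomicInterval | None:
            a = lift(iv.start)
            b = lift(iv.end - 1)
            if a is None or b is None:
                return None
            return GenomicInterval(chrom, a, b + 1, iv.strand)

        acc_seq_assembly = GenomeAssembly(accession_id=leaf,
                                          sequences={chrom: sequences[chrom]})
        for g in chrom_genes:
            ev = gene_events.get(g.gene_id)
            if ev == "lost":
                ortho_rows.append((leaf, g.gene_id, None, "lost"))
                continue
            locus = lift_iv(g.locus)
            exons = [lift_iv(e) for e in g.exons]
            if locus is None or any(e is None for e in exons):
                continue
            gene_counter += 1
            gid = f"{leaf}.g{gene_counter:05d}"
            transcript = _transcript_from_assembly(acc_seq_assembly, exons,
                                                   g.locus.strand)
            protein = (str(Seq(transcript).translate()).rstrip("*")
                       if len(transcript) % 3 == 0 else None)
            new_gene_models.append(GeneModel(
                gene_id=gid, locus=locus, exons=exons, cds=exons,
                transcript_seq=transcript, protein_seq=protein))
            ortho_rows.append((leaf, g.gene_id, gid, "one_to_one"))
        for new_start, (g, copy_len) in dup_intervals.items():
            gene_counter += 1
            gid = f"{leaf}.g{gene_counter:05d}"
            rel = [(e.start - g.locus.start, e.end - g.locus.start)
                   for e in g.exons]
            locus = GenomicInterval(chrom, new_start, new_start + copy_len,
                                    g.locus.strand)
            exons = [GenomicInterval(chrom, new_start + a, new_start + b,
                                     g.locus.strand) for a, b in rel]
            transcript = _transcript_from_assembly(acc_seq_assembly, exons,
                                                   g.locus.strand)
            protein = (str(Seq(transcript).translate()).rstrip("*")
                       if len(transcript) % 3 == 0 else None)
            new_gene_models.append(GeneModel(
                gene_id=gid, locus=locus, exons=exons, cds=exons,
                transcript_seq=transcript, protein_seq=protein))
            ortho_rows.append((leaf, g.gene_id, gid, "tandem_dup"))

    new_gene_models.sort(key=lambda g: (g.locus.sequence_id, g.locus.start))
    assembly = GenomeAssembly(accession_id=leaf, sequences=sequences)
    return AccessionData(assembly=assembly, genes=new_gene_models,
                         elements_present=presence.copy())


# ---------------------------------------------------------------------------
# Assembly fragmentation
# ---------------------------------------------------------------------------

def fragment_assembly(genome: GenomeAssembly, config: SimConfig,
                      rng: np.random.Generator | None = None
                      ) -> tuple[GenomeAssembly, pd.DataFrame]:
    """Cut chromosomes into shuffled, partly reverse-complemented contigs.

    Contig sizes are drawn around ``assembly_n50_target_bp``; cut positions
    and orientations are returned for testing.  No sequence is gained or
    lost: restoring order and orientation reconstructs each chromosome.
    """
    rng = rng if rng is not None else _stage_rng(config.seed, 2)
    target = config.assembly_n50_target_bp
    contigs: list[tuple[str, str, int, int, str]] = []
    for chrom, seq in genome.sequences.items():
        n = len(seq)
        cuts = [0]
        while cuts[-1] < n:
            step = int(target * rng.uniform(0.7, 1.3))
            cuts.append(min(n, cuts[-1] + max(1, step)))
        for i, (a, b) in enumerate(zip(cuts, cuts[1:])):
            strand = "+" if rng.random() < 0.5 else "-"
            cseq = seq[a:b] if strand == "+" else revcomp(seq[a:b])
            contigs.append((f"{chrom}_ctg{i + 1:03d}", cseq, a, b, strand))
    order = rng.permutation(len(contigs))
    rows = []
    sequences = {}
    for j in order:
        cid, cseq, a, b, strand = contigs[j]
        sequences[cid] = cseq
        rows.append((cid, cid.rsplit("_ctg", 1)[0], a, b, strand))
    frag = pd.DataFrame(rows, columns=["contig_id", "chromosome",
                                       "ref_start", "ref_end", "strand"])
    assembly = GenomeAssembly(accession_id=genome.accession_id + "_contigs",
                              sequences=sequences,
                              anchored={cid: False for cid in sequences})
    return assembly, frag


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

def simulate_expression(genes: list[GeneModel], elements: list[GagElement],
                        truth: TruthTables, config: SimConfig,
                        rng: np.random.Generator | None = None
                        ) -> ExpressionMatrix:
    """Simulate the tissue-wide FPKM matrix.

    Log-scale group-mean model: every feature draws an independent mean per
    tissue group from Normal(2,1).  A Bernoulli(p_ripening_inducible) draw
    marks each element ripening-inducible; marked elements get a ripening
    mean of max(other groups) + ripening_delta, unmarked elements never
    have their maximum in the ripening group (the value is swapped away if
    drawn there), so truth labels match the realized profiles.  Each
    flanking gene of a ripening element is co-expressed with probability
    p_neighbor_coexpressed, sharing the element's group-mean profile up to
    Normal(0, noise_sd) jitter.  Per-sample values add Normal(0, noise_sd)
    on the log scale; FPKM = max(exp(x) - 0.01, 0).
    """
    rng = rng if rng is not None else _stage_rng(config.seed, 3)
    if config.ripening_group not in config.tissue_groups:
        raise ValueError("ripening group missing")
    groups = list(config.tissue_groups)
    rip_ix = groups.index(config.ripening_group)
    feature_ids = [e.element_id for e in elements] + [g.gene_id for g in genes]
    n_feat = len(feature_ids)
    means = rng.normal(2.0, 1.0, size=(n_feat, len(groups)))

    n_el = len(elements)
    ripening = rng.random(n_el) < config.p_ripening_inducible
    other_ix = [i for i in range(len(groups)) if i != rip_ix]
    for i in range(n_el):
        if ripening[i]:
            means[i, rip_ix] = means[i, other_ix].max() + config.ripening_delta
        elif means[i, rip_ix] >= means[i, other_ix].max():
            j = other_ix[int(np.argmax(means[i, other_ix]))]
            means[i, rip_ix], means[i, j] = means[i, j], means[i, rip_ix]
    truth.element_ripening = pd.Series(ripening,
                                       index=[e.element_id for e in elements])

    gene_row = {g.gene_id: n_el + k for k, g in enumerate(genes)}
    coexp_rows = []
    for i, el in enumerate(elements):
        if not ripening[i]:
            continue
        for gene, side, dist in nearest_flanking_genes(
                el.locus, genes, config.neighbor_window_bp):
            co = bool(rng.random() < config.p_neighbor_coexpressed)
            if co:
                means[gene_row[gene.gene_id]] = (
                    means[i] + rng.normal(0, config.expression_noise_sd,
                                          size=len(groups)))
            coexp_rows.append((el.element_id, gene.gene_id, side, dist, co))
    truth.neighbor_coexpressed = pd.DataFrame(
        coexp_rows, columns=["element_id", "gene_id", "side", "distance_bp",
                             "coexpressed"])

    sample_ids = []
    sample_groups = {}
    cols = []
    for gidx, grp in enumerate(groups):
        for s in range(config.samples_per_group):
            sid = f"{grp}_s{s + 1}"
            sample_ids.append(sid)
            sample_groups[sid] = grp
            logv = means[:, gidx] + rng.normal(
                0, config.expression_noise_sd, size=n_feat)
            cols.append(np.maximum(np.exp(logv) - 0.01, 0.0))
    values = pd.DataFrame(np.column_stack(cols), index=feature_ids,
                          columns=sample_ids)
    return ExpressionMatrix(values=values, sample_groups=sample_groups,
                            ripening_group=config.ripening_group)


# ---------------------------------------------------------------------------
# Top level
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig, with_expression: bool = True
                     ) -> SimDataset:
    """Run all simulation stages with per-stage substreams of the seed."""
    reference, genes, elements, truth = simulate_reference(config)
    accessions = derive_accessions(reference, genes, elements, config, truth)
    expression = (simulate_expression(genes, elements, truth, config)
                  if with_expression else None)
    return SimDataset(config=config, reference=reference, genes=genes,
                      elements=elements, accessions=accessions, truth=truth,
                      expression=expression)


def write_dataset(ds: SimDataset, outdir) -> None:
    """Emit FASTA/GFF3/BED/TSV/JSON artifacts for a simulated dataset."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(ds.reference, out / "reference.fa")
    write_gff3(ds.genes, ds.elements, out / "reference.gff3")
    write_bed_elements(ds.elements, out / "elements.bed")
    for name, acc in ds.accessions.items():
        if name == REFERENCE_ID:
            continue
        write_fasta(acc.assembly, out / f"{name}.fa")
        write_gff3(acc.genes, [], out / f"{name}.gff3")
    ds.truth.element_presence.to_csv(out / "truth_element_presence.tsv",
                                     sep="\t", index_label="element_id")
    ds.truth.ortho.to_csv(out / "truth_ortho.tsv", sep="\t", index=False)
    if len(ds.truth.element_ripening):
        ds.truth.element_ripening.rename("ripening").to_csv(
            out / "truth_element_ripening.tsv", sep="\t",
            index_label="element_id")
    if len(ds.truth.neighbor_coexpressed):
        ds.truth.neighbor_coexpressed.to_csv(
            out / "truth_neighbor_coexpressed.tsv", sep="\t", index=False)
    if ds.expression is not None:
        write_expression_tsv(ds.expression, out / "expression.tsv",
                             out / "sample_groups.tsv")
    cfg = dataclasses.asdict(ds.config)
    cfg["element_length_range"] = list(cfg["element_length_range"])
    cfg["tissue_groups"] = list(cfg["tissue_groups"])
    (out / "config.json").write_text(json.dumps(cfg, indent=2) + "\n")
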