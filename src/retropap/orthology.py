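"""Cross-genome gene-partner classification.

Reciprocal best hits on transcript (DNA 15-mer) and protein (4-mer)
similarity, confirmed by transcript-to-genome alignment, yield one-to-one
orthologue partners; pairs reciprocal in exactly one channel are
homologous partners; the remaining genes are classified as tandem
duplication CNVs, non-tandem CNV/PAP candidates, or unanchored.
Similarity is shared-k-mer containment (|shared| / |query k-mers|), the
desk-scale stand-in for bidirectional sequence search scores.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .align import DEFAULT_K, KmerIndex, _encode, _kmer_codes, best_matching_region
from .genome_model import GeneModel, GenomeAssembly

TRANSCRIPT_K = DEFAULT_K
PROTEIN_K = 4
MIN_CONTAINMENT_CROSS = 0.3
MIN_CONTAINMENT_WITHIN = 0.5
TANDEM_WINDOW_BP = 100_000
TANDEM_MAX_INTERVENING = 5

CATEGORIES = ("one_to_one", "homologue_partner", "tandem_dup_cnv",
              "non_tandem_cnv_pap", "unanchored", "no_call")


@dataclass
class PartnerCall:
    """Partnership category for one gene (optionally with its partner)."""

    gene_a: str
    gene_b: str | None
    category: str
    evidence: dict = field(default_factory=dict)


def _kmer_set(gene: GeneModel, channel: str) -> frozenset | None:
    if channel == "transcript":
        seq = gene.transcript_seq
        if not seq or len(seq) < TRANSCRIPT_K:
            return None
        codes, valid = _kmer_codes(_encode(seq), TRANSCRIPT_K)
        return frozenset(codes[valid].tolist())
    if channel == "protein":
        seq = gene.protein_seq
        if not seq or len(seq) < PROTEIN_K:
            return None
        return frozenset(seq[i:i + PROTEIN_K]
                         for i in range(len(seq) - PROTEIN_K + 1))
    raise ValueError(f"unknown channel {channel!r}")


def similarity_best_hits(genes_a: list[GeneModel], genes_b: list[GeneModel],
                         channel: str,
                         min_containment: float = MIN_CONTAINMENT_CROSS,
                         exclude_same_id: bool = False
                         ) -> dict[str, tuple[str, float]]:
    """Directed best hit of every query gene in *genes_a* against *genes_b*.

    Similarity is k-mer containment of the query's k-mer set in the
    subject's.  Ties break deterministically: higher containment, longer
    subject, lexicographic subject id.  Hits below *min_containment* are
    dropped.
    """
    subj_sets = {}
    subj_len = {}
    posting: dict[object, list[str]] = {}
    for g in genes_b:
        ks = _kmer_set(g, channel)
        if ks is None:
            continue
        subj_sets[g.gene_id] = ks
        subj_len[g.gene_id] = len(g.transcript_seq if channel == "transcript"
                                  else g.protein_seq)
        for kmer in ks:
            posting.setdefault(kmer, []).append(g.gene_id)

    out: dict[str, tuple[str, float]] = {}
    for g in genes_a:
        qk = _kmer_set(g, channel)
        if not qk:
            continue
        shared: Counter[str] = Counter()
        for kmer in qk:
            for sid in posting.get(kmer, ()):
                shared[sid] += 1
        best = None
        for sid, n in shared.items():
            if exclude_same_id and sid == g.gene_id:
                continue
            cont = n / len(qk)
            if cont < min_containment:
                continue
            key = (-cont, -subj_len[sid], sid)
            if best is None or key < best[0]:
                best = (key, sid, cont)
        if best is not None:
            out[g.gene_id] = (best[1], best[2])
    return out


def _reciprocal(fwd: dict[str, tuple[str, float]],
                rev: dict[str, tuple[str, float]]) -> dict[str, str]:
    return {a: b for a, (b, _) in fwd.items()
            if rev.get(b, (None,))[0] == a}


def call_one_to_one(genes_a: list[GeneModel], genes_b: list[GeneModel],
                    genome_b: GenomeAssembly,
                    index_b: KmerIndex | None = None,
                    min_containment: float = MIN_CONTAINMENT_CROSS
                    ) -> list[PartnerCall]:
    """One-to-one / homologue-partner calls for every gene in *genes_a*.

    A pair is one-to-one iff it is reciprocal best in BOTH the transcript
    and the protein channel AND the query transcript's best-matching
    genomic region in genome B overlaps the partner's locus (>= 1 bp) —
    the transcript-to-genome confirmation.  Pairs reciprocal in exactly
    one channel are homologous partners.  One-to-one calls form a
    bijection by construction.
    """
    if index_b is None:
        index_b = KmerIndex(genome_b, k=DEFAULT_K)
    bt_ab = similarity_best_hits(genes_a, genes_b, "transcript", min_containment)
    bt_ba = similarity_best_hits(genes_b, genes_a, "transcript", min_containment)
    bp_ab = similarity_best_hits(genes_a, genes_b, "protein", min_containment)
    bp_ba = similarity_best_hits(genes_b, genes_a, "protein", min_containment)
    rec_t = _reciprocal(bt_ab, bt_ba)
    rec_p = _reciprocal(bp_ab, bp_ba)
    b_locus = {g.gene_id: g.locus for g in genes_b}

    calls = []
    for g in genes_a:
        a = g.gene_id
        tb = rec_t.get(a)
        pb = rec_p.get(a)
        ev = {"containment_t": bt_ab.get(a, (None, float("nan")))[1],
              "containment_p": bp_ab.get(a, (None, float("nan")))[1],
              "overlap_bp": 0}
        if tb is not None and tb == pb:
            hit = best_matching_region(g.transcript_seq, None, index=index_b)
            if hit is not None:
                iv = hit[0]
                loc = b_locus[tb]
                overlap = (min(iv.end, loc.end) - max(iv.start, loc.start)
                           if iv.sequence_id == loc.sequence_id else 0)
                ev["overlap_bp"] = max(0, overlap)
                if ev["overlap_bp"] >= 1:
                    calls.append(PartnerCall(a, tb, "one_to_one", ev))
                    continue
            calls.append(PartnerCall(a, tb, "homologue_partner", ev))
        elif tb is not None or pb is not None:
            calls.append(PartnerCall(a, tb if tb is not None else pb,
                                     "homologue_partner", ev))
        else:
            calls.append(PartnerCall(a, None, "no_call", ev))
    return calls


def classify_cnv_pap(calls: list[PartnerCall], genes_a: list[GeneModel],
                     genes_b: list[GeneModel], genome_a: GenomeAssembly,
                     genome_b: GenomeAssembly,
                     index_b: KmerIndex | None = None,
                     tandem_window_bp: int = TANDEM_WINDOW_BP,
                     tandem_max_intervening: int = TANDEM_MAX_INTERVENING
                     ) -> list[PartnerCall]:
    """Reclassify genes without a one-to-one partner (CNV/PAP candidates).

    A candidate becomes ``tandem_dup_cnv`` when its best within-genome
    homologue (containment >= 0.5) lies on the same sequence within the
    tandem window with at most ``tandem_max_intervening`` genes between;
    ``non_tandem_cnv_pap`` when it has homologues elsewhere or no genomic
    hit in the other genome at all (pure PAP); ``unanchored`` when it
    sits on an unanchored sequence.  Returns the full updated call list.
    """
    if index_b is None:
        index_b = KmerIndex(genome_b, k=DEFAULT_K)
    by_id = {g.gene_id: g for g in genes_a}
    order: dict[str, list[GeneModel]] = {}
    for g in sorted(genes_a, key=lambda g: (g.locus.sequence_id, g.locus.start)):
        order.setdefault(g.locus.sequence_id, []).append(g)
    rank = {g.gene_id: i for seq in order.values() for i, g in enumerate(seq)}
    cross = similarity_best_hits(
        genes_a, genes_b, "transcript", MIN_CONTAINMENT_CROSS)
    # within-genome homologue search excludes the trivial self-hit
    within_other = similarity_best_hits(
        genes_a, genes_a, "transcript", MIN_CONTAINMENT_WITHIN,
        exclude_same_id=True)

    out = []
    for call in calls:
        if call.category != "no_call":
            out.append(call)
            continue
        g = by_id[call.gene_a]
        ev = dict(call.evidence)
        if not genome_a.anchored.get(g.locus.sequence_id, True):
            out.append(PartnerCall(g.gene_id, None, "unanchored", ev))
            continue
        wh = within_other.get(g.gene_id)
        if wh is not None:
            partner = by_id[wh[0]]
            same_seq = partner.locus.sequence_id == g.locus.sequence_id
            dist = (abs(partner.locus.start - g.locus.start) if same_seq
                    else None)
            intervening = (abs(rank[partner.gene_id] - rank[g.gene_id]) - 1
                           if same_seq else None)
            ev.update(within_homologue=wh[0], within_containment=wh[1])
            if (same_seq and dist <= tandem_window_bp
                    and intervening <= tandem_max_intervening):
                out.append(PartnerCall(g.gene_id, wh[0], "tandem_dup_cnv", ev))
                continue
            out.append(PartnerCall(g.gene_id, wh[0], "non_tandem_cnv_pap", ev))
            continue
        if g.gene_id in cross:
            ev.update(cross_homologue=cross[g.gene_id][0])
            out.append(PartnerCall(g.gene_id, None, "non_tandem_cnv_pap", ev))
            continue
        hit = (best_matching_region(g.transcript_seq, None, index=index_b)
               if g.transcript_seq else None)
        if hit is None:
            ev["no_genomic_hit"] = True
            out.append(PartnerCall(g.gene_id, None, "non_tandem_cnv_pap", ev))
        else:
            out.append(PartnerCall(g.gene_id, None, "no_call", ev))
    return out


def classify_gene_partners(genes_a: list[GeneModel], genes_b: list[GeneModel],
                           genome_a: GenomeAssembly, genome_b: GenomeAssembly,
                           **kwargs) -> list[PartnerCall]:
    """Full A-side partner classification against genome/gene set B."""
    index_b = KmerIndex(genome_b, k=DEFAULT_K)
    calls = call_one_to_one(genes_a, genes_b, genome_b, index_b=index_b)
    return classify_cnv_pap(calls, genes_a, genes_b, genome_a, genome_b,
                            index_b=index_b, **kwargs)


def assign_consensus_ids(calls: list[PartnerCall],
                         suffix: str = ".jh1") -> dict[str, str]:
    """Partner-derived consensus IDs for one-to-one orthologues.

    Each one-to-one gene receives ``<partner_id><suffix>`` (the consensus
    nomenclature); all other genes keep their native IDs.  The mapping is
    injective and idempotent; suffix collisions are an error.
    """
    mapping: dict[str, str] = {}
    for call in calls:
        if call.category == "one_to_one" and call.gene_b is not None:
            mapping[call.gene_a] = call.gene_b + suffix
        else:
            mapping[call.gene_a] = call.gene_a
    values = list(mapping.values())
    if len(set(values)) != len(values):
        dupes = sorted({v for v in values if values.count(v) > 1})
        raise ValueError(f"consensus-id collision: {dupes[:5]}")
    return mapping
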