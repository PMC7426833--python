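"""Gene-partner classification: best hits, one-to-one calls, CNV/PAP."""

import dataclasses

import numpy as np
import pytest

from retropap.genome_model import GeneModel, GenomeAssembly, GenomicInterval
from retropap.orthology import (
    PartnerCall,
    assign_consensus_ids,
    call_one_to_one,
    classify_cnv_pap,
    classify_gene_partners,
    similarity_best_hits,
)
from retropap.synthetic import REFERENCE_ID

from conftest import rand_dna


_AA = "ACDEFGHIKLMNPQRSTVWY"


def _gene(gid, seq_id, start, transcript, protein=None, strand="+"):
    if protein is None:  # deterministic per-codon pseudo-translation
        protein = "".join(
            _AA[sum(ord(c) for c in transcript[i:i + 3]) % 20]
            for i in range(0, len(transcript) - 2, 3))
    iv = GenomicInterval(seq_id, start, start + len(transcript), strand)
    return GeneModel(gene_id=gid, locus=iv, exons=[iv], cds=[iv],
                     transcript_seq=transcript, protein_seq=protein)


def _genome_for(genes, length=200_000, seed=0, accession="G"):
    rng = np.random.default_rng(seed)
    arrs = {}
    for g in genes:
        sid = g.locus.sequence_id
        if sid not in arrs:
            arrs[sid] = list(rand_dna(rng, length))
        arrs[sid][g.locus.start:g.locus.end] = list(g.transcript_seq)
    return GenomeAssembly(accession, {k: "".join(v) for k, v in arrs.items()})


def _mutate(seq, rng, n):
    out = list(seq)
    for p in rng.choice(len(seq), size=n, replace=False):
        out[p] = "ACGT"[("ACGT".index(out[p]) + 1) % 4]
    return "".join(out)


class TestSimilarityBestHits:
    def test_identical_copy_has_containment_one(self, rng):
        a = [_gene(f"a{i}", "c1", 1000 + 3000 * i, rand_dna(rng, 900))
             for i in range(4)]
        b = [dataclasses.replace(g, gene_id=g.gene_id.replace("a", "b"))
             for g in a]
        hits = similarity_best_hits(a, b, "transcript")
        assert all(hits[f"a{i}"] == (f"b{i}", 1.0) for i in range(4))

    def test_random_sequence_has_no_hit(self, rng):
        a = [_gene("a0", "c1", 1000, rand_dna(rng, 900))]
        b = [_gene("b0", "c1", 1000, rand_dna(rng, 900))]
        assert similarity_best_hits(a, b, "transcript") == {}

    def test_containment_matches_brute_force_kmer_ratio(self, rng):
        """Containment of a 1%-mutated subject equals the exact shared
        15-mer fraction computed by direct set intersection."""
        t = rand_dna(rng, 1500)
        t_mut = _mutate(t, rng, 15)
        a = [_gene("a0", "c1", 1000, t)]
        b = [_gene("b0", "c1", 1000, t_mut)]
        hits = similarity_best_hits(a, b, "transcript")
        qk = {t[i:i + 15] for i in range(len(t) - 14)}
        sk = {t_mut[i:i + 15] for i in range(len(t_mut) - 14)}
        assert hits["a0"][1] == pytest.approx(len(qk & sk) / len(qk))

    def test_empty_gene_set(self):
        assert similarity_best_hits([], [], "transcript") == {}


class TestCallOneToOne:
    def test_unique_genes_are_one_to_one(self, rng):
        a = [_gene(f"a{i}", "c1", 1000 + 4000 * i, rand_dna(rng, 1200))
             for i in range(3)]
        b = [dataclasses.replace(g, gene_id=g.gene_id.replace("a", "b"))
             for g in a]
        genome_b = _genome_for(b, seed=1)
        calls = call_one_to_one(a, b, genome_b)
        assert all(c.category == "one_to_one" for c in calls)
        assert [c.gene_b for c in calls] == ["b0", "b1", "b2"]

    def test_one_to_one_calls_form_bijection(self, small_sim):
        acc = small_sim.accessions["ACC03"]
        calls = call_one_to_one(acc.genes, small_sim.genes,
                                small_sim.reference)
        partners = [c.gene_b for c in calls if c.category == "one_to_one"]
        assert len(partners) == len(set(partners))

    def test_duplicated_subject_resolves_by_tie_break(self, rng):
        """Identical duplicate copies in B: the query pairs with the
        deterministic tie-break winner; the other copy stays unpaired for
        CNV classification (hand-enumerated 3-gene similarity table)."""
        t = rand_dna(rng, 1200)
        a = [_gene("a0", "c1", 1000, t)]
        b = [_gene("b1", "c1", 1000, t), _gene("b2", "c1", 2400, t)]
        genome_b = _genome_for(b, seed=2)
        # containments are all 1.0 and lengths equal -> lexicographic: b1
        calls = call_one_to_one(a, b, genome_b)
        assert calls[0].category == "one_to_one"
        assert calls[0].gene_b == "b1"
        rev = call_one_to_one(b, a, _genome_for(a, seed=3))
        cats = {c.gene_a: c.category for c in rev}
        assert cats["b1"] == "one_to_one"
        assert cats["b2"] != "one_to_one"

    def test_deleted_gene_gets_no_call(self, rng):
        a = [_gene("a0", "c1", 1000, rand_dna(rng, 1200)),
             _gene("a1", "c1", 5000, rand_dna(rng, 1200))]
        b = [dataclasses.replace(a[0], gene_id="b0")]
        calls = call_one_to_one(a, b, _genome_for(b, seed=4))
        cats = {c.gene_a: c.category for c in calls}
        assert cats == {"a0": "one_to_one", "a1": "no_call"}


class TestClassifyCnvPap:
    def test_adjacent_duplicate_is_tandem(self, rng):
        t = rand_dna(rng, 1200)
        other = rand_dna(rng, 1200)
        a = [_gene("a1", "c1", 1000, t), _gene("a2", "c1", 2400, t),
             _gene("a3", "c1", 9000, other)]
        b = [_gene("b1", "c1", 1000, t), _gene("b3", "c1", 9000, other)]
        genome_a, genome_b = _genome_for(a, seed=5), _genome_for(b, seed=6)
        calls = classify_gene_partners(a, b, genome_a, genome_b)
        cats = {c.gene_a: c.category for c in calls}
        assert cats["a3"] == "one_to_one"
        assert sorted([cats["a1"], cats["a2"]]) == ["one_to_one",
                                                    "tandem_dup_cnv"]

    def test_distant_duplicate_is_non_tandem(self, rng):
        t = rand_dna(rng, 1200)
        a = [_gene("a1", "c1", 1000, t), _gene("a2", "c2", 1000, t)]
        b = [_gene("b1", "c1", 1000, t)]
        calls = classify_gene_partners(a, b, _genome_for(a, seed=7),
                                       _genome_for(b, seed=8))
        cats = {c.gene_a: c.category for c in calls}
        assert "non_tandem_cnv_pap" in cats.values()

    def test_fully_deleted_gene_is_pap_with_no_genomic_hit(self, rng):
        a = [_gene("a1", "c1", 1000, rand_dna(rng, 1200)),
             _gene("a2", "c1", 9000, rand_dna(rng, 1200))]
        b = [dataclasses.replace(a[0], gene_id="b1")]
        calls = classify_gene_partners(a, b, _genome_for(a, seed=9),
                                       _genome_for(b, seed=10))
        byid = {c.gene_a: c for c in calls}
        assert byid["a2"].category == "non_tandem_cnv_pap"
        assert byid["a2"].evidence.get("no_genomic_hit") is True

    def test_gene_on_unanchored_contig(self, rng):
        a = [_gene("a1", "ctg7", 1000, rand_dna(rng, 1200))]
        genome_a = _genome_for(a, length=5000, seed=11)
        genome_a.anchored["ctg7"] = False
        b = [_gene("b1", "c1", 1000, rand_dna(rng, 1200))]
        calls = classify_gene_partners(a, b, genome_a,
                                       _genome_for(b, seed=12))
        assert calls[0].category == "unanchored"

    def test_every_gene_gets_exactly_one_category(self, small_sim):
        acc = small_sim.accessions["ACC03"]
        calls = classify_gene_partners(acc.genes, small_sim.genes,
                                       acc.assembly, small_sim.reference)
        assert sorted(c.gene_a for c in calls) == \
            sorted(g.gene_id for g in acc.genes)


class TestConsensusIds:
    def test_partner_derived_suffix(self):
        calls = [PartnerCall("MELO.jh000001.1", "MELO3C019694", "one_to_one"),
                 PartnerCall("MELO.jh102711.1", None, "non_tandem_cnv_pap")]
        mapping = assign_consensus_ids(calls)
        assert mapping["MELO.jh000001.1"] == "MELO3C019694.jh1"
        assert mapping["MELO.jh102711.1"] == "MELO.jh102711.1"

    def test_idempotent(self):
        calls = [PartnerCall("a1", "p1", "one_to_one"),
                 PartnerCall("a2", None, "no_call")]
        assert assign_consensus_ids(calls) == assign_consensus_ids(calls)

    def test_collision_errors(self):
        calls = [PartnerCall("a1", "p1", "one_to_one"),
                 PartnerCall("a2", "p1", "one_to_one")]
        with pytest.raises(ValueError, match="collision"):
            assign_consensus_ids(calls)
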