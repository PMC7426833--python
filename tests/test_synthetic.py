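"""Simulator: determinism, conservation laws, statistical calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from retropap.expression import pearson_r
from retropap.genome_model import revcomp
from retropap.synthetic import (
    REFERENCE_ID,
    SimConfig,
    TruthTables,
    _presence_by_leaf,
    _stage_rng,
    derive_accessions,
    fragment_assembly,
    simulate_dataset,
    simulate_expression,
    simulate_reference,
)

from conftest import SMALL_TREE


class TestSimulateReference:
    def test_exact_feature_counts(self, small_sim, small_config):
        assert len(small_sim.genes) == small_config.n_genes
        assert len(small_sim.elements) == small_config.n_elements

    def test_features_do_not_overlap(self, small_sim):
        ivs = sorted([g.locus for g in small_sim.genes]
                     + [e.locus for e in small_sim.elements],
                     key=lambda iv: (iv.sequence_id, iv.start))
        for a, b in zip(ivs, ivs[1:]):
            assert (a.sequence_id != b.sequence_id) or (a.end <= b.start)

    def test_no_elements_config(self):
        cfg = SimConfig(seed=2, n_chromosomes=1, chromosome_length_bp=60_000,
                        n_genes=10, n_elements=0, accession_tree=SMALL_TREE)
        asm, genes, elements, truth = simulate_reference(cfg)
        assert elements == []
        assert truth.element_presence.empty

    def test_infeasible_packing_is_reported(self):
        cfg = SimConfig(seed=2, n_chromosomes=1, chromosome_length_bp=10_000,
                        n_genes=50, n_elements=5, accession_tree=SMALL_TREE)
        with pytest.raises(ValueError, match="infeasible packing"):
            simulate_reference(cfg)

    def test_deterministic_for_fixed_seed(self, small_config, small_sim):
        again = simulate_dataset(small_config)
        for name, acc in small_sim.accessions.items():
            assert acc.assembly.sequences == again.accessions[name].assembly.sequences
        assert small_sim.expression.values.equals(again.expression.values)
        assert small_sim.truth.element_presence.equals(
            again.truth.element_presence)


class TestDeriveAccessions:
    def test_no_mutation_no_flip_reproduces_reference(self):
        cfg = SimConfig(seed=3, n_chromosomes=1, chromosome_length_bp=80_000,
                        n_genes=12, n_elements=3, accession_tree=SMALL_TREE,
                        pap_flip_prob_per_branch=0.0, snp_rate=0.0,
                        small_indel_rate=0.0, tandem_dup_prob=0.0,
                        gene_loss_prob=0.0)
        ds = simulate_dataset(cfg, with_expression=False)
        assert ds.truth.element_presence.all().all()
        for name, acc in ds.accessions.items():
            assert acc.assembly.sequences == ds.reference.sequences

    def test_reference_column_always_present(self, small_sim):
        assert small_sim.truth.element_presence[REFERENCE_ID].all()

    def test_sister_leaves_share_more_presence_states(self):
        """Sister accessions (shared flip history) agree on more element
        presence states than either does with the most distant leaf,
        averaged over seeds."""
        cfg = SimConfig(seed=0)
        ids = [f"e{i}" for i in range(40)]
        sis = far = 0.0
        n_seeds = 25
        for s in range(n_seeds):
            leaves, _ = _presence_by_leaf(cfg, ids, np.random.default_rng(s))
            sis += (leaves["ACC08"] == leaves["ACC09"]).mean()
            far += (leaves["ACC08"] == leaves["ACC01"]).mean()
        assert sis / n_seeds > far / n_seeds

    def test_branch_flip_rate_matches_configuration(self):
        """Empirical per-branch flip frequency on unit branches lies within
        3 SE of the configured probability (50 seeds)."""
        cfg = SimConfig(seed=0)
        ids = [f"e{i}" for i in range(40)]
        flips = trials = 0
        for s in range(50):
            _, df = _presence_by_leaf(cfg, ids, np.random.default_rng(1000 + s))
            unit = df[np.isclose(df["length"], 1.0)]
            flips += unit["n_flips"].sum()
            trials += (unit["n_elements"]).sum()
        p = cfg.pap_flip_prob_per_branch
        se = (p * (1 - p) / trials) ** 0.5
        assert abs(flips / trials - p) < 3 * se

    def test_truth_records_every_gene_event_once(self, small_sim, small_config):
        truth = small_sim.truth.ortho
        for acc in small_sim.accessions:
            if acc == REFERENCE_ID:
                continue
            sub = truth[truth.accession == acc]
            # every reference gene appears exactly once as one_to_one or lost
            main = sub[sub.event.isin(["one_to_one", "lost"])]
            assert sorted(main.ref_gene) == sorted(
                g.gene_id for g in small_sim.genes)


class TestFragmentAssembly:
    def test_conservation_and_reconstruction(self, small_sim, small_config):
        frag, truth = fragment_assembly(small_sim.reference, small_config)
        assert frag.total_bp() == small_sim.reference.total_bp()
        for chrom, seq in small_sim.reference.sequences.items():
            rows = truth[truth.chromosome == chrom].sort_values("ref_start")
            rebuilt = "".join(
                frag.sequences[r.contig_id] if r.strand == "+"
                else revcomp(frag.sequences[r.contig_id])
                for r in rows.itertuples())
            assert rebuilt == seq

    def test_realized_n50_near_target(self):
        cfg = SimConfig(seed=9, n_chromosomes=2, chromosome_length_bp=400_000,
                        n_genes=20, n_elements=4, accession_tree=SMALL_TREE,
                        assembly_n50_target_bp=50_000)
        ds = simulate_dataset(cfg, with_expression=False)
        frag, _ = fragment_assembly(ds.reference, cfg)
        lengths = sorted((len(s) for s in frag.sequences.values()),
                         reverse=True)
        half = sum(lengths) / 2
        acc = 0
        for n50 in lengths:
            acc += n50
            if acc >= half:
                break
        assert 0.5 * cfg.assembly_n50_target_bp <= n50 \
            <= 1.5 * cfg.assembly_n50_target_bp

    def test_target_above_length_gives_one_contig_per_chromosome(self,
                                                                 small_sim):
        cfg = SimConfig(seed=9, assembly_n50_target_bp=10_000_000,
                        accession_tree=SMALL_TREE)
        frag, _ = fragment_assembly(small_sim.reference, cfg)
        assert len(frag.sequences) == len(small_sim.reference.sequences)


class TestSimulateExpression:
    def test_coexpressed_neighbour_correlates_at_low_noise(self, small_sim,
                                                           small_config):
        cfg = SimConfig(**{**small_config.__dict__,
                           "expression_noise_sd": 1e-6})
        truth = TruthTables()
        em = simulate_expression(small_sim.genes, small_sim.elements, truth,
                                 cfg, _stage_rng(cfg.seed, 3))
        co = truth.neighbor_coexpressed.query("coexpressed")
        assert len(co) > 0
        for r in co.itertuples():
            rr = pearson_r(em.values.loc[r.element_id],
                           em.values.loc[r.gene_id])
            assert rr > 0.99

    def test_zero_ripening_probability_yields_no_inducible_elements(
            self, small_sim, small_config):
        from retropap.expression import call_ripening_inducible
        cfg = SimConfig(**{**small_config.__dict__,
                           "p_ripening_inducible": 0.0})
        truth = TruthTables()
        em = simulate_expression(small_sim.genes, small_sim.elements, truth,
                                 cfg, _stage_rng(cfg.seed, 3))
        assert not truth.element_ripening.any()
        rip = call_ripening_inducible(em)
        el_ids = [e.element_id for e in small_sim.elements]
        assert not rip.loc[el_ids, "is_ripening_inducible"].any()

    def test_ripening_truth_fraction_within_binomial_ci(self):
        """With 40 elements at the configured 38.6% rate, the realized
        truth fraction lies inside the exact binomial 99% CI."""
        ds = simulate_dataset(SimConfig(seed=1))
        n = len(ds.truth.element_ripening)
        k = int(ds.truth.element_ripening.sum())
        lo = binom.ppf(0.005, n, 0.386)
        hi = binom.ppf(0.995, n, 0.386)
        assert lo <= k <= hi

    def test_missing_ripening_group_errors(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, tissue_groups=("leaf", "root"),
                      ripening_group="ripening_fruit")
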