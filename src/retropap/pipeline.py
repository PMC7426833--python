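"""End-to-end orchestration of the synthetic PAP experiment.

Runs simulate -> orthology -> PAP genotyping -> expression -> enrichment
on one synthetic dataset, writes every stage table plus a JSON manifest
echoing all parameters, and reports recovered quantities against the
simulation's ground truth (PAP concordance, orthologue recall/precision,
ripening and neighbour co-expression fractions, planted-clade recovery).
Fully deterministic under a fixed seed: re-running a configuration
reproduces the run directory byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .enrichment import enrich
from .expression import (
    call_ripening_inducible,
    filter_expressed,
    neighbor_coexpression,
)
from .genome_model import GAG_TERM, read_newick, write_newick
from .orthology import assign_consensus_ids, classify_gene_partners
from .pap import build_pap_matrix, cluster_accessions
from .synthetic import REFERENCE_ID, SimConfig, simulate_dataset, write_dataset

log = logging.getLogger("retropap")


@dataclass
class RunConfig:
    """Seed, stage toggles and every stage parameter of one pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    run_orthology: bool = True
    run_pap: bool = True
    run_expression: bool = True
    run_enrichment: bool = True
    ortho_accession: str | None = None  # default: first non-reference leaf
    flank_bp: int = 50_000
    present_min: float = 0.8
    absent_max: float = 0.2
    linkage: str = "complete"
    metric: str = "euclidean"
    min_fpkm: float = 0.1
    filter_mode: str = "any"
    r_cutoff: float = 0.8
    consensus_suffix: str = ".jh1"
    n_generic_terms: int = 30

    @property
    def seed(self) -> int:
        return self.sim.seed


def most_distant_leaf(sim: SimConfig) -> str | None:
    """Accession farthest from the reference on the tree — the natural
    partner for the pairwise orthology/CNV comparison."""
    tree = read_newick(sim.accession_tree)

    def depth(tip) -> float:
        d, node = 0.0, tip
        while node.parent is not None:
            d += node.length or 0.0
            node = node.parent
        return d

    tips = [t for t in tree.tips() if t.name != REFERENCE_ID]
    if not tips:
        return None
    return max(tips, key=lambda t: (depth(t), t.name)).name


def planted_clade(sim: SimConfig) -> list[str] | None:
    """Leaf names of the smallest tree clade (>= 3 tips) holding the
    reference — the analog of the same-origin cultivar cluster."""
    tree = read_newick(sim.accession_tree)
    node = next((t for t in tree.tips() if t.name == REFERENCE_ID), None)
    if node is None:
        return None
    while node.parent is not None and node.count(tips=True) < 3:
        node = node.parent
    names = sorted(t.name for t in node.tips())
    return names if 3 <= len(names) < len(list(tree.tips())) else None


def _term_table(ds, rng: np.random.Generator,
                n_generic: int) -> dict[str, set[str]]:
    """Deterministic term assignments: every element carries the Gag-domain
    term; genes draw 1-3 generic terms from a fixed vocabulary."""
    vocab = [f"IPR9{i:05d}" for i in range(n_generic)]
    table: dict[str, set[str]] = {}
    for g in ds.genes:
        k = int(rng.integers(1, 4))
        table[g.gene_id] = set(rng.choice(vocab, size=k, replace=False))
    for e in ds.elements:
        table[e.element_id] = set(e.term_ids) | {
            str(rng.choice(vocab))}
    return table


def run_end_to_end(config: RunConfig, outdir) -> Path:
    """Execute all enabled stages; returns the run directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "retropap",
        "version": __version__,
        "seed": config.seed,
        "parameters": _config_dict(config),
        "stages": {},
    }

    log.info("stage simulate: seed=%d", config.seed)
    ds = simulate_dataset(config.sim, with_expression=config.run_expression)
    write_dataset(ds, out / "simulated")
    manifest["stages"]["simulate"] = {
        "n_genes": len(ds.genes), "n_elements": len(ds.elements),
        "n_accessions": len(ds.accessions)}
    report: list[str] = [f"retropap end-to-end run (seed {config.seed})", ""]

    non_ref = [a for a in ds.accessions if a != REFERENCE_ID]
    default_acc = most_distant_leaf(config.sim)
    if config.run_orthology and non_ref:
        acc_name = config.ortho_accession or default_acc or non_ref[0]
        acc = ds.accessions[acc_name]
        log.info("stage orthology: %s vs %s (%d vs %d genes)", acc_name,
                 REFERENCE_ID, len(acc.genes), len(ds.genes))
        calls = classify_gene_partners(acc.genes, ds.genes, acc.assembly,
                                       ds.reference)
        rows = [(c.gene_a, c.gene_b or "", c.category,
                 c.evidence.get("containment_t"),
                 c.evidence.get("containment_p"),
                 c.evidence.get("overlap_bp")) for c in calls]
        partners = pd.DataFrame(rows, columns=[
            "gene_a", "gene_b", "category", "containment_t", "containment_p",
            "overlap_bp"])
        partners.to_csv(out / "partner_calls.tsv", sep="\t", index=False)
        mapping = assign_consensus_ids(calls, suffix=config.consensus_suffix)
        pd.Series(mapping, name="consensus_id").to_csv(
            out / "consensus_ids.tsv", sep="\t", index_label="gene_id")
        counts = partners.groupby("category").size()
        manifest["stages"]["orthology"] = {"accession": acc_name,
                                           **counts.to_dict()}
        truth = ds.truth.ortho.query("accession == @acc_name")
        o2o = dict(zip(partners.query("category=='one_to_one'").gene_a,
                       partners.query("category=='one_to_one'").gene_b))
        t_pairs = truth.query("event=='one_to_one'")
        recall_n = sum(o2o.get(r.acc_gene) == r.ref_gene
                       for r in t_pairs.itertuples())
        homolog_of = {}
        for r in truth.itertuples():
            if r.acc_gene:
                homolog_of[r.acc_gene] = r.ref_gene
        false_o2o = sum(1 for a, b in o2o.items()
                        if homolog_of.get(a) not in (None, b))
        report += [
            f"orthology ({acc_name} vs {REFERENCE_ID}):",
            f"  one-to-one recall: {recall_n}/{len(t_pairs)} "
            f"({100 * recall_n / max(1, len(t_pairs)):.1f}%)",
            f"  false one-to-one pairs: {false_o2o}",
            f"  categories: {counts.to_dict()}", ""]
        manifest["stages"]["orthology"]["recall"] = recall_n / max(1, len(t_pairs))
        manifest["stages"]["orthology"]["false_one_to_one"] = false_o2o

    pap_matrix = None
    if config.run_pap and non_ref:
        log.info("stage pap: %d elements x %d accessions", len(ds.elements),
                 len(non_ref))
        targets = {a: ds.accessions[a].assembly for a in non_ref}
        pap_matrix = build_pap_matrix(ds.elements, ds.reference, targets,
                                      flank_bp=config.flank_bp,
                                      present_min=config.present_min,
                                      absent_max=config.absent_max)
        pap_matrix.ratio.round(6).to_csv(out / "pap_ratio.tsv", sep="\t",
                                         index_label="element_id")
        pap_matrix.call.to_csv(out / "pap_call.tsv", sep="\t",
                               index_label="element_id")
        pap_matrix.presence_counts().rename("n_present").to_csv(
            out / "pap_presence_counts.tsv", sep="\t",
            index_label="accession")
        tree = cluster_accessions(pap_matrix, method=config.linkage,
                                  metric=config.metric)
        (out / "pap_dendrogram.nwk").write_text(write_newick(tree) + "\n")
        truth_p = ds.truth.element_presence
        concord = 0
        signerr = 0
        total = truth_p.size
        for acc_name in truth_p.columns:
            for el in truth_p.index:
                t, c = truth_p.loc[el, acc_name], pap_matrix.call.loc[el, acc_name]
                if (t and c == "present") or (not t and c == "absent"):
                    concord += 1
                elif (t and c == "absent") or (not t and c == "present"):
                    signerr += 1
        clade = planted_clade(config.sim)
        clade_ok = None
        if clade:
            lca = tree.lca(clade)
            clade_ok = sorted(t.name for t in lca.tips()) == clade
        manifest["stages"]["pap"] = {
            "cells": int(total), "concordant": concord,
            "sign_errors": signerr, "clade_recovered": clade_ok}
        report += [
            "pap genotyping:",
            f"  call/truth concordance: {concord}/{total} "
            f"({100 * concord / max(1, total):.2f}%)",
            f"  present<->absent sign errors: {signerr}",
            f"  planted clade recovered: {clade_ok}", ""]

    ripening_ids: set[str] = set()
    if config.run_expression and ds.expression is not None:
        log.info("stage expression: %d features x %d samples",
                 *ds.expression.values.shape)
        filtered = filter_expressed(ds.expression, min_fpkm=config.min_fpkm,
                                    mode=config.filter_mode)
        rip = call_ripening_inducible(filtered)
        rip.round(6).to_csv(out / "ripening_calls.tsv", sep="\t",
                            index_label="feature_id")
        el_ids = [e.element_id for e in ds.elements]
        rip_el = rip.loc[rip.index.intersection(el_ids)]
        ripening_ids = set(rip_el.index[rip_el["is_ripening_inducible"]])
        nco = neighbor_coexpression(ds.elements, ds.genes, filtered,
                                    window_bp=config.sim.neighbor_window_bp,
                                    r_cutoff=config.r_cutoff,
                                    ripening_ids=ripening_ids)
        nco.pairs.round(6).to_csv(out / "neighbor_pairs.tsv", sep="\t",
                                  index=False)
        nco.histogram.to_csv(out / "neighbor_histogram.tsv", sep="\t",
                             index=False)
        frac_rip = nco.fractions.get("ripening_elements", float("nan"))
        manifest["stages"]["expression"] = {
            "n_filtered": int(filtered.values.shape[0]),
            "n_ripening_elements": len(ripening_ids),
            "fractions": {k: None if pd.isna(v) else round(v, 6)
                          for k, v in nco.fractions.items()},
            "denominators": nco.denominators}
        n_el = max(1, len(el_ids))
        report += [
            "expression:",
            f"  ripening-inducible elements: {len(ripening_ids)}/{len(el_ids)}"
            f" ({100 * len(ripening_ids) / n_el:.1f}%; simulated "
            f"p={config.sim.p_ripening_inducible})",
            f"  neighbour co-expression (r > {config.r_cutoff}): "
            + ", ".join(f"{k}={v:.3f} (n={nco.denominators[k]})"
                        for k, v in sorted(nco.fractions.items())
                        if not pd.isna(v))
            + f"  [simulated p={config.sim.p_neighbor_coexpressed}]", ""]

    if config.run_enrichment and config.run_pap and pap_matrix is not None \
            and non_ref:
        acc_name = config.ortho_accession or default_acc or non_ref[0]
        rng = np.random.default_rng([config.seed, 4])
        table = _term_table(ds, rng, config.n_generic_terms)
        absent = set(pap_matrix.call.index[
            pap_matrix.call[acc_name] == "absent"])
        lost = set(ds.truth.ortho.query(
            "accession == @acc_name and event == 'lost'").ref_gene)
        fg = absent | lost
        bg = set(table)
        if fg:
            rows = enrich(fg, bg, table)
            pd.DataFrame([dataclasses.asdict(r) for r in rows]).to_csv(
                out / "enrichment.tsv", sep="\t", index=False)
            manifest["stages"]["enrichment"] = {
                "n_foreground": len(fg), "n_terms": len(rows),
                "top_term": rows[0].term_id}
            report += [
                "enrichment (PAP/CNV candidates vs genome):",
                f"  foreground size: {len(fg)}",
                f"  top term: {rows[0].term_id} (p={rows[0].p:.3g}, "
                f"q={rows[0].q:.3g}); Gag-domain term is "
                f"{'top-ranked' if rows[0].term_id == GAG_TERM else 'not top'}",
                ""]
        else:
            manifest["stages"]["enrichment"] = {"n_foreground": 0,
                                                "skipped": True}

    for name, enabled in [("orthology", config.run_orthology),
                          ("pap", config.run_pap),
                          ("expression", config.run_expression),
                          ("enrichment", config.run_enrichment)]:
        if not enabled:
            manifest["stages"][name] = {"skipped": True}

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    (out / "report.txt").write_text("\n".join(report) + "\n")
    return out


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["sim"]["element_length_range"] = list(d["sim"]["element_length_range"])
    d["sim"]["tissue_groups"] = list(d["sim"]["tissue_groups"])
    return d


def report_summary(rundir) -> str:
    """Recompute summary tables from a completed run directory's TSVs."""
    run = Path(rundir)
    lines = [f"summary of {run}", ""]
    calls_path = run / "pap_call.tsv"
    if calls_path.exists():
        calls = pd.read_csv(calls_path, sep="\t", index_col=0)
        counts = (calls == "present").sum(axis=0)
        lines.append("elements present per accession:")
        for acc_name, n in counts.items():
            lines.append(f"  {acc_name}: {n}/{len(calls)}")
        lines.append("")
    else:
        lines.append("warning: pap_call.tsv missing; PAP summary skipped\n")
    pairs_path = run / "neighbor_pairs.tsv"
    if pairs_path.exists():
        pairs = pd.read_csv(pairs_path, sep="\t")
        lines.append("neighbour co-expression fraction (r > 0.8):")
        for qset, sub in pairs.groupby("query_set"):
            defined = sub["r"].dropna()
            if len(defined):
                frac = float((defined > 0.8).mean())
                lines.append(f"  {qset}: {frac:.3f} (n={len(defined)})")
        lines.append("")
    else:
        lines.append("warning: neighbor_pairs.tsv missing; co-expression "
                     "summary skipped\n")
    text = "\n".join(lines) + "\n"
    (run / "summary.txt").write_text(text)
    return text
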