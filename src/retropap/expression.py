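"""Expression filtering, ripening classification and neighbour co-expression.

Works on FPKM matrices over genes and Gag-like elements across tissue
groups.  A feature is *fruit-ripening-inducible* when its mean FPKM in the
post-harvest ripening group is the strict maximum over tissue-group means.
Neighbour co-expression pairs each element with its nearest annotated gene
on each side (within a window) and measures the Pearson correlation of
their raw FPKM vectors across all samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_model import ExpressionMatrix, GagElement, GeneModel, GenomicInterval

log = logging.getLogger("retropap")

DEFAULT_NEIGHBOR_WINDOW_BP = 50_000
DEFAULT_R_CUTOFF = 0.8
DEFAULT_MIN_FPKM = 0.1


def filter_expressed(matrix: ExpressionMatrix, min_fpkm: float = DEFAULT_MIN_FPKM,
                     mode: str = "any") -> ExpressionMatrix:
    """Drop non-expressed features.

    ``mode="any"`` keeps a feature expressed at >= *min_fpkm* in at least
    one sample (default); ``mode="all"`` requires every sample to reach the
    threshold.  Feature order is preserved; the operation is idempotent.
    """
    if mode == "any":
        keep = matrix.values.max(axis=1) >= min_fpkm
    elif mode == "all":
        keep = matrix.values.min(axis=1) >= min_fpkm
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    if not keep.any():
        log.warning("filter_expressed: no feature passes FPKM >= %g", min_fpkm)
    return ExpressionMatrix(values=matrix.values.loc[keep],
                            sample_groups=dict(matrix.sample_groups),
                            ripening_group=matrix.ripening_group)


def pearson_r(x, y) -> float:
    """Product-moment correlation; NaN for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = math.sqrt(float(xd @ xd) * float(yd @ yd))
    if denom == 0.0:
        return float("nan")
    return float(xd @ yd) / denom


def call_ripening_inducible(matrix: ExpressionMatrix,
                            min_fold: float = 1.0) -> pd.DataFrame:
    """Classify every feature as ripening-inducible or not.

    A feature is inducible iff its ripening-group mean FPKM is strictly the
    maximum over group means and at least ``min_fold`` times the
    next-highest group mean (the default 1.0 reduces to a pure argmax with
    ties excluded).  Returns the per-group means plus an
    ``is_ripening_inducible`` column, indexed by feature.
    """
    means = matrix.group_means()
    if means.shape[1] < 2:
        raise ValueError("ripening classification needs >= 2 tissue groups")
    rip = means[matrix.ripening_group]
    others = means.drop(columns=[matrix.ripening_group])
    next_highest = others.max(axis=1)
    inducible = (rip > next_highest) & (rip >= min_fold * next_highest)
    out = means.copy()
    out["is_ripening_inducible"] = inducible
    return out


def nearest_flanking_genes(locus: GenomicInterval, genes: list[GeneModel],
                           window_bp: int = DEFAULT_NEIGHBOR_WINDOW_BP,
                           exclude: str | None = None
                           ) -> list[tuple[GeneModel, str, int]]:
    """Nearest gene on each side of *locus* with edge distance <= window.

    Returns up to two (gene, side, distance_bp) tuples; genes overlapping
    the locus are not neighbours.  *exclude* skips a gene id (used when the
    query is itself a gene).
    """
    best: dict[str, tuple[int, GeneModel]] = {}
    for g in genes:
        if g.locus.sequence_id != locus.sequence_id or g.gene_id == exclude:
            continue
        if g.locus.end <= locus.start:
            d = locus.start - g.locus.end
            side = "upstream"
        elif g.locus.start >= locus.end:
            d = g.locus.start - locus.end
            side = "downstream"
        else:
            continue
        if d <= window_bp and (side not in best or d < best[side][0]
                               or (d == best[side][0]
                                   and g.gene_id < best[side][1].gene_id)):
            best[side] = (d, g)
    return [(g, side, d) for side, (d, g) in sorted(best.items())]


@dataclass
class NeighborCoexpression:
    """Result bundle: per-pair table, per-query-set fractions, histogram."""

    pairs: pd.DataFrame          # query_set, query_id, gene_id, side, distance_bp, r
    fractions: dict[str, float]  # set -> |r > cutoff| / |defined r|
    denominators: dict[str, int]
    histogram: pd.DataFrame      # bin_left, bin_right, <one count column per set>


def neighbor_coexpression(elements: list[GagElement], genes: list[GeneModel],
                          matrix: ExpressionMatrix,
                          window_bp: int = DEFAULT_NEIGHBOR_WINDOW_BP,
                          r_cutoff: float = DEFAULT_R_CUTOFF,
                          ripening_ids: set[str] | None = None,
                          include_gene_control: bool = True
                          ) -> NeighborCoexpression:
    """Correlate each query with its nearest flanking genes.

    Three query sets are analyzed, mirroring the ripening-inducible
    contrast: ``ripening_elements``, ``other_elements`` (elements split by
    *ripening_ids*) and, as a control, ``all_genes`` (every gene against
    its own flanking genes).  Pearson r is computed on raw FPKM vectors;
    each set's fraction is |pairs with r > cutoff| / |pairs with defined r|.
    """
    ripening_ids = ripening_ids or set()
    values = matrix.values
    rows = []

    def add_pairs(query_set: str, query_id: str, locus: GenomicInterval,
                  exclude: str | None = None) -> None:
        if query_id not in values.index:
            log.info("neighbor_coexpression: %s absent from matrix; skipped",
                     query_id)
            return
        qv = values.loc[query_id].to_numpy()
        for gene, side, dist in nearest_flanking_genes(locus, genes, window_bp,
                                                       exclude=exclude):
            if gene.gene_id not in values.index:
                log.info("neighbor_coexpression: neighbour %s absent from "
                         "matrix; skipped", gene.gene_id)
                continue
            r = pearson_r(qv, values.loc[gene.gene_id].to_numpy())
            rows.append((query_set, query_id, gene.gene_id, side, dist, r))

    for el in elements:
        qset = ("ripening_elements" if el.element_id in ripening_ids
                else "other_elements")
        add_pairs(qset, el.element_id, el.locus)
    if include_gene_control:
        for g in genes:
            add_pairs("all_genes", g.gene_id, g.locus, exclude=g.gene_id)

    pairs = pd.DataFrame(rows, columns=["query_set", "query_id", "gene_id",
                                        "side", "distance_bp", "r"])
    fractions: dict[str, float] = {}
    denominators: dict[str, int] = {}
    for qset, sub in pairs.groupby("query_set"):
        defined = sub["r"].dropna()
        denominators[qset] = len(defined)
        fractions[qset] = (float((defined > r_cutoff).mean())
                           if len(defined) else float("nan"))

    edges = np.round(np.arange(-1.0, 1.0 + 1e-9, 0.1), 10)
    hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:]})
    for qset, sub in pairs.groupby("query_set"):
        counts, _ = np.histogram(sub["r"].dropna(), bins=edges)
        hist[qset] = counts
    return NeighborCoexpression(pairs=pairs, fractions=fractions,
                                denominators=denominators, histogram=hist)
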