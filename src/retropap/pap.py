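"""Assembly-based presence/absence (PAP) genotyping of Gag-like elements.

For each element, a flank window around its reference locus is used as a
query against each target assembly: the best-matching region is located
genome-wide, the query is re-aligned against that region, and the
alignment ratio over the element span alone gives the PAP genotype in
[0,1] (1.0 = completely present, 0 = absent).  Accessions are then
hierarchically clustered on the numeric ratio matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from skbio import TreeNode

from .align import (
    DEFAULT_K,
    KmerIndex,
    alignment_ratio,
    best_matching_region,
    seed_and_chain,
)
from .genome_model import GagElement, GenomeAssembly, GenomicInterval

log = logging.getLogger("retropap")

DEFAULT_FLANK_BP = 50_000
MAX_FLANK_BP = 100_000
PRESENT_MIN = 0.8
ABSENT_MAX = 0.2


def extract_flank(element: GagElement, reference: GenomeAssembly,
                  flank_bp: int = DEFAULT_FLANK_BP) -> tuple[str, tuple[int, int]]:
    """Element plus surrounding sequence from the reference.

    The window ``[start - flank_bp, end + flank_bp)`` is clipped to the
    chromosome; the element span is returned in window coordinates.
    Flank sizes above 100 kb (the sensible upper bound for local PAP
    comparison) are rejected.
    """
    if not 0 <= flank_bp <= MAX_FLANK_BP:
        raise ValueError(f"flank_bp must be in [0, {MAX_FLANK_BP}]")
    loc = element.locus
    if loc.sequence_id not in reference.sequences:
        raise ValueError(f"{loc.sequence_id} absent from reference")
    seq = reference.sequences[loc.sequence_id]
    w_start = max(0, loc.start - flank_bp)
    w_end = min(len(seq), loc.end + flank_bp)
    return seq[w_start:w_end], (loc.start - w_start, loc.end - w_start)


def genotype_element(query: str, element_span: tuple[int, int],
                     target: GenomeAssembly | None,
                     present_min: float = PRESENT_MIN,
                     absent_max: float = ABSENT_MAX,
                     k: int = DEFAULT_K, min_region_score: float = 100.0,
                     index: KmerIndex | None = None
                     ) -> tuple[float | None, str]:
    """(alignment ratio, call) of one element in one target assembly.

    The full flank query locates its best-matching region in the target;
    the query is re-aligned against that region and the ratio is measured
    over the element span only.  ``present`` if ratio >= present_min,
    ``absent`` if <= absent_max, else ``ambiguous``; ``missing`` (ratio
    None) when no flank region is found at all.
    """
    hit = best_matching_region(query, target, k=k, min_score=min_region_score,
                               index=index)
    if hit is None:
        return None, "missing"
    region_iv, _chain = hit
    assembly = index.assembly if index is not None else target
    region_seq = assembly.fetch(
        GenomicInterval(region_iv.sequence_id, region_iv.start, region_iv.end))
    chains = seed_and_chain(query, region_seq, k=k)
    ratio = alignment_ratio(chains, element_span)
    if ratio >= present_min:
        call = "present"
    elif ratio <= absent_max:
        call = "absent"
    else:
        call = "ambiguous"
    return ratio, call


@dataclass
class PAPMatrix:
    """Elements x accessions alignment-ratio matrix with presence calls."""

    ratio: pd.DataFrame  # float, NaN = missing
    call: pd.DataFrame   # {present, absent, ambiguous, missing}
    reference_id: str

    @property
    def element_ids(self) -> list[str]:
        return list(self.ratio.index)

    @property
    def accession_ids(self) -> list[str]:
        return list(self.ratio.columns)

    def presence_counts(self) -> pd.Series:
        """Per-accession count of elements called present (summary graph)."""
        return (self.call == "present").sum(axis=0)


def build_pap_matrix(elements: list[GagElement], reference: GenomeAssembly,
                     targets: dict[str, GenomeAssembly],
                     flank_bp: int = DEFAULT_FLANK_BP,
                     present_min: float = PRESENT_MIN,
                     absent_max: float = ABSENT_MAX,
                     k: int = DEFAULT_K) -> PAPMatrix:
    """Genotype every element in every target assembly.

    The reference contributes an all-1.0/present column.  Target order is
    preserved; duplicate accession ids are an error.
    """
    names = [reference.accession_id, *targets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate accession ids")
    element_ids = [e.element_id for e in elements]
    ratio = pd.DataFrame(np.nan, index=element_ids, columns=names, dtype=float)
    call = pd.DataFrame("missing", index=element_ids, columns=names)
    ratio[reference.accession_id] = 1.0
    call[reference.accession_id] = "present"
    queries = [extract_flank(e, reference, flank_bp) for e in elements]
    for acc, assembly in targets.items():
        index = KmerIndex(assembly, k=k)
        for e, (query, span) in zip(elements, queries):
            r, c = genotype_element(query, span, None, present_min=present_min,
                                    absent_max=absent_max, k=k, index=index)
            ratio.loc[e.element_id, acc] = np.nan if r is None else r
            call.loc[e.element_id, acc] = c
    return PAPMatrix(ratio=ratio, call=call,
                     reference_id=reference.accession_id)


def _scipy_tree_to_treenode(node, labels: list[str]) -> TreeNode:
    if node.is_leaf():
        return TreeNode(name=labels[node.id], length=0.0)
    left = _scipy_tree_to_treenode(node.get_left(), labels)
    right = _scipy_tree_to_treenode(node.get_right(), labels)
    # branch length = merge height difference to each child's own height
    for child in (left, right):
        child.length = node.dist - (child.length if child.children else 0.0)
    out = TreeNode(children=[left, right], length=node.dist)
    return out


def cluster_accessions(matrix: PAPMatrix | pd.DataFrame,
                       method: str = "complete",
                       metric: str = "euclidean") -> TreeNode:
    """Agglomerative clustering of accessions on the ratio matrix.

    Rows are accessions (a :class:`PAPMatrix` is transposed internally);
    missing ratios are imputed as the per-element mean across accessions
    (logged); rows enter in lexicographic accession order so the
    dendrogram is invariant to input row order.  Complete linkage on
    Euclidean distances by default — R hclust's defaults.
    """
    data = matrix.ratio.T if isinstance(matrix, PAPMatrix) else matrix
    if data.shape[0] < 2:
        raise ValueError("need >= 2 accessions to cluster")
    data = data.sort_index()
    if data.isna().any().any():
        log.info("cluster_accessions: imputing %d missing ratios by element "
                 "mean", int(data.isna().sum().sum()))
        data = data.fillna(data.mean(axis=0)).fillna(0.0)
    z = linkage(data.to_numpy(), method=method, metric=metric)
    root = to_tree(z)
    tree = _scipy_tree_to_treenode(root, list(data.index))
    tree.length = None
    return tree
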