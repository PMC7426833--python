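"""Seed-and-chain local alignment between genome sequences.

A desk-scale aligner in the spirit of long-read genome aligners: exact
k-mer anchors (maximal shared runs) are chained by sparse dynamic
programming into colinear local alignments on both strands.  SNP-level
divergence is absorbed by chaining across broken anchors rather than by
substitution-tolerant seeds.  Provides the best-matching-region search and
the alignment-ratio statistic used for presence/absence genotyping, plus
dot-plot export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_model import GenomeAssembly, GenomicInterval, revcomp

DEFAULT_K = 15
GAP_COST_PER_BP = 0.01  # permissive chaining across indels / deletions
MAX_KMER_HITS = 16      # k-mers more frequent than this are repeat-masked

_ENC = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling 2-bit k-mer codes and a validity mask (no N in window)."""
    n = len(enc)
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    codes = np.zeros(m, dtype=np.int64)
    for i in range(k):
        codes = (codes << 2) | (enc[i : i + m] & 3)
    cs = np.concatenate([[0], np.cumsum(enc == 4)])
    valid = (cs[k:] - cs[:-k]) == 0
    return codes, valid


@dataclass(frozen=True)
class MatchBlock:
    """An ungapped exact-match block between query and target."""

    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str
    identity: float = 1.0

    def __post_init__(self) -> None:
        if self.q_end - self.q_start != self.t_end - self.t_start:
            raise ValueError("ungapped block with unequal spans")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity outside [0,1]")

    def __len__(self) -> int:
        return self.q_end - self.q_start


@dataclass
class AlignmentChain:
    """A colinear, non-overlapping set of match blocks on one strand."""

    blocks: list[MatchBlock]
    score: float
    strand: str
    target_id: str = ""

    @property
    def aligned_bp(self) -> int:
        return sum(len(b) for b in self.blocks)

    @property
    def q_start(self) -> int:
        return min(b.q_start for b in self.blocks)

    @property
    def q_end(self) -> int:
        return max(b.q_end for b in self.blocks)

    @property
    def t_start(self) -> int:
        return min(b.t_start for b in self.blocks)

    @property
    def t_end(self) -> int:
        return max(b.t_end for b in self.blocks)

    @property
    def identity(self) -> float:
        """Aligned fraction of the chain's query span (exact blocks only)."""
        return self.aligned_bp / max(1, self.q_end - self.q_start)


class KmerIndex:
    """Sorted k-mer index of a genome assembly, reusable across queries."""

    def __init__(self, assembly: GenomeAssembly, k: int = DEFAULT_K):
        if k < 8:
            raise ValueError("k < 8 enters the spurious-anchor regime")
        self.assembly = assembly
        self.k = k
        # per sequence: unique codes, offsets into the position array, and
        # positions grouped by code
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for sid, seq in assembly.sequences.items():
            codes, valid = _kmer_codes(_encode(seq), k)
            pos = np.flatnonzero(valid)
            codes = codes[pos]
            order = np.argsort(codes, kind="stable")
            codes, pos = codes[order], pos[order]
            uniq, first = np.unique(codes, return_index=True)
            offsets = np.concatenate([first, [len(codes)]])
            self._index[sid] = (uniq, offsets, pos)

    def matches(self, qcodes: np.ndarray, qvalid: np.ndarray,
                sequence_id: str) -> tuple[np.ndarray, np.ndarray]:
        """All (query_pos, target_pos) shared k-mer pairs for one target seq."""
        uniq, offsets, sp = self._index[sequence_id]
        if len(uniq) == 0 or len(qcodes) == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        # search sorted query codes for cache-friendly sequential access
        qorder = np.argsort(qcodes, kind="stable")
        sq = qcodes[qorder]
        ii = np.searchsorted(uniq, sq, "left")
        ii_c = np.minimum(ii, len(uniq) - 1)
        hitmask = (uniq[ii_c] == sq) & qvalid[qorder]
        cnt = np.where(hitmask, offsets[ii_c + 1] - offsets[ii_c], 0)
        cnt[cnt > MAX_KMER_HITS] = 0  # repeat masking
        nz = np.flatnonzero(cnt)
        if len(nz) == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        counts = cnt[nz]
        starts = offsets[ii_c[nz]]
        total = int(counts.sum())
        # vectorized ragged expansion of [starts[i], starts[i]+counts[i])
        idx = np.ones(total, dtype=np.int64)
        ends = np.cumsum(counts)
        idx[0] = starts[0]
        idx[ends[:-1]] = starts[1:] - (starts[:-1] + counts[:-1] - 1)
        idx = np.cumsum(idx)
        qpos = np.repeat(qorder[nz], counts)
        return qpos, sp[idx]


def _anchors_from_pairs(qpos: np.ndarray, tpos: np.ndarray,
                        k: int) -> tuple[np.ndarray, ...]:
    """Merge diagonal runs of shared k-mers into maximal exact anchors.

    Returns (q_start, q_end, t_start, t_end) arrays.
    """
    if len(qpos) == 0:
        e = np.empty(0, dtype=np.int64)
        return e, e, e, e
    diag = tpos - qpos
    order = np.lexsort((qpos, diag))
    q = qpos[order]
    t = tpos[order]
    d = diag[order]
    brk = np.flatnonzero((np.diff(d) != 0) | (np.diff(q) != 1))
    starts = np.concatenate([[0], brk + 1])
    ends = np.concatenate([brk, [len(q) - 1]])
    qs = q[starts]
    qe = q[ends] + k
    ts = t[starts]
    te = t[ends] + k
    return qs, qe, ts, te


def _chain_anchors(qs, qe, ts, te, max_gap_bp: int,
                   min_block_bp: int, slack: int = 0, max_chains: int = 200
                   ) -> list[tuple[list[tuple[int, int, int, int]], float]]:
    """Sparse-DP chaining; returns (trimmed block list, score) per chain.

    Anchors may overlap a previous anchor by up to *slack* bp on either
    axis (chance extension of exact runs across a breakpoint); the overlap
    is trimmed off the downstream block so emitted chains are strictly
    colinear and non-overlapping.
    """
    n = len(qs)
    if n == 0:
        return []
    order = np.lexsort((ts, qs))
    qs, qe, ts, te = qs[order], qe[order], ts[order], te[order]
    length = (qe - qs).astype(float)
    score = length.copy()
    parent = np.full(n, -1, dtype=np.int64)
    for i in range(1, n):
        gq = qs[i] - qe[:i]
        gt = ts[i] - te[:i]
        ok = ((gq >= -slack) & (gt >= -slack)
              & (gq <= max_gap_bp) & (gt <= max_gap_bp))
        if not ok.any():
            continue
        gap = np.maximum(np.maximum(gq, gt), 0)
        overlap = np.maximum(-np.minimum(gq, gt), 0)
        cand = score[:i] - GAP_COST_PER_BP * gap - overlap
        cand[~ok] = -np.inf
        j = int(np.argmax(cand))
        if cand[j] > 0:
            score[i] = length[i] + cand[j]
            parent[i] = j

    used = np.zeros(n, dtype=bool)
    chains: list[tuple[list[tuple[int, int, int, int]], float]] = []
    for i in np.argsort(-score):
        if used[i]:
            continue
        path = []
        j = int(i)
        while j >= 0 and not used[j]:
            path.append(j)
            used[j] = True
            j = int(parent[j])
        path.reverse()
        # trim overlaps, rescore the (possibly truncated) path from scratch
        blocks: list[tuple[int, int, int, int]] = []
        s = 0.0
        for p in path:
            bqs, bqe, bts, bte = int(qs[p]), int(qe[p]), int(ts[p]), int(te[p])
            if blocks:
                trim = max(blocks[-1][1] - bqs, blocks[-1][3] - bts, 0)
                bqs += trim
                bts += trim
                if bqe <= bqs:
                    continue
                gap = max(bqs - blocks[-1][1], bts - blocks[-1][3])
                s -= GAP_COST_PER_BP * gap
            blocks.append((bqs, bqe, bts, bte))
            s += bqe - bqs
        total = sum(b[1] - b[0] for b in blocks)
        if total < min_block_bp or not blocks:
            continue
        chains.append((blocks, s))
        if len(chains) >= max_chains:
            break
    chains.sort(key=lambda c: -c[1])
    return chains


def _chains_one_strand(qcodes, qvalid, index: KmerIndex, sid: str, strand: str,
                       qlen: int, min_block_bp: int, max_gap_bp: int
                       ) -> list[AlignmentChain]:
    qpos, tpos = index.matches(qcodes, qvalid, sid)
    qs, qe, ts, te = _anchors_from_pairs(qpos, tpos, index.k)
    out = []
    for blocks, score in _chain_anchors(qs, qe, ts, te, max_gap_bp,
                                        min_block_bp, slack=index.k):
        mbs = []
        for (bqs, bqe, bts, bte) in blocks:
            if strand == "-":
                # map back from reverse-complemented query coordinates
                mbs.append(MatchBlock(qlen - bqe, qlen - bqs, bts, bte, "-"))
            else:
                mbs.append(MatchBlock(bqs, bqe, bts, bte, "+"))
        mbs.sort(key=lambda b: b.q_start)
        out.append(AlignmentChain(blocks=mbs, score=score, strand=strand,
                                  target_id=sid))
    return out


def seed_and_chain(query: str, target: str | GenomeAssembly, k: int = DEFAULT_K,
                   min_block_bp: int = 50, max_gap_bp: int = 20000,
                   index: KmerIndex | None = None) -> list[AlignmentChain]:
    """Local alignment chains between *query* and *target*, both strands.

    *target* may be a plain sequence, a :class:`GenomeAssembly`, or a
    prebuilt :class:`KmerIndex` can be passed to amortize indexing across
    queries.  Chains whose total aligned length is below ``min_block_bp``
    are dropped.  Deterministic for fixed inputs.
    """
    if k < 8:
        raise ValueError("k < 8 enters the spurious-anchor regime")
    if index is None:
        if isinstance(target, str):
            target = GenomeAssembly(accession_id="target",
                                    sequences={"target": target})
        index = KmerIndex(target, k=k)
    if len(query) < index.k:
        raise ValueError("query shorter than k")
    qcodes, qvalid = _kmer_codes(_encode(query), index.k)
    rc = revcomp(query)
    rcodes, rvalid = _kmer_codes(_encode(rc), index.k)
    chains: list[AlignmentChain] = []
    for sid in index.assembly.sequences:
        chains += _chains_one_strand(qcodes, qvalid, index, sid, "+",
                                     len(query), min_block_bp, max_gap_bp)
        chains += _chains_one_strand(rcodes, rvalid, index, sid, "-",
                                     len(query), min_block_bp, max_gap_bp)
    chains.sort(key=lambda c: (-c.score, -c.aligned_bp, c.target_id, c.t_start))
    return chains


def best_matching_region(query: str, target: GenomeAssembly, pad_bp: int = 1000,
                         k: int = DEFAULT_K, min_score: float = 100.0,
                         min_block_bp: int = 50, max_gap_bp: int = 20000,
                         index: KmerIndex | None = None
                         ) -> tuple[GenomicInterval, AlignmentChain] | None:
    """Target interval spanned by the highest-scoring chain, padded/clipped.

    Returns ``None`` when no chain reaches ``min_score`` (absent query).
    Ties are broken by longer aligned length, then lexicographic sequence
    id, then smaller target start.
    """
    if not query:
        raise ValueError("empty query")
    chains = seed_and_chain(query, target, k=k, min_block_bp=min_block_bp,
                            max_gap_bp=max_gap_bp, index=index)
    if index is not None:
        target = index.assembly
    chains = [c for c in chains if c.score >= min_score]
    if not chains:
        return None
    best = min(chains, key=lambda c: (-c.score, -c.aligned_bp, c.target_id,
                                      c.t_start))
    tlen = len(target.sequences[best.target_id])
    iv = GenomicInterval(best.target_id,
                         max(0, best.t_start - pad_bp),
                         min(tlen, best.t_end + pad_bp),
                         best.strand)
    return iv, best


def alignment_ratio(chains: list[AlignmentChain],
                    query_span: tuple[int, int]) -> float:
    """Fraction of *query_span* covered by the union of aligned blocks.

    A ratio of 1.0 means the complete presence of the spanned sequence in
    the target; 0 means it is absent.  Overlapping blocks are merged before
    measuring.
    """
    start, end = query_span
    if end <= start:
        raise ValueError("empty query span")
    ivs = sorted((b.q_start, b.q_end) for c in chains for b in c.blocks)
    covered = 0
    cur_s, cur_e = None, None
    for s, e in ivs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += max(0, min(cur_e, end) - max(cur_s, start))
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += max(0, min(cur_e, end) - max(cur_s, start))
    return covered / (end - start)


def dotplot_points(chains: list[AlignmentChain]) -> pd.DataFrame:
    """One (query-midpoint, target-midpoint, strand) row per match block."""
    rows = [((b.q_start + b.q_end) / 2, (b.t_start + b.t_end) / 2, b.strand,
             c.target_id)
            for c in chains for b in c.blocks]
    return pd.DataFrame(rows, columns=["q_mid", "t_mid", "strand", "target_id"])
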