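"""Bespoke assembly-editing rules: depth-based splitting and hint joining.

``split_low_depth`` removes chimeric joins by cutting contigs wherever
long-read coverage drops below a threshold (depth < 4 by default).
``hint_join`` connects two scaffolds when both terminal windows of a
hint sequence from an independent assembly align to their ends with
near-perfect long alignments (identity >= 99%, aligned length >= 5 kb,
chain score >= 1000), inserting a fixed run of N at the junction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .align import KmerIndex, best_matching_region
from .genome_model import GenomeAssembly, revcomp

log = logging.getLogger("retropap")

MIN_DEPTH = 4          # split where depth < 4
MIN_RUN_BP = 100       # runs shorter than this are discarded
JOIN_MIN_IDENTITY = 0.99
JOIN_MIN_LEN_BP = 5_000
JOIN_MIN_SCORE = 1_000.0
END_WINDOW_BP = 50_000
GAP_FILL_N = 100


@dataclass
class DepthTrack:
    """Per-bp integer read depth along one sequence."""

    sequence_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if (self.depth < 0).any():
            raise ValueError("negative depth")


def split_low_depth(assembly: GenomeAssembly, depths: dict[str, DepthTrack],
                    min_depth: int = MIN_DEPTH,
                    min_run_bp: int = MIN_RUN_BP) -> GenomeAssembly:
    """Split contigs at positions with read depth below *min_depth*.

    Maximal runs with depth >= min_depth become contigs named
    ``<id>_partN`` (a contig retained in full keeps its name); retained
    runs shorter than *min_run_bp* are discarded, as is all sequence
    outside retained runs.
    """
    sequences: dict[str, str] = {}
    anchored: dict[str, bool] = {}
    for sid, seq in assembly.sequences.items():
        if sid not in depths:
            raise ValueError(f"missing depth track for {sid}")
        track = depths[sid].depth
        if len(track) != len(seq):
            raise ValueError(f"depth track length mismatch for {sid}")
        ok = track >= min_depth
        bounded = np.concatenate([[False], ok, [False]])
        starts = np.flatnonzero(~bounded[:-1] & bounded[1:])
        ends = np.flatnonzero(bounded[:-1] & ~bounded[1:])
        runs = [(a, b) for a, b in zip(starts, ends) if b - a >= min_run_bp]
        if len(runs) == 1 and runs[0] == (0, len(seq)):
            sequences[sid] = seq
            anchored[sid] = assembly.anchored.get(sid, True)
            continue
        for n, (a, b) in enumerate(runs, start=1):
            name = f"{sid}_part{n}"
            sequences[name] = seq[a:b]
            anchored[name] = assembly.anchored.get(sid, True)
    if not sequences:
        raise ValueError("no contig survives depth splitting")
    return GenomeAssembly(accession_id=assembly.accession_id,
                          sequences=sequences, anchored=anchored)


def _end_hit(window: str, index: KmerIndex, min_identity: float,
             min_len_bp: int, min_score: float):
    hit = best_matching_region(window, None, index=index, min_score=min_score)
    if hit is None:
        return None
    _, chain = hit
    if chain.aligned_bp < min_len_bp or chain.identity < min_identity:
        return None
    return chain


def hint_join(primary: GenomeAssembly, hints: GenomeAssembly,
              min_identity: float = JOIN_MIN_IDENTITY,
              min_len_bp: int = JOIN_MIN_LEN_BP,
              min_score: float = JOIN_MIN_SCORE,
              end_window_bp: int = END_WINDOW_BP,
              gap_fill_n: int = GAP_FILL_N) -> GenomeAssembly:
    """Join primary scaffolds bridged by hint sequences.

    Both terminal ``end_window_bp`` windows of each hint are aligned to
    the primary assembly; when the two ends hit two *distinct* primary
    scaffolds with chains passing the identity/length/score thresholds,
    those scaffolds are joined in hint-implied order and orientation with
    a ``gap_fill_n``-N gap.  Each scaffold end is used at most once;
    conflicting joins are resolved greedily by descending combined score
    (the loser is skipped with a warning).
    """
    if not primary.sequences or not hints.sequences:
        raise ValueError("both assemblies must be non-empty")
    index = KmerIndex(primary)
    candidates = []
    for hid, hseq in hints.sequences.items():
        w = min(end_window_bp, len(hseq) // 2)
        if w < index.k:
            continue
        left = _end_hit(hseq[:w], index, min_identity, min_len_bp, min_score)
        right = _end_hit(hseq[-w:], index, min_identity, min_len_bp, min_score)
        if left is None or right is None:
            continue
        if left.target_id == right.target_id:
            continue  # both ends on one scaffold: nothing to connect
        candidates.append((left.score + right.score, hid, left, right))

    # hint orientation: the join runs left-hit scaffold -> right-hit scaffold.
    # A '+' left hit means the scaffold's ascending axis points toward the
    # junction (use as-is, junction on its right end); '-' means revcomp.
    used_ends: set[tuple[str, str]] = set()
    joins = []
    for score, hid, left, right in sorted(candidates, key=lambda c: -c[0]):
        a, b = left.target_id, right.target_id
        a_end = ("right" if left.strand == "+" else "left")
        b_end = ("left" if right.strand == "+" else "right")
        keys = {(a, a_end), (b, b_end)}
        if keys & used_ends:
            log.warning("hint_join: conflicting join via %s skipped "
                        "(score %.0f)", hid, score)
            continue
        used_ends |= keys
        joins.append((a, left.strand, b, right.strand, hid))

    # build join-graph paths; one-use-per-end above guarantees simple paths.
    # Orientation: '+' = scaffold as stored, '-' = reverse-complemented so
    # its aligned end faces the junction.
    succ: dict[str, tuple[str, str, str]] = {}
    for a, astrand, b, bstrand, _ in joins:
        succ[a] = (b, astrand, bstrand)
    has_pred = {b for (b, _, _) in succ.values()}
    gap = "N" * gap_fill_n
    sequences: dict[str, str] = {}
    consumed: set[str] = set()

    def oriented(sid: str, strand: str) -> str:
        seq = primary.sequences[sid]
        return seq if strand == "+" else revcomp(seq)

    for start in sorted(succ):
        if start in has_pred:
            continue
        path = [(start, succ[start][1])]
        nxt = (succ[start][0], succ[start][2])
        while True:
            sid, orient = nxt
            path.append((sid, orient))
            if (sid in succ and succ[sid][1] == orient
                    and succ[sid][0] not in {p[0] for p in path}):
                nxt = (succ[sid][0], succ[sid][2])
            else:
                if sid in succ:
                    log.warning("hint_join: orientation conflict at %s; "
                                "path truncated", sid)
                break
        name = "_".join(sid for sid, _ in path) + "_joined"
        sequences[name] = gap.join(oriented(sid, st) for sid, st in path)
        consumed.update(sid for sid, _ in path)
    for sid, seq in primary.sequences.items():
        if sid not in consumed:
            sequences[sid] = seq
    return GenomeAssembly(accession_id=primary.accession_id,
                          sequences=sequences,
                          anchored={s: False for s in sequences})
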