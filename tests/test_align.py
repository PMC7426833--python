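"""Seed-and-chain aligner: anchors vs brute force, chaining, ratios."""

import numpy as np
import pytest

from retropap.align import (
    KmerIndex,
    MatchBlock,
    AlignmentChain,
    alignment_ratio,
    best_matching_region,
    dotplot_points,
    seed_and_chain,
    _encode,
    _kmer_codes,
)
from retropap.genome_model import GenomeAssembly, revcomp

from conftest import rand_dna


def brute_force_matches(query: str, target: str, k: int) -> set:
    """Independent oracle: every shared exact k-mer (q_pos, t_pos) pair."""
    tmap: dict[str, list[int]] = {}
    for i in range(len(target) - k + 1):
        kmer = target[i:i + k]
        if "N" not in kmer:
            tmap.setdefault(kmer, []).append(i)
    out = set()
    for j in range(len(query) - k + 1):
        kmer = query[j:j + k]
        if "N" in kmer:
            continue
        for i in tmap.get(kmer, ()):
            out.add((j, i))
    return out


class TestAnchors:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_anchor_matches_equal_brute_force(self, seed):
        """Index-derived k-mer matches equal the all-pairs oracle, including
        on sequences with planted internal duplications."""
        rng = np.random.default_rng(seed)
        k = 11
        q = rand_dna(rng, 800)
        t = rand_dna(rng, 500) + q[100:300] + rand_dna(rng, 200) + q[100:200]
        index = KmerIndex(GenomeAssembly("t", {"s": t}), k=k)
        qc, qv = _kmer_codes(_encode(q), k)
        qpos, tpos = index.matches(qc, qv, "s")
        assert set(zip(qpos.tolist(), tpos.tolist())) == \
            brute_force_matches(q, t, k)

    def test_small_k_rejected(self, rng):
        with pytest.raises(ValueError, match="k < 8"):
            seed_and_chain(rand_dna(rng, 100), rand_dna(rng, 100), k=7)


class TestSeedAndChain:
    def test_self_alignment_is_one_full_forward_chain(self, rng):
        q = rand_dna(rng, 5000)
        chains = seed_and_chain(q, q)
        top = chains[0]
        assert top.strand == "+"
        assert (top.q_start, top.q_end, top.t_start, top.t_end) == \
            (0, 5000, 0, 5000)
        assert top.identity == 1.0

    def test_reverse_complement_gives_minus_chain(self, rng):
        q = rand_dna(rng, 4000)
        top = seed_and_chain(q, revcomp(q))[0]
        assert top.strand == "-"
        assert (top.q_start, top.q_end) == (0, 4000)
        assert top.aligned_bp == 4000

    def test_central_deletion_chains_across_gap(self, rng):
        """A 1 kb deletion in the target yields one chain aligning the
        4 kb of conserved query in two blocks; block coordinates agree
        with the shared-k-mer oracle's diagonals."""
        q = rand_dna(rng, 5000)
        t = q[:2000] + q[3000:]
        top = seed_and_chain(q, t)[0]
        assert len(top.blocks) == 2
        assert top.aligned_bp >= 4000 - 30  # breakpoint k-mer slack
        oracle = brute_force_matches(q, t, 15)
        for b in top.blocks:
            for j in range(b.q_start, b.q_end - 14):
                assert (j, j - (b.q_start - b.t_start)) in oracle

    def test_score_symmetry_on_clean_pair(self, rng):
        q = rand_dna(rng, 3000)
        t = rand_dna(rng, 500) + q + rand_dna(rng, 500)
        assert seed_and_chain(q, t)[0].score == seed_and_chain(t, q)[0].score


class TestBestMatchingRegion:
    def test_verbatim_copy_is_located(self, rng):
        q = rand_dna(rng, 5000)
        genome = GenomeAssembly("g", {
            "chr1": rand_dna(rng, 20000) + q + rand_dna(rng, 10000)})
        iv, chain = best_matching_region(q, genome)
        assert iv.sequence_id == "chr1"
        assert iv.start <= 20000 and iv.end >= 25000

    def test_unrelated_query_returns_none(self, rng):
        genome = GenomeAssembly("g", {"chr1": rand_dna(rng, 30000)})
        assert best_matching_region(rand_dna(rng, 5000), genome) is None

    def test_less_mutated_locus_wins(self, rng):
        """With the query present at two loci, the one carrying fewer
        mutations scores higher (verified against per-locus chain scores)."""
        q = rand_dna(rng, 4000)
        mutated = list(q)
        for p in rng.choice(4000, size=80, replace=False):  # 2% divergence
            mutated[p] = "ACGT"[("ACGT".index(mutated[p]) + 1) % 4]
        mutated = "".join(mutated)
        spacer = rand_dna(rng, 30000)
        chrom = mutated + spacer + q
        genome = GenomeAssembly("g", {"chr1": chrom})
        iv, chain = best_matching_region(q, genome)
        assert iv.start >= len(mutated) + 20000
        clean_score = seed_and_chain(q, q)[0].score
        mut_score = seed_and_chain(q, mutated)[0].score
        assert mut_score < clean_score
        assert chain.score > mut_score

    def test_empty_query_error(self, rng):
        genome = GenomeAssembly("g", {"chr1": rand_dna(rng, 1000)})
        with pytest.raises(ValueError):
            best_matching_region("", genome)


def _chain_with_blocks(blocks):
    return AlignmentChain(blocks=[MatchBlock(*b, "+") for b in blocks],
                          score=1.0, strand="+")


class TestAlignmentRatio:
    def test_full_coverage_is_one(self):
        ch = _chain_with_blocks([(0, 10000, 0, 10000)])
        assert alignment_ratio([ch], (0, 10000)) == 1.0

    def test_no_overlap_is_zero(self):
        ch = _chain_with_blocks([(0, 100, 0, 100)])
        assert alignment_ratio([ch], (5000, 6000)) == 0.0

    def test_union_merge_on_overlapping_blocks(self):
        # blocks cover [0,3000) u [2000,5000) u [8000,9000) = 6000 of 10000
        ch = _chain_with_blocks([(0, 3000, 0, 3000),
                                 (2000, 5000, 10000, 13000),
                                 (8000, 9000, 20000, 21000)])
        assert alignment_ratio([ch], (0, 10000)) == pytest.approx(0.6)

    def test_empty_span_error(self):
        with pytest.raises(ValueError):
            alignment_ratio([], (100, 100))

    def test_monotone_in_deleted_fraction(self, rng):
        """Deleting a larger nested fraction of the query from the target
        never increases the ratio."""
        q = rand_dna(rng, 10000)
        last = 1.1
        for f in [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]:
            cut = int(10000 * f)
            lo, hi = 5000 - cut // 2, 5000 + (cut - cut // 2)
            t = q[:lo] + q[hi:]
            ratio = (alignment_ratio(seed_and_chain(q, t), (0, 10000))
                     if len(t) >= 15 else 0.0)
            assert ratio <= last + 1e-9
            last = ratio


class TestDotplot:
    def test_self_alignment_points_on_diagonal(self, rng):
        q = rand_dna(rng, 2000)
        pts = dotplot_points(seed_and_chain(q, q))
        assert (pts["q_mid"] == pts["t_mid"]).all()
        assert (pts["strand"] == "+").all()

    def test_reverse_alignment_flagged_minus(self, rng):
        q = rand_dna(rng, 2000)
        pts = dotplot_points(seed_and_chain(q, revcomp(q)))
        assert (pts["strand"] == "-").all()
        # anti-diagonal: query and target midpoints sum to sequence length
        assert ((pts["q_mid"] + pts["t_mid"] - 2000).abs() < 20).all()

    def test_empty_chains_empty_table(self):
        assert len(dotplot_points([])) == 0


class TestAlignmentRatioProperties:
    """Hypothesis: ratio equals brute-force per-base coverage counting."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    def _coverage_oracle(blocks, span):
        lo, hi = span
        covered = [False] * (hi - lo)
        for (qs, qe) in blocks:
            for p in range(max(qs, lo), min(qe, hi)):
                covered[p - lo] = True
        return sum(covered) / (hi - lo)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 400), st.integers(1, 120)),
                    min_size=0, max_size=12),
           st.integers(0, 300), st.integers(1, 200))
    def test_matches_per_base_coverage(self, raw_blocks, span_lo, span_len):
        blocks = [(s, s + l) for s, l in raw_blocks]
        chains = [AlignmentChain(
            blocks=[MatchBlock(s, e, 1000 + s, 1000 + e, "+")
                    for s, e in blocks],
            score=1.0, strand="+")] if blocks else []
        span = (span_lo, span_lo + span_len)
        assert alignment_ratio(chains, span) == pytest.approx(
            self._coverage_oracle(blocks, span))
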