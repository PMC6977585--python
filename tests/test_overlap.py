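"""Aligner oracles: exact diffs, chaining vs exhaustive search, classification."""

import itertools

import numpy as np
import pytest

from olcasm.intervals import IntervalTrack
from olcasm.overlap import (AlignmentChain, AlignParams, LocalAlignment,
                            all_vs_all, chain_alignments, classify_chain,
                            local_align, normalized_ops, realign_unmasked,
                            revcomp)
from olcasm.readstore import SubRead, build_db
from olcasm.simulate import simulate_genome, simulate_reads, _apply_errors

from conftest import edit_distance_dp


def noisy(seq, rate, seed):
    rng = np.random.default_rng(seed)
    out, _ = _apply_errors(rng, seq, np.full(len(seq), rate), (0.55, 0.25, 0.20))
    return out


class TestLocalAlign:
    def test_exact_shared_block(self):
        g = simulate_genome(6000, seed=1).sequence
        alns = local_align(g[:3000], g[2000:5000])
        assert len(alns) == 1
        a = alns[0]
        assert (a.a_begin, a.a_end, a.b_begin, a.b_end) == (2000, 3000, 0, 1000)
        assert a.diffs == 0 and a.orientation == "normal"

    def test_reverse_complement_full_length(self):
        g = simulate_genome(3000, seed=2).sequence
        alns = local_align(g, revcomp(g))
        assert len(alns) == 1
        a = alns[0]
        assert a.orientation == "complement"
        assert (a.a_begin, a.a_end, a.b_begin, a.b_end) == (0, 3000, 0, 3000)
        assert a.diffs == 0

    @pytest.mark.parametrize("rate,seed", [(0.0, 0), (0.05, 1), (0.12, 2),
                                           (0.15, 3)])
    def test_diffs_equal_dp_edit_distance(self, rate, seed):
        g = simulate_genome(4000, seed=seed).sequence
        a = noisy(g[:2000], rate, seed + 10)
        b = noisy(g[800:2800], rate, seed + 20)
        for aln in local_align(a, b):
            seg_a = a[aln.a_begin : aln.a_end]
            bo = b if aln.orientation == "normal" else revcomp(b)
            ob, oe = aln.b_oriented()
            seg_b = bo[ob:oe]
            assert aln.diffs == edit_distance_dp(seg_a, seg_b)

    def test_single_substitution(self):
        g = simulate_genome(2000, seed=4).sequence
        b = g[:1000] + ("A" if g[1000] != "A" else "C") + g[1001:]
        alns = local_align(g, b)
        assert len(alns) == 1
        assert alns[0].diffs == edit_distance_dp(g, b) == 1

    def test_no_seeds_empty_result(self):
        a = simulate_genome(1000, seed=5).sequence
        b = simulate_genome(1000, seed=6).sequence
        assert local_align(a, b) == []

    def test_masking_suppresses_seeding(self):
        g = simulate_genome(4000, seed=7).sequence
        a, b = g[:3000], g[1000:4000]
        full = local_align(a, b)
        masked = local_align(a, b, mask_a=[(0, 3000)])
        assert full and masked == []

    def test_mask_only_removes_alignments(self):
        g = simulate_genome(8000, seed=8).sequence
        a, b = g[:5000], g[2500:8000]
        unmasked = {x.sort_key() for x in local_align(a, b)}
        part = {x.sort_key() for x in
                local_align(a, b, mask_a=[(2600, 3400)], mask_b=[(100, 900)])}
        # masking can only remove seeds, never create new overlap regions
        assert len(part) <= len(unmasked)


def _mk(a_begin, a_end, b_begin, b_end, diffs=0, a_len=10_000, b_len=10_000):
    return LocalAlignment("A", "B", "normal", a_begin, a_end, b_begin, b_end,
                          diffs, a_len, b_len)


def chain_score_oracle(alignments, max_gap):
    """Exhaustive best co-linear chain (subset enumeration, n <= 10)."""
    best = 0
    idx = range(len(alignments))
    for r in range(1, len(alignments) + 1):
        for combo in itertools.permutations(idx, r):
            if list(combo) != sorted(combo, key=lambda i: alignments[i].a_begin):
                continue
            ok = True
            for i, j in zip(combo, combo[1:]):
                x, y = alignments[i], alignments[j]
                ga = y.a_begin - x.a_end
                gb = y.b_begin - x.b_end
                if not (0 <= ga <= max_gap and 0 <= gb <= max_gap):
                    ok = False
                    break
            if ok:
                score = sum(alignments[i].a_span + alignments[i].b_span
                            for i in combo)
                best = max(best, score)
    return best


class TestChaining:
    def test_two_colinear_alignments_form_one_chain(self):
        alns = [_mk(0, 1000, 0, 1000), _mk(1200, 2000, 1200, 2000)]
        chains = chain_alignments(alns, max_gap=1500)
        assert len(chains) == 1 and len(chains[0]) == 2

    def test_crossing_alignments_stay_separate(self):
        alns = [_mk(0, 1000, 2000, 3000), _mk(1500, 2500, 0, 1000)]
        chains = chain_alignments(alns, max_gap=1500)
        assert sorted(len(c) for c in chains) == [1, 1]

    def test_gap_beyond_limit_splits(self):
        alns = [_mk(0, 1000, 0, 1000), _mk(3000, 4000, 3000, 4000)]
        chains = chain_alignments(alns, max_gap=1500)
        assert sorted(len(c) for c in chains) == [1, 1]

    @pytest.mark.parametrize("seed", range(8))
    def test_best_chain_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        alns = []
        for _ in range(rng.integers(2, 7)):
            ab = int(rng.integers(0, 8000))
            span = int(rng.integers(200, 1500))
            off = int(rng.integers(-2000, 2000))
            bb = max(0, ab + off)
            alns.append(_mk(ab, ab + span, bb, bb + span))
        chains = chain_alignments(alns, max_gap=1500)
        got = max(c.aligned_a + c.aligned_b for c in chains)
        assert got == chain_score_oracle(alns, 1500)

    def test_mixed_pairs_rejected(self):
        bad = [_mk(0, 1000, 0, 1000),
               LocalAlignment("A", "C", "normal", 0, 1000, 0, 1000, 0,
                              10_000, 10_000)]
        with pytest.raises(ValueError):
            chain_alignments(bad)

    def test_each_alignment_in_at_most_one_chain(self):
        alns = [_mk(i * 900, i * 900 + 800, i * 900, i * 900 + 800)
                for i in range(5)]
        chains = chain_alignments(alns, max_gap=1500)
        used = [id(a) for c in chains for a in c.alignments]
        assert len(used) == len(set(used)) == 5


class TestClassify:
    def test_full_span_is_proper(self):
        chain = AlignmentChain([_mk(0, 10_000, 0, 10_000)])
        assert classify_chain(chain, IntervalTrack()) == "proper"

    def test_interior_end_in_repeat_is_premature(self):
        chain = AlignmentChain([_mk(10, 7000, 10, 7000)])
        track = IntervalTrack({"A": [(6500, 7500)]})
        assert classify_chain(chain, track) == "premature_in_repeat"

    def test_interior_end_without_repeat_is_improper(self):
        chain = AlignmentChain([_mk(10, 7000, 10, 7000)])
        assert classify_chain(chain, IntervalTrack()) == "improper"

    def test_either_read_boundary_counts(self):
        # reaches B's start and A's end: proper dovetail shape
        chain = AlignmentChain([_mk(4000, 10_000, 0, 6000)])
        assert classify_chain(chain, IntervalTrack()) == "proper"


class TestRealign:
    def _repeat_pair(self):
        g = simulate_genome(30_000, seed=9).sequence
        rep = simulate_genome(2000, seed=99).sequence
        a = g[:6000] + rep + g[6000:10_000]
        b = g[2000:6000] + rep + g[6000:14_000]
        mask_a = [(6000, 8000)]
        mask_b = [(4000, 6000)]
        return a, b, mask_a, mask_b

    def test_premature_chain_becomes_proper_after_mask_free_realign(self):
        a, b, mask_a, mask_b = self._repeat_pair()
        track = IntervalTrack({"A": mask_a, "B": mask_b})
        alns = local_align(a, b, mask_a, mask_b)
        chains = []
        for chain in chain_alignments(alns, 1500):
            classify_chain(chain, track)
            chains.append(chain)
        new = realign_unmasked(a, b, chains)
        merged = chain_alignments(new, 1500)
        statuses = [classify_chain(c, track) for c in merged]
        assert "proper" in statuses

    def test_control_pair_without_shared_flank_stays_non_proper(self):
        g = simulate_genome(30_000, seed=10).sequence
        h = simulate_genome(30_000, seed=11).sequence
        rep = simulate_genome(2000, seed=98).sequence
        a = g[:6000] + rep + g[6000:10_000]
        b = h[:4000] + rep + h[4000:12_000]
        track = IntervalTrack({"A": [(6000, 8000)], "B": [(4000, 6000)]})
        new = realign_unmasked(a, b, [])
        statuses = [classify_chain(c, track)
                    for c in chain_alignments(new, 1500)] if new else []
        assert "proper" not in statuses

    def test_proper_chains_returned_unchanged(self):
        aln = _mk(0, 10_000, 0, 10_000)
        chain = AlignmentChain([aln])
        classify_chain(chain, IntervalTrack())
        out = realign_unmasked("A" * 10, "A" * 10, [chain])
        assert out == [aln]


class TestAllVsAll:
    def test_three_identical_reads(self):
        seq = simulate_genome(5000, seed=12).sequence
        db = build_db([SubRead(f"r{i}", f"r{i}", 0, seq) for i in range(3)],
                      min_length=1000)
        piles = all_vs_all(db)
        for pile in piles:
            full = [a for a in pile.alignments
                    if a.a_span == 5000 and a.b_span == 5000]
            assert len(full) == 2

    def test_symmetric_under_pair_exchange(self):
        g = simulate_genome(40_000, seed=13)
        reads, _ = simulate_reads(g, 5, (8000, 4000), 0.05, None, seed=14)
        db = build_db(reads, 4000)
        keys = set()
        for pile in all_vs_all(db):
            for x in pile.alignments:
                keys.add((x.a_id, x.b_id, x.orientation, x.a_begin, x.a_end,
                          x.b_begin, x.b_end, x.diffs))
        for (ai, bi, o, ab, ae, bb, be, d) in keys:
            assert (bi, ai, o, bb, be, ab, ae, d) in keys

    def test_true_overlaps_found_on_tiling_reads(self):
        g = simulate_genome(50_000, seed=15)
        reads, truths = simulate_reads(g, 4, (8000, 5000), 0.0, None, seed=16)
        db = build_db(reads, 4000)
        spans = {}
        for t in truths:
            if t.read_id in db:
                gb, ge, _ = t.source_intervals[0]
                spans[t.read_id] = (gb, ge)
        expected = set()
        ids = sorted(spans, key=db.index_of)
        for i, ri in enumerate(ids):
            for rj in ids[i + 1:]:
                ov = min(spans[ri][1], spans[rj][1]) - max(spans[ri][0], spans[rj][0])
                if ov >= 700:  # min_alignment_length plus slack
                    expected.add(frozenset((ri, rj)))
        found = set()
        for pile in all_vs_all(db):
            for a in pile.alignments:
                found.add(frozenset((a.a_id, a.b_id)))
        assert expected <= found


def test_normalized_ops_consistent_for_mirrors():
    g = simulate_genome(3000, seed=17).sequence
    b = noisy(g[500:2500], 0.08, 18)
    for b_seq in (b, revcomp(b)):
        for aln in local_align(g, b_seq):
            for rec, a_seq, p_seq in ((aln, g, b_seq),
                                      (aln.mirrored(), b_seq, g)):
                bo = p_seq if rec.orientation == "normal" else revcomp(p_seq)
                a_pos, j = rec.a_begin, rec.b_oriented()[0]
                for n, op in normalized_ops(rec):
                    if op in "=X":
                        match = a_seq[a_pos:a_pos + n] == bo[j:j + n]
                        assert match == (op == "=")
                        a_pos += n
                        j += n
                    elif op == "I":
                        a_pos += n
                    else:
                        j += n
                assert a_pos == rec.a_end and j == rec.b_oriented()[1]
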