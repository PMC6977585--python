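"""Layout: quality track, pile filtering, reduction oracle, touring, stats."""

import numpy as np
import pytest

from olcasm.intervals import IntervalTrack
from olcasm.layout import (Contig, LayoutParams, OverlapEdge, assembly_stats,
                           consensus, filter_piles, quality_track, tour,
                           transitive_reduction)
from olcasm.overlap import (AlignParams, LocalAlignment, Pile, all_vs_all,
                            local_align, revcomp)
from olcasm.readstore import ReadDB, SubRead, build_db
from olcasm.simulate import simulate_genome, simulate_reads, _apply_errors


def noisy(seq, rate, seed):
    rng = np.random.default_rng(seed)
    out, _ = _apply_errors(rng, seq, np.full(len(seq), rate), (0.55, 0.25, 0.20))
    return out


class TestQualityTrack:
    def test_error_free_pile_is_zero(self):
        g = simulate_genome(20_000, seed=81)
        reads, _ = simulate_reads(g, 10, (6000, 4000), 0.0, None, seed=82)
        db = build_db(reads, 4000)
        pile = all_vs_all(db)[0]
        q = quality_track(pile, db.length_of(pile.a_id))
        covered = q[q >= 0]
        assert len(covered) and np.all(covered == 0.0)

    def test_no_alignments_all_sentinel(self):
        q = quality_track(Pile("r", []), 5000)
        assert np.all(q == -1.0)

    def test_locally_divergent_segment_stands_out(self):
        g = simulate_genome(12_000, seed=83).sequence
        # A carries a private noisy patch; partners are clean
        a = g[:5000] + noisy(g[5000:6000], 0.30, 1) + g[6000:11_000]
        partners = [g[i : i + 9000] for i in (0, 500, 1000)]
        alns = []
        for i, pseq in enumerate(partners):
            for aln in local_align(a, pseq, a_id="A", b_id=f"P{i}"):
                alns.append(aln)
        pile = Pile("A", alns)
        q = quality_track(pile, len(a))
        bad = q[51:59][q[51:59] >= 0]
        flank = np.concatenate([q[20:48], q[62:90]])
        flank = flank[flank >= 0]
        assert len(bad) and bad.mean() >= 3 * max(flank.mean(), 0.01)


def layout_edges(n_reads, length, overlap, signs=None):
    """Edges of a linear true layout of equally spaced reads."""
    signs = signs or [1] * n_reads
    step = length - overlap
    edges = []
    for i in range(n_reads - 1):
        u, v = (f"r{i}", signs[i]), (f"r{i+1}", signs[i + 1])
        edges.append(OverlapEdge(u, v, overlap, 0, overlap))
        edges.append(OverlapEdge((v[0], -v[1]), (u[0], -u[1]), overlap, 0,
                                 length - step))
    return edges


def reachability(edges):
    nodes = sorted({e.u for e in edges} | {e.v for e in edges})
    idx = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    reach = [[False] * n for _ in range(n)]
    for e in edges:
        reach[idx[e.u]][idx[e.v]] = True
    for k in range(n):
        for i in range(n):
            if reach[i][k]:
                row, rk = reach[i], reach[k]
                for j in range(n):
                    if rk[j]:
                        row[j] = True
    return {(nodes[i], nodes[j]) for i in range(n) for j in range(n)
            if reach[i][j]}


def random_consistent_graph(seed, max_reads=12):
    """A string graph derived from a random true read layout (oracle input)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, max_reads + 1))
    starts = np.sort(rng.integers(0, 30_000, n))
    lengths = rng.integers(6000, 14_000, n)
    reads = {f"r{i}": int(lengths[i]) for i in range(n)}
    flip = set(f"r{i}" for i in np.flatnonzero(rng.random(n) < 0.4))

    def node(r, s):
        return (r, -s) if r in flip else (r, s)

    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = int(starts[i]), int(starts[j])
            ei, ej = si + int(lengths[i]), sj + int(lengths[j])
            ov = min(ei, ej) - max(si, sj)
            if ov <= 0 or (si <= sj and ej <= ei) or (sj <= si and ei <= ej):
                continue  # disjoint or contained
            a, b = (i, j) if si <= sj else (j, i)
            ra, rb = f"r{a}", f"r{b}"
            edges.append(OverlapEdge(node(ra, 1), node(rb, 1), ov, 0, ov))
            edges.append(OverlapEdge(node(rb, -1), node(ra, -1), ov, 0,
                                     reads[ra] - (int(starts[b]) - int(starts[a]))))
    return edges, reads


class TestTransitiveReduction:
    def test_three_node_chain_removes_long_edge(self):
        reads = {"A": 10_000, "B": 10_000, "C": 10_000}
        e_ab = OverlapEdge(("A", 1), ("B", 1), 5000, 0, 5000)
        e_bc = OverlapEdge(("B", 1), ("C", 1), 5000, 0, 5000)
        e_ac = OverlapEdge(("A", 1), ("C", 1), 100, 0, 100)
        reduced = transitive_reduction([e_ab, e_bc, e_ac], fuzz=200,
                                       read_lengths=reads)
        keys = {(e.u, e.v) for e in reduced}
        assert (("A", 1), ("C", 1)) not in keys
        assert (("A", 1), ("B", 1)) in keys and (("B", 1), ("C", 1)) in keys

    def test_no_transitive_triples_unchanged(self):
        reads = {"A": 10_000, "B": 10_000}
        e = OverlapEdge(("A", 1), ("B", 1), 4000, 0, 4000)
        assert transitive_reduction([e], 200, reads) == [e]

    @pytest.mark.parametrize("seed", range(25))
    def test_reachability_preserved_on_random_layout_graphs(self, seed):
        edges, reads = random_consistent_graph(seed)
        reduced = transitive_reduction(edges, 200, reads)
        assert {(e.u, e.v) for e in reduced} <= {(e.u, e.v) for e in edges}
        assert reachability(reduced) == reachability(edges)


class TestTour:
    def _db(self, ids, length=10_000):
        return ReadDB([SubRead(r, r, 0, "A" * length) for r in ids])

    def test_linear_chain_single_contig(self):
        edges = layout_edges(5, 10_000, 4000)
        db = self._db([f"r{i}" for i in range(5)])
        contigs = tour(edges, db)
        assert len(contigs) == 1
        assert [r for r, _ in contigs[0].path] == [f"r{i}" for i in range(5)]
        assert not contigs[0].circular

    def test_simple_cycle_is_circular(self):
        edges = layout_edges(4, 10_000, 4000)
        edges.append(OverlapEdge(("r3", 1), ("r0", 1), 4000, 0, 4000))
        edges.append(OverlapEdge(("r0", -1), ("r3", -1), 4000, 0, 6000))
        db = self._db([f"r{i}" for i in range(4)])
        contigs = tour(edges, db)
        assert len(contigs) == 1 and contigs[0].circular

    def test_branch_takes_most_aligned_bases(self):
        edges = layout_edges(4, 10_000, 5000)  # main chain r0..r3
        # weaker branch from r1 to a dead-end read
        edges.append(OverlapEdge(("r1", 1), ("x", 1), 1000, 0, 1000))
        edges.append(OverlapEdge(("x", -1), ("r1", -1), 1000, 0, 9000))
        db = self._db(["r0", "r1", "r2", "r3", "x"])
        contigs = tour(edges, db)
        main = max(contigs, key=lambda c: len(c.path))
        assert [r for r, _ in main.path] == ["r0", "r1", "r2", "r3"]


class TestConsensus:
    def test_error_free_path_reconstructs_genome(self):
        g = simulate_genome(30_000, seed=85)
        reads, _ = simulate_reads(g, 20, (8000, 5000), 0.0, None, seed=86)
        db = build_db(reads, 4000)
        piles = all_vs_all(db)
        track = IntervalTrack()
        quality = {p.a_id: quality_track(p, db.length_of(p.a_id)) for p in piles}
        edges, contained = filter_piles(piles, db, track, quality)
        lengths = {r.read_id: len(r) for r in db}
        reduced = transitive_reduction(edges, 200, lengths)
        contigs = tour(reduced, db, contained)
        main = max(contigs, key=lambda c: sum(db.length_of(r) for r, _ in c.path))
        seq = consensus(main, db, {p.a_id: p for p in piles})
        assert seq == g.sequence or seq == revcomp(g.sequence)

    def test_single_read_path_without_votes_is_the_read(self):
        db = ReadDB([SubRead("r", "r", 0, "ACGTACGTAC" * 100)])
        c = Contig("c", [("r", 1)], [])
        assert consensus(c, db, {}) == db["r"].sequence


class TestFilterPiles:
    def test_contained_read_recorded_not_edged(self):
        g = simulate_genome(20_000, seed=87).sequence
        reads = [SubRead("big", "big", 0, g[:15_000]),
                 SubRead("small", "small", 0, g[4000:9000])]
        db = build_db(reads, 4000)
        piles = all_vs_all(db)
        edges, contained = filter_piles(piles, db, IntervalTrack())
        assert contained == ["small"]
        assert edges == []

    def test_dovetail_produces_edge_pair(self):
        g = simulate_genome(20_000, seed=88).sequence
        reads = [SubRead("a", "a", 0, g[:12_000]),
                 SubRead("b", "b", 0, g[6000:20_000])]
        db = build_db(reads, 4000)
        edges, contained = filter_piles(all_vs_all(db), db, IntervalTrack())
        assert contained == []
        keys = {(e.u, e.v) for e in edges}
        assert (("a", 1), ("b", 1)) in keys and (("b", -1), ("a", -1)) in keys

    def test_repeat_only_alignment_dropped(self):
        rep = simulate_genome(3000, seed=89).sequence
        ga = simulate_genome(12_000, seed=90).sequence
        gb = simulate_genome(12_000, seed=91).sequence
        a = ga[:6000] + rep + ga[6000:]
        b = gb[:5000] + rep + gb[5000:]
        reads = [SubRead("a", "a", 0, a), SubRead("b", "b", 0, b)]
        db = build_db(reads, 4000)
        track = IntervalTrack({"a": [(6000, 9000)], "b": [(5000, 8000)]})
        edges, contained = filter_piles(all_vs_all(db), db, track)
        assert edges == [] and contained == []


class TestAssemblyStats:
    def test_textbook_example(self):
        st = assembly_stats([10, 7, 5, 3])
        assert st.n50 == 7
        assert st.total_length == 25 and st.contig_count == 4

    def test_single_contig_constant_curve(self):
        st = assembly_stats([42])
        assert st.n_curve == [42] * 101

    def test_curve_endpoints(self):
        st = assembly_stats([10, 7, 5, 3])
        assert st.n_curve[0] == 10 and st.n_curve[100] == 3
        assert all(st.n_curve[i] >= st.n_curve[i + 1] for i in range(100))

    def test_empty_is_all_zero(self):
        st = assembly_stats([])
        assert st.contig_count == 0 and st.n50 == 0 and st.n_curve == [0] * 101

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sort_and_accumulate_oracle(self, seed):
        rng = np.random.default_rng(seed)
        lengths = rng.integers(1, 10_000, int(rng.integers(1, 60))).tolist()
        st = assembly_stats(lengths)
        srt = sorted(lengths, reverse=True)
        total = sum(srt)
        # oracle: smallest contig, taking longest first, reaching x%
        for x in (10, 50, 90, 100):
            acc = 0
            expect = srt[-1]
            for L in srt:
                acc += L
                if acc >= total * x / 100:
                    expect = L
                    break
            assert st.n_curve[x] == expect
        assert all(st.n_curve[i] >= st.n_curve[i + 1] for i in range(100))
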