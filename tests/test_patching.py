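"""Artefact detection on simulated piles, the repeat rule, patch application."""

import numpy as np
import pytest

from olcasm.intervals import IntervalTrack
from olcasm.overlap import AlignmentChain, LocalAlignment, all_vs_all
from olcasm.patching import (ChimeraRuleParams, PatchEvent, apply_chimera_repeat_rule,
                             apply_patches, detect_artefacts)
from olcasm.readstore import SubRead, build_db
from olcasm.simulate import simulate_genome, simulate_reads

from conftest import make_read


@pytest.fixture(scope="module")
def chimera_pile():
    """Error-free 30x pile around one chimeric read."""
    genome = simulate_genome(60_000, seed=71)
    reads, truths = simulate_reads(genome, 30, (8000, 4000), 0.0,
                                   {"chimera": 0.04}, seed=72)
    db = build_db(reads, 4000)
    piles = {p.a_id: p for p in all_vs_all(db)}
    truth = {t.read_id: t for t in truths}
    return db, piles, truth


class TestDetect:
    def test_chimeric_junction_found_within_slack(self, chimera_pile):
        db, piles, truth = chimera_pile
        checked = 0
        for rid, pile in piles.items():
            junctions = [w for k, w in truth[rid].artefacts if k == "chimera"]
            if not junctions:
                continue
            j = junctions[0]
            n = db.length_of(rid)
            if not (600 <= j <= n - 600):
                continue
            events = detect_artefacts(pile, db, IntervalTrack())
            breaks = [e for e in events if e.kind == "chimera_break"]
            assert len(breaks) == 1, rid
            assert abs(breaks[0].begin - j) <= 100
            checked += 1
        assert checked >= 1

    def test_clean_reads_have_no_events(self, chimera_pile):
        db, piles, truth = chimera_pile
        clean_checked = 0
        for rid, pile in piles.items():
            if truth[rid].artefacts:
                continue
            events = detect_artefacts(pile, db, IntervalTrack())
            assert events == [], rid
            clean_checked += 1
            if clean_checked >= 30:
                break
        assert clean_checked >= 10

    def test_empty_pile_no_events(self, chimera_pile):
        db, piles, _ = chimera_pile
        from olcasm.overlap import Pile

        rid = next(iter(piles))
        assert detect_artefacts(Pile(rid, []), db, IntervalTrack()) == []

    def test_foldback_adapter_detected(self):
        genome = simulate_genome(60_000, seed=73)
        reads, truths = simulate_reads(genome, 30, (9000, 5000), 0.0,
                                       {"adapter": 0.04}, seed=74)
        db = build_db(reads, 4000)
        piles = {p.a_id: p for p in all_vs_all(db)}
        truth = {t.read_id: t for t in truths}
        found = checked = 0
        for rid, pile in piles.items():
            folds = [w for k, w in truth[rid].artefacts if k == "adapter"]
            if not folds or rid not in db:
                continue
            n = db.length_of(rid)
            if not (600 <= folds[0] <= n - 600):
                continue
            checked += 1
            events = detect_artefacts(pile, db, IntervalTrack())
            if any(e.kind in ("adapter_break", "strand_jump_break")
                   and abs(e.begin - folds[0]) <= 200 for e in events):
                found += 1
        assert checked >= 1 and found >= checked * 0.7


class TestChimeraRepeatRule:
    def _chain(self, a_begin, a_end, a_len=20_000):
        c = AlignmentChain([LocalAlignment("A", "B", "normal", a_begin, a_end,
                                           0, a_end - a_begin, 0, a_len,
                                           a_end - a_begin)])
        c.status = "proper"
        return c

    def test_two_spanning_chains_exclude(self):
        track = IntervalTrack({"A": [(8000, 13_000)]})  # 5-kb repeat
        chains = [self._chain(7000, 14_000), self._chain(7400, 13_600)]
        assert apply_chimera_repeat_rule("A", chains, track) == "exclude"

    def test_three_spanning_chains_keep(self):
        track = IntervalTrack({"A": [(8000, 13_000)]})
        chains = [self._chain(7000, 14_000), self._chain(7400, 13_600),
                  self._chain(7500, 13_500)]
        assert apply_chimera_repeat_rule("A", chains, track) == "keep"

    def test_repeat_longer_than_limit_not_applied(self):
        track = IntervalTrack({"A": [(5000, 14_000)]})  # 9 kb > 8-kb limit
        assert apply_chimera_repeat_rule("A", [], track,
                                         read_length=20_000) == "keep"

    def test_non_proper_chains_do_not_count(self):
        track = IntervalTrack({"A": [(8000, 13_000)]})
        chains = [self._chain(7000, 14_000) for _ in range(3)]
        for c in chains:
            c.status = "improper"
        assert apply_chimera_repeat_rule("A", chains, track) == "exclude"

    def test_monotone_in_added_chains(self):
        track = IntervalTrack({"A": [(8000, 13_000)]})
        chains = [self._chain(7000, 14_000), self._chain(7400, 13_600)]
        assert apply_chimera_repeat_rule("A", chains, track) == "exclude"
        chains.append(self._chain(6000, 15_000))
        assert apply_chimera_repeat_rule("A", chains, track) == "keep"

    def test_flank_requirement(self):
        # chains touch the repeat but lack the 500-base anchors
        track = IntervalTrack({"A": [(8000, 13_000)]})
        chains = [self._chain(7900, 13_100) for _ in range(5)]
        assert apply_chimera_repeat_rule("A", chains, track) == "exclude"


class TestApplyPatches:
    def test_break_splits_read(self):
        read = make_read("ACGT" * 5000)  # 20 kb
        out = apply_patches(read, [PatchEvent("r1", "chimera_break",
                                              12_000, 12_000)], min_length=4000)
        assert [len(r) for r in out] == [12_000, 8000]
        assert out[0].sequence + out[1].sequence == read.sequence
        assert out[0].read_id.endswith(".part0")

    def test_no_events_identity(self):
        read = make_read("ACGT" * 2000)
        assert apply_patches(read, []) == [read]

    def test_patch_changes_length_by_replacement_delta(self):
        read = make_read("ACGT" * 2500)  # 10 kb
        repl = "G" * 980
        out = apply_patches(read, [PatchEvent("r1", "low_quality_patch",
                                              5000, 6000, repl)], min_length=4000)
        assert len(out) == 1 and len(out[0]) == 10_000 - 20
        assert out[0].sequence[:5000] == read.sequence[:5000]
        assert out[0].sequence[5000:5980] == repl

    def test_short_fragments_discarded(self):
        read = make_read("ACGT" * 2000)  # 8 kb
        out = apply_patches(read, [PatchEvent("r1", "chimera_break",
                                              1000, 1000)], min_length=4000)
        assert [len(r) for r in out] == [7000]

    def test_overlapping_events_rejected(self):
        read = make_read("ACGT" * 2500)
        events = [PatchEvent("r1", "low_quality_patch", 1000, 2000, "A"),
                  PatchEvent("r1", "low_quality_patch", 1500, 2500, "A")]
        with pytest.raises(ValueError, match="overlap"):
            apply_patches(read, events)

    def test_out_of_bounds_rejected(self):
        read = make_read("ACGT" * 100)
        with pytest.raises(ValueError, match="bounds"):
            apply_patches(read, [PatchEvent("r1", "chimera_break", 500, 500)])

    def test_splitting_conserves_sequence(self):
        read = make_read("ACGT" * 3000)
        events = [PatchEvent("r1", "chimera_break", 4000, 4000),
                  PatchEvent("r1", "adapter_break", 8000, 8000)]
        out = apply_patches(read, events, min_length=1000)
        assert "".join(r.sequence for r in out) == read.sequence
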