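"""Read-artefact detection and correction from alignment piles.

Long single-molecule reads carry artefacts — chimeric joins of unrelated
loci, missed-adapter fold-backs, polymerase strand jumps, and long
low-quality stretches — that are the primary impediment to contiguous
assembly.  All of them leave characteristic footprints in a read's alignment
pile:

* a **chimeric junction** is a position no partner alignment spans, although
  alignments end on both sides of it;
* a **missed adapter** makes partners align twice, in opposite orientations,
  to adjacent intervals of the read with mirrored partner coordinates
  (fold-back); a **strand jump** shows the same two-orientation signature
  without the coordinate mirroring;
* a **low-quality segment** keeps normal coverage but an alignment divergence
  well above the pile's baseline.

Breaks split the read; low-quality segments are replaced with the
best-supported partner sequence.  A second, stricter rule targets chimeras
hiding *inside* repeats: any read with a repeat interval up to 8 kb that
cannot be spanned end-to-end (with flanks) by at least three proper alignment
chains is excluded outright.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .intervals import IntervalTrack, contains_point, normalize
from .overlap import (AlignmentChain, LocalAlignment, Pile, COMPLEMENT, NORMAL,
                      PROPER, normalized_ops)
from .readstore import ReadDB, SubRead

log = logging.getLogger(__name__)

KEEP = "keep"
EXCLUDE = "exclude"


@dataclass
class PatchParams:
    """Artefact-detection tunables (all configurable; see methods note)."""

    span_slack: int = 100          # half-width of the spanning test window
    min_flank_support: int = 3     # alignments required on each side of a break
    min_patch_length: int = 400    # shortest low-quality interval patched
    quality_factor: float = 1.5    # cutoff = factor x median segment divergence
    quality_floor: float = 0.03    # absolute divergence floor for the cutoff
    segment: int = 100             # divergence segment width (bases)
    end_margin: int = 500          # no break calls this close to a read end
    support_window: int = 600      # window for counting flank support


@dataclass
class ChimeraRuleParams:
    """The repeat re-analysis rule: repeats up to ``max_repeat_length`` must
    be spanned by at least ``min_spanning_chains`` proper chains with
    ``flank`` anchored bases on each side, or the read is excluded."""

    max_repeat_length: int = 8000
    min_spanning_chains: int = 3
    flank: int = 500

    def __post_init__(self):
        if self.max_repeat_length <= 0 or self.min_spanning_chains <= 0:
            raise ValueError("parameters must be positive")


@dataclass
class PatchEvent:
    """A break (begin == end) or a replacement patch on one read."""

    read_id: str
    kind: str  # chimera_break | adapter_break | strand_jump_break | low_quality_patch
    begin: int
    end: int
    replacement: Optional[str] = None

    def is_break(self) -> bool:
        return self.begin == self.end


def _segment_profile(pile: Pile, read_len: int, seg: int
                     ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(diffs, aligned bases, covering alignments) per fixed-width segment."""
    nseg = (read_len + seg - 1) // seg
    diffs = np.zeros(nseg)
    bases = np.zeros(nseg)
    cover = np.zeros(nseg, dtype=np.int64)
    for aln in pile.alignments:
        d, b = per_segment_counts(aln, seg, nseg)
        diffs += d
        bases += b
        s0 = (aln.a_begin + seg - 1) // seg
        s1 = aln.a_end // seg
        if s1 > s0:
            cover[s0:s1] += 1
        # trailing partial read segment counts as covered when fully aligned
        if aln.a_end == read_len and read_len % seg and s1 < nseg:
            cover[s1] += 1
    return diffs, bases, cover


def per_segment_counts(aln: LocalAlignment, seg: int, nseg: int
                       ) -> Tuple[np.ndarray, np.ndarray]:
    """Distribute an alignment's edit operations over fixed-width segments of
    its A-read (diffs, aligned bases per segment)."""
    diffs = np.zeros(nseg)
    bases = np.zeros(nseg)
    a = aln.a_begin
    for n, op in normalized_ops(aln):
        if op in "=X":
            left = n
            while left:
                m = min(left, seg - a % seg)
                si = a // seg
                bases[si] += m
                if op == "X":
                    diffs[si] += m
                a += m
                left -= m
        elif op == "I":
            left = n
            while left:
                m = min(left, seg - a % seg)
                si = a // seg
                diffs[si] += m
                bases[si] += m
                a += m
                left -= m
        else:  # D: partner-only bases, charge to the current segment
            diffs[min(a // seg, nseg - 1)] += n
    return diffs, bases


def _map_a_to_ob(aln: LocalAlignment, pos: int) -> int:
    """Oriented-B coordinate aligned to A-read position ``pos``."""
    a = aln.a_begin
    ob = aln.b_oriented()[0]
    for n, op in normalized_ops(aln):
        if op in "=X":
            if a + n > pos:
                return ob + (pos - a)
            a += n
            ob += n
        elif op == "I":
            if a + n > pos:
                return ob
            a += n
        else:
            ob += n
    return ob


def detect_artefacts(pile: Pile, db: ReadDB, repeat_track: IntervalTrack,
                     params: Optional[PatchParams] = None) -> List[PatchEvent]:
    """All patch events for one read, from its alignment pile."""
    p = params or PatchParams()
    if not pile.alignments:
        return []
    rid = pile.a_id
    read = db[rid]
    n = len(read)
    events: List[PatchEvent] = []

    # --- fold-back / strand-jump signature ------------------------------
    taken: List[Tuple[int, int]] = []  # intervals claimed by break events
    by_b: Dict[str, List[LocalAlignment]] = {}
    for aln in pile.alignments:
        by_b.setdefault(aln.b_id, []).append(aln)
    fold_points: Dict[str, List[Tuple[int, str]]] = {"adapter": [], "strand_jump": []}
    for b_id, alns in sorted(by_b.items()):
        fwd = [x for x in alns if x.orientation == NORMAL]
        rev = [x for x in alns if x.orientation == COMPLEMENT]
        for x in fwd:
            for y in rev:
                first, second = (x, y) if x.a_begin <= y.a_begin else (y, x)
                gap = second.a_begin - first.a_end
                if not (-2 * p.span_slack <= gap <= 4 * p.span_slack):
                    continue
                ov = min(x.b_end, y.b_end) - max(x.b_begin, y.b_begin)
                mirrored = ov >= 0.5 * min(x.b_span, y.b_span)
                point = (first.a_end + second.a_begin) // 2
                kind = "adapter" if mirrored else "strand_jump"
                fold_points[kind].append((point, b_id))
    for kind, pts in fold_points.items():
        pts.sort()
        i = 0
        while i < len(pts):
            j = i
            while j + 1 < len(pts) and pts[j + 1][0] - pts[i][0] <= 2 * p.span_slack:
                j += 1
            supporters = {b for _, b in pts[i : j + 1]}
            if len(supporters) >= 2:
                point = pts[(i + j) // 2][0]
                if p.end_margin <= point <= n - p.end_margin:
                    events.append(PatchEvent(rid, f"{kind}_break", point, point))
                    taken.append((point - 2 * p.span_slack, point + 2 * p.span_slack))
            i = j + 1

    # --- chimeric junctions: positions no alignment spans ----------------
    diff = np.zeros(n + 1, dtype=np.int64)
    for aln in pile.alignments:
        lo = aln.a_begin + p.span_slack
        hi = aln.a_end - p.span_slack
        if hi > lo:
            diff[lo] += 1
            diff[hi] -= 1
    span_cov = np.cumsum(diff[:-1])
    zero = span_cov == 0
    zero[: p.end_margin] = False
    zero[n - p.end_margin :] = False
    edges = np.flatnonzero(np.diff(np.concatenate(([0], zero.view(np.int8), [0]))))
    ends = sorted(a.a_end for a in pile.alignments)
    begins = sorted(a.a_begin for a in pile.alignments)
    for s, e in zip(edges[0::2].tolist(), edges[1::2].tolist()):
        point = (s + e) // 2
        if contains_point(repeat_track[rid], point):
            continue  # repeat interior: handled by the repeat re-analysis rule
        if any(b <= point < t for b, t in normalize(taken)):
            continue
        lo, hi = s - p.support_window, e + p.support_window
        left = sum(1 for x in ends if lo <= x <= hi)
        right = sum(1 for x in begins if lo <= x <= hi)
        if left >= p.min_flank_support and right >= p.min_flank_support:
            events.append(PatchEvent(rid, "chimera_break", point, point))

    # --- low-quality segments --------------------------------------------
    diffs, bases, cover = _segment_profile(pile, n, p.segment)
    with np.errstate(invalid="ignore", divide="ignore"):
        div = np.where(bases > 0, diffs / np.maximum(bases, 1), -1.0)
    covered = (cover >= 2) & (bases > 0)
    if covered.any():
        median = float(np.median(div[covered]))
        cutoff = max(p.quality_factor * median, p.quality_floor)
        bad = covered & (div > cutoff) & (cover >= p.min_flank_support)
        idx = np.flatnonzero(np.diff(np.concatenate(([0], bad.view(np.int8), [0]))))
        for s, e in zip(idx[0::2].tolist(), idx[1::2].tolist()):
            b0, e0 = s * p.segment, min(e * p.segment, n)
            if e0 - b0 < p.min_patch_length:
                continue
            if any(x.is_break() and b0 <= x.begin < e0 for x in events):
                continue
            repl = _best_replacement(pile, db, b0, e0, cutoff)
            if repl is not None:
                events.append(PatchEvent(rid, "low_quality_patch", b0, e0, repl))

    events.sort(key=lambda ev: (ev.begin, ev.end, ev.kind))
    return events


def _best_replacement(pile: Pile, db: ReadDB, b0: int, e0: int,
                      cutoff: float) -> Optional[str]:
    """Sequence of the best-supported partner across [b0, e0)."""
    margin = 50
    best = None
    for aln in pile.alignments:
        if aln.a_begin > b0 - margin or aln.a_end < e0 + margin:
            continue
        d = aln.diffs / max(aln.a_span, aln.b_span)
        key = (d, aln.b_id, aln.b_begin)
        if best is None or key < best[0]:
            best = (key, aln)
    if best is None:
        return None
    aln = best[1]
    partner = db[aln.b_id].sequence
    bo = partner if aln.orientation == NORMAL else _rc(partner)
    j0 = _map_a_to_ob(aln, b0)
    j1 = _map_a_to_ob(aln, e0)
    if j1 <= j0:
        return None
    return bo[j0:j1]


def _rc(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def apply_chimera_repeat_rule(read_id: str, chains: Sequence[AlignmentChain],
                              repeat_track: IntervalTrack,
                              params: Optional[ChimeraRuleParams] = None,
                              read_length: Optional[int] = None) -> str:
    """keep/exclude decision for one read under the repeat re-analysis rule.

    Every repeat interval on the read not longer than ``max_repeat_length``
    must be covered, with ``flank`` extra bases on both sides, by at least
    ``min_spanning_chains`` proper chains.  Intervals too close to a read end
    to admit both flanks cannot be certified either way and are skipped.
    """
    p = params or ChimeraRuleParams()
    if read_length is None:
        if not chains:
            raise ValueError("read_length required when no chains are given")
        read_length = chains[0].alignments[0].a_length
    proper = [c for c in chains if c.status == PROPER]
    for b, e in repeat_track[read_id]:
        if e - b > p.max_repeat_length:
            continue  # beyond the re-analysis limit: rule not applied
        lo, hi = b - p.flank, e + p.flank
        if lo < 0 or hi > read_length:
            continue
        spanning = sum(1 for c in proper if c.a_begin <= lo and c.a_end >= hi)
        if spanning < p.min_spanning_chains:
            return EXCLUDE
    return KEEP


def apply_patches(read: SubRead, events: Sequence[PatchEvent],
                  min_length: int = 4000) -> List[SubRead]:
    """Split at breaks and substitute low-quality patches.

    Fragments shorter than ``min_length`` are discarded.  Fragments are named
    ``<id>.part<i>`` whenever the read is split; an unsplit (possibly
    patched) read keeps its name.
    """
    if not events:
        return [read]
    evs = sorted(events, key=lambda ev: (ev.begin, ev.end))
    n = len(read)
    last_end = 0
    for ev in evs:
        if not (0 <= ev.begin <= ev.end <= n):
            raise ValueError(f"event out of bounds: {ev}")
        if ev.begin < last_end:
            raise ValueError(f"overlapping events on {read.read_id}")
        last_end = ev.end if ev.end > ev.begin else ev.begin
    fragments: List[str] = []
    parts: List[str] = []
    cursor = 0
    for ev in evs:
        if ev.is_break():
            parts.append(read.sequence[cursor : ev.begin])
            fragments.append("".join(parts))
            parts = []
            cursor = ev.begin
        else:
            parts.append(read.sequence[cursor : ev.begin])
            parts.append(ev.replacement or "")
            cursor = ev.end
    parts.append(read.sequence[cursor:])
    fragments.append("".join(parts))
    out: List[SubRead] = []
    if len(fragments) == 1:
        if len(fragments[0]) >= min_length:
            out.append(SubRead(read.read_id, read.zmw, read.subread_index,
                               fragments[0]))
    else:
        kept = 0
        for i, frag in enumerate(fragments):
            if len(frag) < min_length:
                continue
            rid = f"{read.read_id}.part{i}"
            out.append(SubRead(rid, rid, 0, frag))
            kept += 1
        log.debug("split %s into %d fragments (%d kept)", read.read_id,
                  len(fragments), kept)
    return out
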