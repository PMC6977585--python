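"""Assembly phase: quality track, pile filtering, string graph, touring,
consensus and contiguity statistics.

The layout follows the classic string-graph recipe: proper dovetail chains
between patched reads become edges between oriented reads, contained reads
are set aside, transitively implied edges are removed, and maximal unbranched
paths are toured into primary contigs.  Consensus is a deterministic
column-majority vote of every pile alignment over the path backbone — a
stand-in for signal-level polishing that is exact on error-free data and
reaches ~99% identity at a 10% read error rate with 30x coverage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .intervals import IntervalTrack, intersect, total_length
from .overlap import (AlignmentChain, AlignParams, LocalAlignment, Pile,
                      COMPLEMENT, NORMAL, PROPER, chain_alignments,
                      classify_chain, normalized_ops, revcomp)
from .patching import per_segment_counts
from .readstore import ReadDB

log = logging.getLogger(__name__)

QUALITY_SENTINEL = -1.0

#: oriented read: (read_id, +1 | -1)
Node = Tuple[str, int]


@dataclass
class LayoutParams:
    segment: int = 100            # quality-track segment width (bases)
    end_slack: int = 25           # dovetail slack at read ends
    fuzz: int = 200               # transitive-reduction length tolerance
    repeat_cov_factor: float = 2.0  # detailed repeat mask coverage multiple
    min_quality_cov: int = 2      # below this, quality is the sentinel


# ---------------------------------------------------------------------------
# quality track and detailed repeat mask

def quality_track(pile: Pile, read_length: int, segment: int = 100,
                  min_cov: int = 2) -> np.ndarray:
    """Mean alignment divergence per fixed-width segment of the A-read;
    sentinel (-1) where fewer than ``min_cov`` partners cover the segment."""
    nseg = (read_length + segment - 1) // segment
    diffs = np.zeros(nseg)
    bases = np.zeros(nseg)
    cover = np.zeros(nseg, dtype=np.int64)
    for aln in pile.alignments:
        d, b = per_segment_counts(aln, segment, nseg)
        diffs += d
        bases += b
        s0 = (aln.a_begin + segment - 1) // segment
        s1 = aln.a_end // segment
        if aln.a_end == read_length and read_length % segment:
            s1 += 1
        if s1 > s0:
            cover[s0:min(s1, nseg)] += 1
    out = np.full(nseg, QUALITY_SENTINEL)
    ok = (cover >= min_cov) & (bases > 0)
    out[ok] = diffs[ok] / bases[ok]
    return out


def detailed_repeat_mask(piles: Sequence[Pile], db: ReadDB,
                         expected_coverage: float,
                         factor: float = 2.0) -> IntervalTrack:
    """Repeat intervals from patched-read piles: regions whose distinct-read
    alignment coverage exceeds ``factor`` times the expected coverage."""
    from .masking import coverage_mask_from_piles

    threshold = max(int(np.ceil(factor * expected_coverage)), 2)
    lengths = {r.read_id: len(r) for r in db}
    return coverage_mask_from_piles(piles, threshold, lengths)


# ---------------------------------------------------------------------------
# pile filtering -> string graph edges

@dataclass
class OverlapEdge:
    """A dovetail overlap as a directed edge between oriented reads.

    Following the edge appends ``oriented(v)[v_trim:]`` to a contig ending at
    ``u``.  ``overlap_length`` is the aligned span on the source read.
    """

    u: Node
    v: Node
    overlap_length: int
    diffs: int
    v_trim: int

    @property
    def from_end(self) -> Tuple[str, str]:
        return (self.u[0], "right" if self.u[1] > 0 else "left")

    @property
    def to_end(self) -> Tuple[str, str]:
        return (self.v[0], "left" if self.v[1] > 0 else "right")

    @property
    def orientation(self) -> str:
        return NORMAL if self.u[1] == self.v[1] else COMPLEMENT

    def key(self):
        return (self.u, self.v)


def _edge_pair(a_id: str, b_id: str, o: int, chain: AlignmentChain,
               direction: str) -> List[OverlapEdge]:
    """Directed edge + its reverse-complement twin for one dovetail chain.

    ``o`` is +1 for normal, -1 for complement; ``direction`` 'ab' means A's
    suffix overlaps oriented-B's prefix.
    """
    first = chain.alignments[0]
    a_len, b_len = first.a_length, first.b_length
    ab, ae = chain.a_begin, chain.a_end
    bb, be = chain.ob_begin(), chain.ob_end()
    ov = ae - ab
    if direction == "ab":
        return [
            OverlapEdge((a_id, 1), (b_id, o), ov, chain.diffs, be),
            OverlapEdge((b_id, -o), (a_id, -1), ov, chain.diffs, a_len - ab),
        ]
    return [
        OverlapEdge((b_id, o), (a_id, 1), ov, chain.diffs, ae),
        OverlapEdge((a_id, -1), (b_id, -o), ov, chain.diffs, b_len - bb),
    ]


def filter_piles(piles: Sequence[Pile], db: ReadDB, repeat_track: IntervalTrack,
                 quality: Optional[Dict[str, np.ndarray]] = None,
                 align_params: Optional[AlignParams] = None,
                 layout_params: Optional[LayoutParams] = None,
                 ) -> Tuple[List[OverlapEdge], List[str]]:
    """Keep proper dovetail chains as graph edges; record containments.

    Alignments lying entirely within repeat intervals on both reads are
    dropped before chaining (they carry no layout information), and reads
    fully covered by a partner are recorded as contained and excluded from
    the graph.
    """
    ap = align_params or AlignParams()
    lp = layout_params or LayoutParams()
    slack = lp.end_slack
    edges: Dict[Tuple[Node, Node], OverlapEdge] = {}
    contained: Set[str] = set()
    for pile in piles:
        a_id = pile.a_id
        for (b_id, orientation), alns in sorted(pile.by_pair().items()):
            if db.index_of(b_id) <= db.index_of(a_id):
                continue  # each unordered pair handled from the lower index
            kept = []
            for aln in alns:
                in_rep_a = total_length(intersect(
                    [(aln.a_begin, aln.a_end)], repeat_track[a_id])) == aln.a_span
                in_rep_b = total_length(intersect(
                    [(aln.b_begin, aln.b_end)], repeat_track[b_id])) == aln.b_span
                if in_rep_a and in_rep_b and aln.a_span > 0:
                    continue
                kept.append(aln)
            if not kept:
                continue
            for chain in chain_alignments(kept, ap.max_gap):
                if classify_chain(chain, repeat_track, slack) != PROPER:
                    continue
                first = chain.alignments[0]
                a_len, b_len = first.a_length, first.b_length
                a_l = chain.a_begin <= slack
                a_r = chain.a_end >= a_len - slack
                b_l = chain.ob_begin() <= slack
                b_r = chain.ob_end() >= b_len - slack
                o = 1 if orientation == NORMAL else -1
                if b_l and b_r:
                    # B contained in A (identical reads: contain the later one)
                    contained.add(b_id if not (a_l and a_r) or
                                  db.index_of(b_id) > db.index_of(a_id) else a_id)
                elif a_l and a_r:
                    contained.add(a_id)
                elif a_r and b_l:
                    for e in _edge_pair(a_id, b_id, o, chain, "ab"):
                        _add_edge(edges, e)
                elif a_l and b_r:
                    for e in _edge_pair(a_id, b_id, o, chain, "ba"):
                        _add_edge(edges, e)
    out = [edges[k] for k in sorted(edges)]
    out = [e for e in out
           if e.u[0] not in contained and e.v[0] not in contained]
    return out, sorted(contained)


def _add_edge(edges: Dict[Tuple[Node, Node], OverlapEdge], e: OverlapEdge) -> None:
    cur = edges.get(e.key())
    if cur is None or (e.overlap_length, -e.diffs) > (cur.overlap_length, -cur.diffs):
        edges[e.key()] = e


# ---------------------------------------------------------------------------
# transitive reduction

def transitive_reduction(edges: Sequence[OverlapEdge], fuzz: int = 200,
                         read_lengths: Optional[Dict[str, int]] = None,
                         ) -> List[OverlapEdge]:
    """Remove edges implied by a two-edge path with consistent lengths.

    Edges are examined weakest-overlap-first and removed only when a two-edge
    path of *remaining* edges implies them (advance lengths agreeing within
    ``fuzz``), so pairwise reachability between oriented reads is preserved by
    construction.  The reverse-complement twin of a removed edge is removed
    with it to keep the graph skew-symmetric.
    """
    adv = {}
    out_adj: Dict[Node, Dict[Node, OverlapEdge]] = {}
    for e in edges:
        if e.overlap_length <= 0 or e.v_trim < 0:
            log.warning("dropping inconsistent edge %s -> %s", e.u, e.v)
            continue
        out_adj.setdefault(e.u, {})[e.v] = e
        adv[(e.u, e.v)] = _advance(e, read_lengths)
    alive = dict(adv)
    order = sorted(adv, key=lambda k: (-adv[k], k))
    for (u, w) in order:
        if (u, w) not in alive:
            continue
        target = adv[(u, w)]
        implied = False
        for v, e_uv in sorted(out_adj.get(u, {}).items()):
            if v == w or (u, v) not in alive:
                continue
            e_vw = out_adj.get(v, {}).get(w)
            if e_vw is None or (v, w) not in alive:
                continue
            if abs(adv[(u, v)] + adv[(v, w)] - target) <= 2 * fuzz:
                implied = True
                break
        if implied:
            del alive[(u, w)]
            twin = ((w[0], -w[1]), (u[0], -u[1]))
            alive.pop(twin, None)
    return [out_adj[u][v] for (u, v) in sorted(alive)]


def _advance(e: OverlapEdge, read_lengths: Optional[Dict[str, int]]) -> int:
    if read_lengths is not None:
        return read_lengths[e.v[0]] - e.v_trim
    # fall back: advance encoded by trim against the edge itself is unknown;
    # use overlap-relative ordering (larger overlap = smaller advance)
    return -e.overlap_length


# ---------------------------------------------------------------------------
# touring

@dataclass
class Contig:
    """A toured path with its consensus sequence."""

    name: str
    path: List[Node]
    edges: List[OverlapEdge]
    sequence: str = ""
    circular: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


def tour(edges: Sequence[OverlapEdge], db: ReadDB,
         contained: Iterable[str] = ()) -> List[Contig]:
    """Traverse maximal unbranched paths into primary contig paths.

    Tips (no incoming edge) are toured first; at a branch the extension with
    the most aligned bases wins (ties: fewer diffs, then smaller read index).
    Remaining cycles are toured from their smallest read and flagged circular.
    Contained reads never start or join a path.
    """
    contained = set(contained)
    adj: Dict[Node, List[OverlapEdge]] = {}
    indeg: Dict[Node, int] = {}
    for e in edges:
        adj.setdefault(e.u, []).append(e)
        indeg[e.v] = indeg.get(e.v, 0) + 1
    for u in adj:
        adj[u].sort(key=lambda e: (-e.overlap_length, e.diffs,
                                   db.index_of(e.v[0]), -e.v[1]))
    used: Set[str] = set(contained)
    contigs: List[Contig] = []

    def _walk(start: Node) -> Contig:
        path = [start]
        path_edges: List[OverlapEdge] = []
        used.add(start[0])
        cur = start
        circular = False
        while True:
            nxt = None
            for e in adj.get(cur, []):
                if e.v == start and len(path) > 1:
                    path_edges.append(e)
                    circular = True
                    break
                if e.v[0] not in used:
                    nxt = e
                    break
            if circular or nxt is None:
                break
            path.append(nxt.v)
            path_edges.append(nxt)
            used.add(nxt.v[0])
            cur = nxt.v
        return Contig(name="", path=path, edges=path_edges, circular=circular)

    nodes = sorted(set(adj) | set(indeg), key=lambda u: (db.index_of(u[0]), -u[1]))
    for u in nodes:
        if u[0] in used or indeg.get(u, 0) > 0:
            continue
        contigs.append(_walk(u))
    for u in nodes:  # remaining components are cycles
        if u[0] in used:
            continue
        contigs.append(_walk(u))
    for r in db:
        if r.read_id not in used:
            contigs.append(Contig(name="", path=[(r.read_id, 1)], edges=[]))
            used.add(r.read_id)
    for i, c in enumerate(contigs):
        c.name = f"contig_{i + 1}"
    return contigs


# ---------------------------------------------------------------------------
# consensus

def _oriented(seq: str, sign: int) -> str:
    return seq if sign > 0 else revcomp(seq)


def consensus(contig: Contig, db: ReadDB,
              piles: Optional[Dict[str, Pile]] = None) -> str:
    """Column-majority consensus over the path backbone.

    The backbone concatenates the path's oriented reads trimmed at edge
    overlaps.  Every pile alignment of a path read casts per-column votes
    (substitution, deletion, or insertion); a strict majority against the
    backbone applies the change, ties keep the backbone.  Deterministic, and
    the identity on error-free input.
    """
    segments: List[Tuple[str, int, int, int]] = []  # (read, sign, or_start, offset)
    parts: List[str] = []
    offset = 0
    rid, sign = contig.path[0]
    seq = _oriented(db[rid].sequence, sign)
    segments.append((rid, sign, 0, offset))
    parts.append(seq)
    offset += len(seq)
    for e in contig.edges:
        if e.v == contig.path[0] and contig.circular:
            break
        rid, sign = e.v
        seq = _oriented(db[rid].sequence, sign)[e.v_trim:]
        segments.append((rid, sign, e.v_trim, offset))
        parts.append(seq)
        offset += len(seq)
    backbone = "".join(parts)
    if not piles:
        return backbone
    m = len(backbone)
    cov = np.zeros(m + 1, dtype=np.int64)
    alt: Dict[int, Dict[str, int]] = {}     # col -> base -> votes (non-backbone)
    gaps: Dict[int, int] = {}               # col -> deletion votes
    ins: Dict[int, Dict[str, int]] = {}     # col -> inserted seq -> votes

    comp = str.maketrans("ACGTN", "TGCAN")
    for rid, sign, or_start, off in segments:
        pile = piles.get(rid)
        if pile is None:
            continue
        rlen = db.length_of(rid)
        for aln in pile.alignments:
            bo = _oriented(db[aln.b_id].sequence, 1 if aln.orientation == NORMAL else -1)
            a = aln.a_begin
            j = aln.b_oriented()[0]

            def col_of(a_pos: int) -> int:
                if sign > 0:
                    c = a_pos - or_start
                else:
                    c = (rlen - 1 - a_pos) - or_start
                return off + c if c >= 0 else -1

            # coverage over the backbone columns this alignment spans
            c0 = col_of(aln.a_begin)
            c1 = col_of(aln.a_end - 1)
            lo, hi = (c0, c1) if c0 <= c1 else (c1, c0)
            lo = max(lo, off)
            if hi >= lo:
                cov[lo] += 1
                cov[hi + 1] -= 1
            for n, op in normalized_ops(aln):
                if op == "=":
                    a += n
                    j += n
                elif op == "X":
                    for t in range(n):
                        col = col_of(a + t)
                        if col >= off:
                            base = bo[j + t]
                            if sign < 0:
                                base = base.translate(comp)
                            alt.setdefault(col, {})[base] = \
                                alt.get(col, {}).get(base, 0) + 1
                    a += n
                    j += n
                elif op == "I":
                    for t in range(n):
                        col = col_of(a + t)
                        if col >= off:
                            gaps[col] = gaps.get(col, 0) + 1
                    a += n
                else:  # D: partner-only bases between columns a-1 and a
                    piece = bo[j : j + n]
                    if sign > 0:
                        col = col_of(a)
                        ins_seq = piece
                    else:
                        cprev = col_of(a - 1) if a > aln.a_begin else -1
                        col = cprev if cprev >= off else -1
                        ins_seq = piece.translate(comp)[::-1]
                    if col >= off:
                        d = ins.setdefault(col, {})
                        d[ins_seq] = d.get(ins_seq, 0) + 1
                    j += n

    coverage = np.cumsum(cov[:-1])
    out: List[str] = []
    for col in range(m):
        bb = backbone[col]
        n_other = sum(alt.get(col, {}).values()) + gaps.get(col, 0)
        n_bb = int(coverage[col]) - n_other + 1  # backbone read's own vote
        best_base, best_n = bb, n_bb
        for base in sorted(alt.get(col, {})):
            if alt[col][base] > best_n:
                best_base, best_n = base, alt[col][base]
        if gaps.get(col, 0) > best_n:
            best_base = ""
        if col in ins:
            # decide on the total insertion evidence, then take the
            # plurality sequence (votes may split over near-identical seqs)
            total_i = sum(ins[col].values())
            if total_i * 2 > coverage[col] + 1:
                items = sorted(ins[col].items(), key=lambda kv: (-kv[1], kv[0]))
                out.append(items[0][0])
        out.append(best_base)
    return "".join(out)


def polish(sequence: str, db: ReadDB, params: Optional[AlignParams] = None,
           rounds: int = 1) -> str:
    """Additional consensus rounds: re-map the reads onto the current
    consensus and redo the column-majority vote.

    A second round re-anchors indel votes that were diluted by a noisy
    backbone (the classic two-round polishing effect); on error-free input it
    is the identity.
    """
    from .overlap import map_to_reference
    from .readstore import SubRead

    name = "__consensus__"
    for _ in range(rounds):
        if not sequence:
            break
        alns = map_to_reference(list(db), name, sequence, params)
        pile = Pile(name, sorted((a.mirrored() for a in alns),
                                 key=LocalAlignment.sort_key))
        tmp = ReadDB([SubRead(name, name, 0, sequence)] + list(db))
        contig = Contig(name, [(name, 1)], [])
        sequence = consensus(contig, tmp, {name: pile})
    return sequence


# ---------------------------------------------------------------------------
# statistics

@dataclass
class AssemblyStats:
    contig_count: int
    total_length: int
    n_curve: List[int] = field(default_factory=list)  # index x = 0..100
    n50: int = 0

    def to_dict(self) -> dict:
        return {"contig_count": self.contig_count,
                "total_length": self.total_length,
                "n50": self.n50, "n_curve": self.n_curve}


def assembly_stats(lengths: Sequence[int]) -> AssemblyStats:
    """N(x) curve: the length of the smallest contig needed, longest-first,
    to reach x% of the total assembly; N50 = N(50)."""
    lengths = sorted((int(x) for x in lengths), reverse=True)
    total = sum(lengths)
    if not lengths or total == 0:
        return AssemblyStats(0, 0, [0] * 101, 0)
    cum = np.cumsum(lengths)
    curve = [lengths[0]]
    for x in range(1, 101):
        need = total * x / 100.0
        i = int(np.searchsorted(cum, need, side="left"))
        curve.append(lengths[min(i, len(lengths) - 1)])
    return AssemblyStats(len(lengths), total, curve, curve[50])


# ---------------------------------------------------------------------------
# export

def write_gfa(contig_edges: Sequence[OverlapEdge], db: ReadDB, path,
              contained: Iterable[str] = ()) -> None:
    """String graph as GFA 1: S lines for reads in the graph, L lines for
    dovetail edges (overlap as a CIGAR match length)."""
    contained = set(contained)
    in_graph = sorted({u[0] for e in contig_edges for u in (e.u, e.v)},
                      key=lambda r: 0 if r not in contained else 1)
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for rid in in_graph:
            fh.write(f"S\t{rid}\t{db[rid].sequence}\n")
        for e in contig_edges:
            if e.u > (e.v[0], -e.v[1]):  # one record per edge pair
                continue
            fh.write("L\t{}\t{}\t{}\t{}\t{}M\n".format(
                e.u[0], "+" if e.u[1] > 0 else "-",
                e.v[0], "+" if e.v[1] > 0 else "-",
                e.overlap_length))


def write_contigs_fasta(contigs: Sequence[Contig], path) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            circ = " circular=true" if c.circular else ""
            fh.write(f">{c.name} reads={len(c.path)}{circ}\n")
            for i in range(0, len(c.sequence), 80):
                fh.write(c.sequence[i : i + 80] + "\n")


def write_stats_json(stats: AssemblyStats, path) -> None:
    with open(path, "w") as fh:
        json.dump(stats.to_dict(), fh, indent=1)
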