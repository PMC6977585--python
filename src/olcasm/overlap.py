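"""Mask-aware k-mer-seeded pairwise local alignment, chaining, and piles.

The aligner follows the classic seed–cluster–extend recipe used by long-read
overlappers: exact k-mer matches (seeds) whose start lies outside the repeat
mask of both reads are clustered by diagonal, each cluster is extended outward
in chunks with a banded edit-distance check, and the final segment is
re-aligned globally so that the reported ``diffs`` is exactly the edit
distance of the reported segments.  B-read coordinates are always stored on
B's forward strand together with an orientation flag; all coordinates are
0-based half-open.

Alignments between one read pair are organised into co-linear
:class:`AlignmentChain` objects; a chain is *proper* when both of its ends
reach a read boundary (of either read), the signal used to distinguish true
dovetail overlaps from repeat-induced partial matches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import edlib
import numpy as np

from .intervals import Interval, IntervalTrack, contains_point

log = logging.getLogger(__name__)

NORMAL = "normal"
COMPLEMENT = "complement"

PROPER = "proper"
PREMATURE_IN_REPEAT = "premature_in_repeat"
IMPROPER = "improper"

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class AlignParams:
    """Tunables of the seed-and-extend aligner.

    Defaults follow common long-read overlapper practice: a 14-mer seed with
    at least 3 seeds per diagonal cluster before extension, a divergence
    ceiling of 0.30 (two ~15%-error reads), and a 600-base minimum alignment
    length.  ``end_slack`` is how close to a read end a chain must reach to be
    called proper.
    """

    k: int = 14
    min_seeds: int = 3
    seed_sample: int = 4
    diag_gap: int = 100
    max_divergence: float = 0.30
    min_alignment_length: int = 600
    end_slack: int = 25
    max_gap: int = 1500
    chunk: int = 1000
    min_chunk: int = 32
    max_candidates_per_pair: int = 30


@dataclass
class LocalAlignment:
    """A pairwise local alignment; B coordinates on B's forward strand."""

    a_id: str
    b_id: str
    orientation: str
    a_begin: int
    a_end: int
    b_begin: int
    b_end: int
    diffs: int
    a_length: int
    b_length: int
    #: extended cigar over (query, target); which read is the query is given
    #: by ``cigar_query`` ('a': query = A fwd segment, target = B oriented
    #: segment; 'b': the transpose, as stored on mirrored records).
    cigar: Optional[str] = None
    cigar_query: str = "a"

    @property
    def a_span(self) -> int:
        return self.a_end - self.a_begin

    @property
    def b_span(self) -> int:
        return self.b_end - self.b_begin

    @property
    def identity(self) -> float:
        m = max(self.a_span, self.b_span)
        return 1.0 - self.diffs / m if m else 1.0

    def b_oriented(self) -> Tuple[int, int]:
        """B interval in oriented-B coordinates (rc coordinates if complement)."""
        if self.orientation == NORMAL:
            return self.b_begin, self.b_end
        return self.b_length - self.b_end, self.b_length - self.b_begin

    def mirrored(self) -> "LocalAlignment":
        """The same alignment seen from the B-read's pile."""
        return LocalAlignment(
            a_id=self.b_id,
            b_id=self.a_id,
            orientation=self.orientation,
            a_begin=self.b_begin,
            a_end=self.b_end,
            b_begin=self.a_begin,
            b_end=self.a_end,
            diffs=self.diffs,
            a_length=self.b_length,
            b_length=self.a_length,
            cigar=self.cigar,
            cigar_query="b" if self.cigar_query == "a" else "a",
        )

    def sort_key(self):
        return (self.a_id, self.b_id, self.orientation, self.a_begin,
                self.a_end, self.b_begin, self.b_end)


_OPS = {"=": 0, "X": 1, "I": 2, "D": 3}


def parse_cigar(cigar: str) -> List[Tuple[int, str]]:
    out = []
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + ord(ch) - 48
        else:
            out.append((n, ch))
            n = 0
    return out


def normalized_ops(aln: LocalAlignment) -> List[Tuple[int, str]]:
    """Cigar ops with query = this record's A fwd segment, target = its
    oriented B segment (mirrored records are transposed, and reversed for
    complement orientation, to restore that convention)."""
    if aln.cigar is None:
        raise ValueError("alignment has no cigar")
    ops = parse_cigar(aln.cigar)
    if aln.cigar_query == "b":
        swap = {"I": "D", "D": "I", "=": "=", "X": "X"}
        ops = [(n, swap[op]) for n, op in ops]
        if aln.orientation == COMPLEMENT:
            ops.reverse()
    return ops


@dataclass
class AlignmentChain:
    """An ordered, co-linear set of alignments between one read pair."""

    alignments: List[LocalAlignment]
    status: Optional[str] = None

    @property
    def a_id(self) -> str:
        return self.alignments[0].a_id

    @property
    def b_id(self) -> str:
        return self.alignments[0].b_id

    @property
    def orientation(self) -> str:
        return self.alignments[0].orientation

    @property
    def a_begin(self) -> int:
        return self.alignments[0].a_begin

    @property
    def a_end(self) -> int:
        return self.alignments[-1].a_end

    def ob_begin(self) -> int:
        return self.alignments[0].b_oriented()[0]

    def ob_end(self) -> int:
        return self.alignments[-1].b_oriented()[1]

    @property
    def aligned_a(self) -> int:
        return sum(a.a_span for a in self.alignments)

    @property
    def aligned_b(self) -> int:
        return sum(a.b_span for a in self.alignments)

    @property
    def diffs(self) -> int:
        return sum(a.diffs for a in self.alignments)

    def score(self) -> Tuple[int, int, tuple]:
        return (self.aligned_a + self.aligned_b, -self.diffs,
                tuple(-c for a in self.alignments for c in
                      (a.a_begin, a.b_begin)))

    def __len__(self) -> int:
        return len(self.alignments)


@dataclass
class Pile:
    """All local alignments sharing a fixed A-read."""

    a_id: str
    alignments: List[LocalAlignment] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.alignments)

    def by_pair(self) -> Dict[Tuple[str, str], List[LocalAlignment]]:
        groups: Dict[Tuple[str, str], List[LocalAlignment]] = {}
        for a in self.alignments:
            groups.setdefault((a.b_id, a.orientation), []).append(a)
        return groups


# ---------------------------------------------------------------------------
# k-mer machinery

def _encode(seq: str) -> Tuple[np.ndarray, np.ndarray]:
    """2-bit encode; returns (codes 0..3 with N as 0, isN mask)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int64)
    lut[ord("C")] = 1
    lut[ord("G")] = 2
    lut[ord("T")] = 3
    isn = arr == ord("N")
    return lut[arr], isn


def _sample_keep(codes: np.ndarray, sample: int) -> np.ndarray:
    """Deterministic hash-based seed subsampling (same criterion on both the
    index and the query side, so sampling never breaks seed pairing)."""
    if sample <= 1:
        return np.ones(len(codes), dtype=bool)
    h = (codes * np.int64(2654435761)) & np.int64(0xFFFFFFFF)
    return h < (1 << 32) // sample


def kmer_codes(seq: str, k: int, masked: Sequence[Interval] = (),
               sample: int = 1) -> Tuple[np.ndarray, np.ndarray]:
    """(positions, codes) of valid k-mers: no N inside, start unmasked."""
    n = len(seq)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    codes, isn = _encode(seq)
    m = n - k + 1
    out = np.zeros(m, dtype=np.int64)
    for j in range(k):
        out = out * 4 + codes[j : j + m]
    csn = np.concatenate(([0], np.cumsum(isn)))
    valid = (csn[k:] - csn[:-k]) == 0
    allowed = np.ones(m, dtype=bool)
    for b, e in masked:
        allowed[max(b, 0) : min(e, m)] = False
    keep = valid & allowed & _sample_keep(out, sample)
    pos = np.flatnonzero(keep)
    return pos, out[pos]


def rc_kmer_codes(seq: str, k: int, masked: Sequence[Interval] = (),
                  sample: int = 1) -> Tuple[np.ndarray, np.ndarray]:
    """(forward positions, codes of the reverse-complement k-mer at each)."""
    pos, _ = kmer_codes(seq, k, masked)
    rpos, rcodes = kmer_codes(revcomp(seq), k)
    # rc k-mer starting at fwd position i is the k-mer at n-k-i of revcomp(seq)
    n = len(seq)
    lookup = np.full(max(n - k + 1, 1), -1, dtype=np.int64)
    lookup[rpos] = rcodes
    codes = lookup[n - k - pos]
    ok = codes >= 0
    pos, codes = pos[ok], codes[ok]
    ok = _sample_keep(codes, sample)
    return pos[ok], codes[ok]


# ---------------------------------------------------------------------------
# extension

def _extend_dir(a_part: str, b_part: str, p: AlignParams) -> Tuple[int, int, int]:
    """Greedy chunked extension of an alignment into (a_part, b_part),
    both read in the forward direction from index 0.

    Returns (a_advance, b_advance, diffs).  Each chunk is accepted while its
    banded edit distance stays within ``max_divergence``; on rejection the
    chunk is halved down to ``min_chunk``, which localizes the divergence
    point (e.g. a chimeric junction) to within a few tens of bases.
    """
    xa = xb = d = 0
    chunk = p.chunk
    na, nb = len(a_part), len(b_part)
    while xa < na and xb < nb:
        ra, rb = na - xa, nb - xb
        a_is_query = ra <= rb
        rq = ra if a_is_query else rb
        c = min(chunk, rq)
        tcap = c + c // 3 + 64
        if a_is_query:
            q = a_part[xa : xa + c]
            t = b_part[xb : xb + min(rb, tcap)]
        else:
            q = b_part[xb : xb + c]
            t = a_part[xa : xa + min(ra, tcap)]
        lim = int(p.max_divergence * c) + 1
        res = edlib.align(q, t, mode="SHW", task="locations", k=lim)
        ed = res["editDistance"]
        if ed >= 0 and ed <= p.max_divergence * c:
            t_adv = res["locations"][0][1] + 1
            if a_is_query:
                xa += c
                xb += t_adv
            else:
                xb += c
                xa += t_adv
            d += ed
            chunk = p.chunk
        else:
            if c <= p.min_chunk:
                break
            chunk = max(c // 2, p.min_chunk)
    # force the last few bases onto a read end: classification slack is
    # smaller than the chunk granularity, so a true dovetail must not stop
    # a sub-chunk short of the boundary
    rem = min(na - xa, nb - xb)
    if 0 < rem <= p.min_chunk:
        a_is_query = (na - xa) <= (nb - xb)
        if a_is_query:
            q, t = a_part[xa:], b_part[xb : xb + rem + rem // 2 + 16]
        else:
            q, t = b_part[xb:], a_part[xa : xa + rem + rem // 2 + 16]
        res = edlib.align(q, t, mode="SHW", task="locations")
        ed = res["editDistance"]
        if ed >= 0 and ed <= max(p.max_divergence * len(q), 0.45 * len(q) + 4):
            t_adv = res["locations"][0][1] + 1
            if a_is_query:
                xa += len(q)
                xb += t_adv
            else:
                xb += len(q)
                xa += t_adv
            d += ed
    return xa, xb, d


def _best_scoring_window(cigar: str, match: int = 1, penalty: int = 2
                         ) -> Tuple[int, int, int, int]:
    """Max-scoring contiguous run window of an extended cigar (Kadane).

    Scores +match per matching column and -penalty per difference, so noisy
    tails (e.g. a chunk that slid past a chimeric junction into unrelated
    sequence) are trimmed off.  Returns (query_trim_left, target_trim_left,
    query_trim_right, target_trim_right) in consumed bases.
    """
    runs = parse_cigar(cigar)
    score = best = cur = 0
    q = t = 0
    cur_start = (0, 0)
    best_bounds = None  # ((ql, tl), (qr, tr))
    for n, op in runs:
        s = n * match if op == "=" else -n * penalty
        if cur <= 0:
            cur = 0
            cur_start = (q, t)
        cur += s
        if op in "=X":
            q += n
            t += n
        elif op == "I":
            q += n
        else:
            t += n
        if cur > best:
            best = cur
            best_bounds = (cur_start, (q, t))
    if best_bounds is None:
        return 0, 0, 0, 0
    (ql, tl), (qr, tr) = best_bounds
    return ql, tl, q - qr, t - tr


def _align_segment(a_seq: str, bo_seq: str, ab: int, ae: int, bb: int, be: int,
                   p: AlignParams) -> Optional[Tuple[int, str]]:
    """Exact global alignment of the reported segments; (diffs, cigar)."""
    span = max(ae - ab, be - bb)
    lim = int(p.max_divergence * span) + 64
    res = edlib.align(a_seq[ab:ae], bo_seq[bb:be], mode="NW", task="path", k=lim)
    if res["editDistance"] < 0:
        return None
    return res["editDistance"], res["cigar"]


def _extend_cluster(a_seq: str, bo_seq: str, seeds: List[Tuple[int, int]],
                    p: AlignParams) -> Optional[Tuple[int, int, int, int, int, str]]:
    """Extend a co-linear seed cluster to a trimmed local alignment.

    ``seeds`` are (a_pos, oriented_b_pos) k-mer start pairs on one diagonal
    band.  Returns (ab, ae, bb, be, diffs, cigar) or None.
    """
    seeds = sorted(set(seeds))
    chain = []
    last_a = last_b = -1
    for i, j in seeds:
        if i > last_a and j > last_b:
            chain.append((i, j))
            last_a, last_b = i, j
    if len(chain) < p.min_seeds:
        return None
    i0, j0 = chain[0]
    i1, j1 = chain[-1]
    la, lb, dl = _extend_dir(a_seq[:i0][::-1], bo_seq[:j0][::-1], p)
    ra, rb, dr = _extend_dir(a_seq[i1 + p.k:], bo_seq[j1 + p.k:], p)
    ab, bb = i0 - la, j0 - lb
    ae, be = i1 + p.k + ra, j1 + p.k + rb
    if min(ae - ab, be - bb) < p.min_alignment_length:
        return None
    if (dl + dr == 0 and ae - ab == be - bb
            and a_seq[ab:ae] == bo_seq[bb:be]):
        # identical segments: skip the global re-alignment
        diffs, cigar = 0, f"{ae - ab}="
    else:
        res = _align_segment(a_seq, bo_seq, ab, ae, bb, be, p)
        if res is None:
            return None
        diffs, cigar = res
        ql, tl, qr, tr = _best_scoring_window(cigar)
        if max(ql, tl) > 15 or max(qr, tr) > 15:
            ab, bb, ae, be = ab + ql, bb + tl, ae - qr, be - tr
            if min(ae - ab, be - bb) < p.min_alignment_length:
                return None
            res = _align_segment(a_seq, bo_seq, ab, ae, bb, be, p)
            if res is None:
                return None
            diffs, cigar = res
    if 1.0 - diffs / max(ae - ab, be - bb) < 1.0 - p.max_divergence:
        return None
    return ab, ae, bb, be, diffs, cigar


def _cluster_seeds(a_pos: np.ndarray, b_pos: np.ndarray, p: AlignParams,
                   min_diag_offset: int = 0) -> List[List[Tuple[int, int]]]:
    """Split seeds (oriented coordinates) into diagonal clusters."""
    diag = a_pos - b_pos
    order = np.lexsort((a_pos, diag))
    diag_s = diag[order]
    splits = np.flatnonzero(np.diff(diag_s) > p.diag_gap) + 1
    clusters = []
    for s, e in zip(np.concatenate(([0], splits)),
                    np.concatenate((splits, [len(order)]))):
        if e - s < p.min_seeds:
            continue
        idx = order[s:e]
        if min_diag_offset and abs(int(np.median(diag[idx]))) < min_diag_offset:
            continue
        sub = idx[:500]
        clusters.append(list(zip(a_pos[sub].tolist(), b_pos[sub].tolist())))
    return clusters


def _dedupe(alns: List[LocalAlignment]) -> List[LocalAlignment]:
    alns = sorted(alns, key=lambda a: (-(a.a_span + a.b_span), a.sort_key()))
    kept: List[LocalAlignment] = []
    for a in alns:
        redundant = False
        for b in kept:
            if b.orientation != a.orientation or b.b_id != a.b_id:
                continue
            oa = min(a.a_end, b.a_end) - max(a.a_begin, b.a_begin)
            ob = min(a.b_end, b.b_end) - max(a.b_begin, b.b_begin)
            if oa > 0.5 * a.a_span and ob > 0.5 * a.b_span:
                redundant = True
                break
        if not redundant:
            kept.append(a)
    kept.sort(key=LocalAlignment.sort_key)
    return kept


def local_align(a: str, b: str, mask_a: Sequence[Interval] = (),
                mask_b: Sequence[Interval] = (), params: Optional[AlignParams] = None,
                a_id: str = "A", b_id: str = "B",
                min_diag_offset: int = 0, self_pair: bool = False) -> List[LocalAlignment]:
    """All local alignments between two sequences (both strands of ``b``).

    Seeds are exact k-mer matches whose start is unmasked in both reads.  For
    self-alignment pass ``self_pair=True`` with a positive ``min_diag_offset``
    to suppress the trivial main diagonal.
    """
    p = params or AlignParams()
    if min(len(a), len(b)) < p.k:
        return []
    qa_pos, qa_codes = kmer_codes(a, p.k, mask_a, p.seed_sample)
    out: List[LocalAlignment] = []
    for orientation in (NORMAL, COMPLEMENT):
        if orientation == NORMAL:
            bo = b
            tb_pos, tb_codes = kmer_codes(b, p.k, mask_b, p.seed_sample)
        else:
            bo = revcomp(b)
            mask_o = [(len(b) - e, len(b) - bg) for bg, e in mask_b]
            tb_pos, tb_codes = kmer_codes(bo, p.k, mask_o, p.seed_sample)
        if not len(tb_pos) or not len(qa_pos):
            continue
        order = np.argsort(tb_codes, kind="stable")
        sc, sp = tb_codes[order], tb_pos[order]
        left = np.searchsorted(sc, qa_codes, "left")
        right = np.searchsorted(sc, qa_codes, "right")
        counts = right - left
        tot = int(counts.sum())
        if not tot:
            continue
        hit_idx = np.repeat(left, counts) + _ranges(counts)
        a_hit = np.repeat(qa_pos, counts)
        b_hit = sp[hit_idx]
        if self_pair and orientation == NORMAL:
            keep = a_hit != b_hit
            a_hit, b_hit = a_hit[keep], b_hit[keep]
        for seeds in _cluster_seeds(a_hit, b_hit, p, min_diag_offset if self_pair else 0):
            r = _extend_cluster(a, bo, seeds, p)
            if r is None:
                continue
            ab, ae, bb, be, diffs, cigar = r
            if orientation == NORMAL:
                fb, fe = bb, be
            else:
                fb, fe = len(b) - be, len(b) - bb
            out.append(LocalAlignment(a_id, b_id, orientation, ab, ae, fb, fe,
                                      diffs, len(a), len(b), cigar, "a"))
    return _dedupe(out)


def _ranges(counts: np.ndarray) -> np.ndarray:
    """[0..c0-1, 0..c1-1, ...] for the repeat-offset trick."""
    if not len(counts):
        return counts
    ends = np.cumsum(counts)
    out = np.arange(ends[-1]) - np.repeat(ends - counts, counts)
    return out


# ---------------------------------------------------------------------------
# chaining and classification

def chain_alignments(alignments: Sequence[LocalAlignment], max_gap: int = 1500) -> List[AlignmentChain]:
    """Partition one read pair's alignments into maximum-coverage co-linear
    chains with per-read gaps at most ``max_gap``.

    Chains are extracted best-first (total aligned bases, then fewer diffs,
    then lexicographic coordinates); each alignment joins at most one chain.
    """
    if not alignments:
        return []
    key = {(a.a_id, a.b_id, a.orientation) for a in alignments}
    if len(key) != 1:
        raise ValueError("chain_alignments requires one (a, b, orientation) group")
    pool = sorted(alignments, key=lambda x: (x.a_begin, x.b_oriented()[0],
                                             x.a_end, x.b_oriented()[1]))
    chains: List[AlignmentChain] = []
    while pool:
        n = len(pool)
        ob = [x.b_oriented() for x in pool]
        score = [0] * n
        parent = [-1] * n
        for j in range(n):
            best = pool[j].a_span + (ob[j][1] - ob[j][0])
            score[j] = best
            for i in range(j):
                ga = pool[j].a_begin - pool[i].a_end
                gb = ob[j][0] - ob[i][1]
                if 0 <= ga <= max_gap and 0 <= gb <= max_gap:
                    cand = score[i] + pool[j].a_span + (ob[j][1] - ob[j][0])
                    if cand > score[j]:
                        score[j] = cand
                        parent[j] = i
        end = max(range(n), key=lambda j: (score[j], -pool[j].a_begin))
        members = []
        while end != -1:
            members.append(pool[end])
            end = parent[end]
        members.reverse()
        chains.append(AlignmentChain(members))
        used = set(id(m) for m in members)
        pool = [x for x in pool if id(x) not in used]
    chains.sort(key=lambda c: (c.a_begin, c.ob_begin(), -len(c)))
    return chains


def classify_chain(chain: AlignmentChain, repeat_track: IntervalTrack,
                   end_slack: int = 25) -> str:
    """proper / premature_in_repeat / improper for one chain.

    Proper requires each chain end to reach within ``end_slack`` of an end of
    read A or read B.  A failing end whose endpoint lies inside a masked
    repeat interval (on either read) makes the chain premature_in_repeat — the
    signature of a true overlap whose seeds were suppressed by the mask.
    """
    if not chain.alignments:
        raise ValueError("empty chain")
    first, last = chain.alignments[0], chain.alignments[-1]
    a_len, b_len = first.a_length, first.b_length
    start_ok = chain.a_begin <= end_slack or chain.ob_begin() <= end_slack
    end_ok = chain.a_end >= a_len - end_slack or chain.ob_end() >= b_len - end_slack
    if start_ok and end_ok:
        chain.status = PROPER
        return PROPER
    rep_a = repeat_track[chain.a_id]
    rep_b = repeat_track[chain.b_id]
    in_repeat = False
    if not start_ok:
        fwd_b = first.b_begin if first.orientation == NORMAL else first.b_end - 1
        if contains_point(rep_a, chain.a_begin) or contains_point(rep_b, max(fwd_b, 0)):
            in_repeat = True
    if not end_ok:
        fwd_b = last.b_end - 1 if last.orientation == NORMAL else last.b_begin
        if contains_point(rep_a, max(chain.a_end - 1, 0)) or contains_point(rep_b, max(fwd_b, 0)):
            in_repeat = True
    chain.status = PREMATURE_IN_REPEAT if in_repeat else IMPROPER
    return chain.status


def realign_unmasked(a: str, b: str, chains: Sequence[AlignmentChain],
                     params: Optional[AlignParams] = None,
                     a_id: str = "A", b_id: str = "B") -> List[LocalAlignment]:
    """Mask-free re-alignment of a read pair whose chains end prematurely in
    repeats; replaces the pair's previous alignment set.  Pairs with no
    premature chains are returned unchanged."""
    if not any(c.status == PREMATURE_IN_REPEAT for c in chains):
        return [x for c in chains for x in c.alignments]
    return local_align(a, b, (), (), params, a_id=a_id, b_id=b_id)


# ---------------------------------------------------------------------------
# all-vs-all

def all_vs_all(db, masks: Optional[IntervalTrack] = None,
               params: Optional[AlignParams] = None,
               subset: Optional[Sequence[str]] = None) -> List[Pile]:
    """Attempt every unordered read pair once; return one Pile per read.

    A shared k-mer index over all forward strands finds candidate seed sets;
    each pair's alignments are computed with the A-read being the smaller
    index, and the mirrored counterpart is placed in the B-read's pile.
    """
    p = params or AlignParams()
    masks = masks or IntervalTrack()
    reads = [db[rid] for rid in subset] if subset is not None else list(db)
    n = len(reads)
    piles: Dict[str, List[LocalAlignment]] = {r.read_id: [] for r in reads}
    if n < 2:
        return [Pile(r.read_id, []) for r in reads]

    idx_pos = []
    idx_code = []
    idx_read = []
    fwd_cache = {}
    for i, r in enumerate(reads):
        pos, codes = kmer_codes(r.sequence, p.k, masks[r.read_id], p.seed_sample)
        fwd_cache[i] = (pos, codes)
        idx_pos.append(pos)
        idx_code.append(codes)
        idx_read.append(np.full(len(pos), i, dtype=np.int64))
    all_code = np.concatenate(idx_code)
    all_pos = np.concatenate(idx_pos)
    all_read = np.concatenate(idx_read)
    order = np.argsort(all_code, kind="stable")
    sc, sp, sr = all_code[order], all_pos[order], all_read[order]
    blen_arr = np.array([len(r) for r in reads], dtype=np.int64)

    for i, ra in enumerate(reads):
        bo_cache: Dict[Tuple[int, str], str] = {}
        for orientation in (NORMAL, COMPLEMENT):
            if orientation == NORMAL:
                q_pos, q_codes = fwd_cache[i]
            else:
                q_pos, q_codes = rc_kmer_codes(ra.sequence, p.k, masks[ra.read_id], p.seed_sample)
            if not len(q_pos):
                continue
            left = np.searchsorted(sc, q_codes, "left")
            right = np.searchsorted(sc, q_codes, "right")
            counts = right - left
            tot = int(counts.sum())
            if not tot:
                continue
            hit = np.repeat(left, counts) + _ranges(counts)
            b_read = sr[hit]
            keep = b_read > i
            if not keep.any():
                continue
            b_read = b_read[keep]
            b_pos = sp[hit][keep]
            a_pos = np.repeat(q_pos, counts)[keep]
            # oriented B coordinate of each hit
            if orientation == COMPLEMENT:
                b_pos = blen_arr[b_read] - p.k - b_pos
            order2 = np.lexsort((a_pos, b_pos, b_read))
            b_read, b_pos, a_pos = b_read[order2], b_pos[order2], a_pos[order2]
            bounds = np.flatnonzero(np.diff(b_read)) + 1
            for s, e in zip(np.concatenate(([0], bounds)),
                            np.concatenate((bounds, [len(b_read)]))):
                j = int(b_read[s])
                if e - s < p.min_seeds:
                    continue
                clusters = _cluster_seeds(a_pos[s:e], b_pos[s:e], p)
                if not clusters:
                    continue
                clusters.sort(key=len, reverse=True)
                clusters = clusters[: p.max_candidates_per_pair]
                key = (j, orientation)
                if key not in bo_cache:
                    bo_cache[key] = (reads[j].sequence if orientation == NORMAL
                                     else revcomp(reads[j].sequence))
                bo = bo_cache[key]
                new = []
                for seeds in clusters:
                    r = _extend_cluster(ra.sequence, bo, seeds, p)
                    if r is None:
                        continue
                    ab, ae, bb, be, diffs, cigar = r
                    if orientation == NORMAL:
                        fb, fe = bb, be
                    else:
                        fb, fe = len(reads[j]) - be, len(reads[j]) - bb
                    new.append(LocalAlignment(ra.read_id, reads[j].read_id,
                                              orientation, ab, ae, fb, fe, diffs,
                                              len(ra), len(reads[j]), cigar, "a"))
                for aln in _dedupe(new):
                    piles[ra.read_id].append(aln)
                    piles[reads[j].read_id].append(aln.mirrored())

    out = []
    for r in reads:
        alns = sorted(piles[r.read_id], key=LocalAlignment.sort_key)
        out.append(Pile(r.read_id, alns))
    return out


def map_to_reference(reads: Sequence, ref_id: str, ref_seq: str,
                     params: Optional[AlignParams] = None) -> List[LocalAlignment]:
    """Align reads against one reference sequence (both read strands).

    The reference k-mer index is built once; each read is seeded, clustered
    and extended exactly as in read-vs-read alignment.  Returns alignments
    with the read as the A-side.
    """
    p = params or AlignParams()
    t_pos, t_codes = kmer_codes(ref_seq, p.k, (), p.seed_sample)
    if not len(t_pos):
        return []
    order = np.argsort(t_codes, kind="stable")
    sc, sp = t_codes[order], t_pos[order]
    ref_rc = revcomp(ref_seq)
    nref = len(ref_seq)
    out: List[LocalAlignment] = []
    for read in reads:
        for orientation in (NORMAL, COMPLEMENT):
            if orientation == NORMAL:
                q_pos, q_codes = kmer_codes(read.sequence, p.k, (), p.seed_sample)
                bo = ref_seq
            else:
                q_pos, q_codes = rc_kmer_codes(read.sequence, p.k, (), p.seed_sample)
                bo = ref_rc
            if not len(q_pos):
                continue
            left = np.searchsorted(sc, q_codes, "left")
            right = np.searchsorted(sc, q_codes, "right")
            counts = right - left
            if not counts.sum():
                continue
            hit = np.repeat(left, counts) + _ranges(counts)
            b_pos = sp[hit]
            a_pos = np.repeat(q_pos, counts)
            if orientation == COMPLEMENT:
                b_pos = nref - p.k - b_pos
            for seeds in _cluster_seeds(a_pos, b_pos, p):
                r = _extend_cluster(read.sequence, bo, seeds, p)
                if r is None:
                    continue
                ab, ae, bb, be, diffs, cigar = r
                if orientation == NORMAL:
                    fb, fe = bb, be
                else:
                    fb, fe = nref - be, nref - bb
                out.append(LocalAlignment(read.read_id, ref_id, orientation,
                                          ab, ae, fb, fe, diffs,
                                          len(read.sequence), nref, cigar, "a"))
    final: List[LocalAlignment] = []
    by_read: Dict[str, List[LocalAlignment]] = {}
    for aln in out:
        by_read.setdefault(aln.a_id, []).append(aln)
    for rid in sorted(by_read):
        final.extend(_dedupe(by_read[rid]))
    return final


# ---------------------------------------------------------------------------
# PAF output

def write_paf(alignments: Iterable[LocalAlignment], path) -> None:
    """Standard PAF columns; diffs carried in an NM-style tag."""
    with open(path, "w") as fh:
        for a in alignments:
            strand = "+" if a.orientation == NORMAL else "-"
            matches = max(a.a_span, a.b_span) - a.diffs
            fh.write("\t".join(map(str, [
                a.a_id, a.a_length, a.a_begin, a.a_end, strand,
                a.b_id, a.b_length, a.b_begin, a.b_end,
                matches, max(a.a_span, a.b_span), 255,
                f"NM:i:{a.diffs}",
            ])) + "\n")
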