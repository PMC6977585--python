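"""Three-tier repeat masking of reads before alignment seeding.

Masking exists to keep k-mer seeding out of repetitive sequence, which is both
the dominant cost of all-vs-all alignment and the main source of spurious
overlaps.  Three tiers are combined:

1. **Low-complexity** (microsatellites, homopolymers): a windowed triplet
   composition score in the DUST family.
2. **Tandem repeats**: periodic self-matches of a read against itself at a
   positive offset bounded by the maximum period.
3. **Interspersed repeats**: reads are split into groups of roughly 1× genome
   coverage, aligned all-vs-all within each group, and every local region
   where at least ``mask_threshold`` (default 10) *distinct* other reads align
   is masked — in a 1× group, unique sequence cannot attract that much
   coverage, so high pile coverage identifies repeats without any repeat
   library.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .intervals import Interval, IntervalTrack, normalize
from .overlap import AlignParams, Pile, all_vs_all
from .readstore import ReadDB, SubRead

log = logging.getLogger(__name__)


@dataclass
class DustParams:
    """Low-complexity masking: windowed triplet score threshold.

    A window's score is ``sum_t c_t (c_t - 1) / 2`` over triplet counts
    ``c_t``, divided by the number of triplet positions in the window; pure
    homopolymer scores ~(w-3)/2, random sequence ~0.5.
    """

    window: int = 64
    threshold: float = 2.0

    def __post_init__(self):
        if self.window < 3:
            raise ValueError("window must be >= 3")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")


@dataclass
class CoverageMaskParams:
    """Coverage-based interspersed-repeat masking in 1x read groups."""

    genome_size_estimate: int
    mask_threshold: int = 10

    def __post_init__(self):
        if self.genome_size_estimate <= 0:
            raise ValueError("genome_size_estimate must be > 0")
        if self.mask_threshold < 1:
            raise ValueError("mask_threshold must be >= 1")


_TRIPLET_LUT = np.zeros(256, dtype=np.int64)
_TRIPLET_LUT[ord("C")] = 1
_TRIPLET_LUT[ord("G")] = 2
_TRIPLET_LUT[ord("T")] = 3


def dust_mask(read: SubRead, params: Optional[DustParams] = None) -> List[Interval]:
    """Intervals whose windowed triplet-composition score exceeds the
    threshold; merged and clipped to read bounds."""
    p = params or DustParams()
    seq = read.sequence
    n = len(seq)
    w = p.window
    if n < w:
        return []
    arr = _TRIPLET_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    tri = arr[:-2] * 16 + arr[1:-1] * 4 + arr[2:]
    nt = w - 2  # triplet positions per window
    counts = np.zeros(64, dtype=np.int64)
    s = 0
    out = []
    for i in range(nt):
        s += counts[tri[i]]
        counts[tri[i]] += 1
    if s / nt > p.threshold:
        out.append((0, w))
    for start in range(1, n - w + 1):
        old = tri[start - 1]
        counts[old] -= 1
        s -= counts[old]
        new = tri[start + nt - 1]
        s += counts[new]
        counts[new] += 1
        if s / nt > p.threshold:
            out.append((start, start + w))
    return normalize(out)


def tandem_mask(read: SubRead, max_period: int = 500, min_span: int = 100,
                k: int = 8, min_matches: int = 3) -> List[Interval]:
    """Intervals where the read matches itself at a positive offset
    ``<= max_period`` over a span ``>= min_span``.

    Self-matches are exact k-mer pairs at the same offset; a run of at least
    ``min_matches`` consistent-offset matches spanning ``min_span`` bases is
    called tandem and masked over its full extent (including the final period).
    """
    if max_period < 1:
        raise ValueError("max_period must be >= 1")
    seq = read.sequence
    n = len(seq)
    if n < k + 1:
        return []
    occ: Dict[str, List[int]] = {}
    for i in range(n - k + 1):
        km = seq[i : i + k]
        if "N" in km:
            continue
        occ.setdefault(km, []).append(i)
    by_offset: Dict[int, List[int]] = {}
    for positions in occ.values():
        for ix, i in enumerate(positions):
            hops = 0
            for j in positions[ix + 1 :]:
                d = j - i
                if d > max_period or hops >= 8:
                    break
                by_offset.setdefault(d, []).append(i)
                hops += 1
    out = []
    for d, pos in sorted(by_offset.items()):
        pos.sort()
        gap = max(2 * d, 50)
        start = prev = pos[0]
        count = 1
        for i in pos[1:] + [None]:
            if i is not None and i - prev <= gap:
                prev = i
                count += 1
                continue
            # a real tandem matches itself at almost every position of the
            # repeat region; demand that density, not just a few hits
            span_core = prev - start
            if (count >= min_matches
                    and count >= 0.1 * span_core
                    and span_core >= max(2 * k, 0.5 * d)
                    and (prev + d + k) - start >= min_span):
                out.append((start, min(prev + d + k, n)))
            if i is not None:
                start = prev = i
                count = 1
    return normalize(out)


def split_into_groups(db: ReadDB, genome_size_estimate: int) -> List[List[str]]:
    """Greedy 1x grouping: reads in database order, accumulated until a
    group's total length reaches the genome size estimate."""
    if genome_size_estimate > db.total_length():
        log.warning(
            "genome_size_estimate (%d) exceeds total read length (%d); "
            "using a single group", genome_size_estimate, db.total_length(),
        )
        return [[r.read_id for r in db]] if len(db) else []
    groups: List[List[str]] = []
    cur: List[str] = []
    acc = 0
    for r in db:
        cur.append(r.read_id)
        acc += len(r)
        if acc >= genome_size_estimate:
            groups.append(cur)
            cur = []
            acc = 0
    if cur:
        groups.append(cur)
    return groups


def coverage_mask_from_piles(piles: Sequence[Pile], mask_threshold: int,
                             read_lengths: Dict[str, int]) -> IntervalTrack:
    """Per read, mask positions covered by >= mask_threshold distinct other
    reads' alignments (multiple alignments from one partner count once)."""
    track = IntervalTrack()
    for pile in piles:
        n = read_lengths[pile.a_id]
        diff = np.zeros(n + 1, dtype=np.int64)
        per_b: Dict[str, List[Tuple[int, int]]] = {}
        for aln in pile.alignments:
            per_b.setdefault(aln.b_id, []).append((aln.a_begin, aln.a_end))
        for ivs in per_b.values():
            for b, e in normalize(ivs):
                diff[b] += 1
                diff[e] -= 1
        cov = np.cumsum(diff[:-1])
        hot = cov >= mask_threshold
        if hot.any():
            edges = np.flatnonzero(np.diff(np.concatenate(([0], hot.view(np.int8), [0]))))
            track[pile.a_id] = list(zip(edges[0::2].tolist(), edges[1::2].tolist()))
    return track


def coverage_repeat_mask(db: ReadDB, params: CoverageMaskParams,
                         align_params: Optional[AlignParams] = None,
                         base_masks: Optional[IntervalTrack] = None) -> IntervalTrack:
    """Interspersed-repeat mask from 1x-group all-vs-all alignment."""
    if not len(db):
        raise ValueError("empty read database")
    lengths = {r.read_id: len(r) for r in db}
    out = IntervalTrack()
    groups = split_into_groups(db, params.genome_size_estimate)
    for gi, group in enumerate(groups):
        piles = all_vs_all(db, base_masks, align_params, subset=group)
        part = coverage_mask_from_piles(piles, params.mask_threshold, lengths)
        for rid, ivs in part.items():
            out.add(rid, ivs)
        log.debug("coverage mask: group %d/%d, %d reads", gi + 1, len(groups), len(group))
    return out


def mask_reads(db: ReadDB, dust_params: Optional[DustParams] = None,
               max_period: int = 500, min_span: int = 100,
               coverage_params: Optional[CoverageMaskParams] = None,
               align_params: Optional[AlignParams] = None) -> Dict[str, IntervalTrack]:
    """Compute all mask tiers; returns tracks 'dust', 'tandem', 'coverage'
    (if requested) and their union 'mask'."""
    dust = IntervalTrack()
    tandem = IntervalTrack()
    for r in db:
        dust[r.read_id] = dust_mask(r, dust_params)
        tandem[r.read_id] = tandem_mask(r, max_period, min_span)
    tracks = {"dust": dust, "tandem": tandem}
    base = IntervalTrack()
    for t in (dust, tandem):
        for rid, ivs in t.items():
            base.add(rid, ivs)
    if coverage_params is not None:
        cov = coverage_repeat_mask(db, coverage_params, align_params, base)
        tracks["coverage"] = cov
        for rid, ivs in cov.items():
            base.add(rid, ivs)
    tracks["mask"] = base
    return tracks
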