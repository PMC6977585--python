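"""Reference-baited circular genome assembly (mitogenome mode).

Organelle genomes are short, circular, and vastly outnumbered in coverage by
the nuclear background, so they are assembled separately: reads are *baited*
by aligning everything against a related circular reference (doubled, so that
chains may wrap the origin), filtered for proper circular alignment chains
(aligned length within a band around the reference length, little unaligned
sequence), split into overlapping fragments so the final assembly consists of
more than one read, assembled with the general pipeline, and finally
circularized by mapping the contig to itself and trimming the redundant
overlap — the Circlator recipe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .layout import Contig
from .overlap import (AlignmentChain, AlignParams, LocalAlignment,
                      chain_alignments, local_align)
from .readstore import ReadDB, SubRead

log = logging.getLogger(__name__)


@dataclass
class CircularChainFilter:
    """Bounds on a proper circular alignment chain: total aligned read bases
    in [min_chain, max_chain], unaligned read bases (tails plus internal
    gaps) at most max_unaligned."""

    min_chain: int = 4000
    max_chain: int = 14000
    max_unaligned: int = 1500

    def __post_init__(self):
        if not 0 < self.min_chain <= self.max_chain:
            raise ValueError("need 0 < min_chain <= max_chain")


@dataclass
class MitoParams:
    chain_filter: CircularChainFilter = None  # type: ignore[assignment]
    split_overlap: int = 1500
    target_length: Optional[int] = None  # default: half the reference length
    min_circ_overlap: int = 500
    circ_identity: float = 0.95

    def __post_init__(self):
        if self.chain_filter is None:
            self.chain_filter = CircularChainFilter()


def bait_reads(db: ReadDB, reference: str,
               params: Optional[AlignParams] = None
               ) -> List[Tuple[SubRead, List[AlignmentChain]]]:
    """Reads with at least one alignment chain to the circular reference.

    The reference is doubled so a single aligner pass finds origin-wrapping
    chains; reference coordinates can be mapped back modulo its length.
    """
    p = params or AlignParams()
    ref2 = reference + reference
    out = []
    for read in db:
        alns = local_align(read.sequence, ref2, params=p,
                           a_id=read.read_id, b_id="reference")
        if not alns:
            continue
        groups: Dict[Tuple[str, str], List[LocalAlignment]] = {}
        for a in alns:
            groups.setdefault((a.b_id, a.orientation), []).append(a)
        chains: List[AlignmentChain] = []
        for key in sorted(groups):
            chains.extend(chain_alignments(groups[key], p.max_gap))
        if chains:
            out.append((read, chains))
    return out


def wrap_reference_interval(begin: int, end: int, ref_length: int
                            ) -> List[Tuple[int, int]]:
    """Map a doubled-reference interval back modulo the reference length."""
    span = end - begin
    begin %= ref_length
    end = begin + span
    if end <= ref_length:
        return [(begin, end)]
    return [(begin, ref_length), (0, end - ref_length)]


def filter_circular_chains(
    candidates: Sequence[Tuple[SubRead, Sequence[AlignmentChain]]],
    params: Optional[CircularChainFilter] = None,
) -> List[SubRead]:
    """Keep a read iff one of its chains passes the circular chain filter."""
    p = params or CircularChainFilter()
    kept = []
    for read, chains in candidates:
        for chain in chains:
            aligned = chain.aligned_a
            unaligned = len(read) - aligned
            if p.min_chain <= aligned <= p.max_chain and unaligned <= p.max_unaligned:
                kept.append(read)
                break
    return kept


def split_with_overlap(read: SubRead, target_length: int,
                       overlap: int = 1500) -> List[SubRead]:
    """Split a read into ``target_length`` fragments starting at multiples of
    ``target_length - overlap`` so consecutive fragments share exactly
    ``overlap`` bases; the last fragment extends to the read end and is
    merged into the previous one if shorter than ``overlap``."""
    if overlap >= target_length:
        raise ValueError("overlap must be smaller than target_length")
    n = len(read)
    if n <= target_length:
        return [read]
    step = target_length - overlap
    bounds: List[Tuple[int, int]] = []
    start = 0
    while start + target_length < n:
        bounds.append((start, start + target_length))
        start += step
    if n - start < overlap and bounds:
        bounds[-1] = (bounds[-1][0], n)
    else:
        bounds.append((start, n))
    out = []
    for i, (b, e) in enumerate(bounds):
        rid = f"{read.read_id}.split{i}"
        out.append(SubRead(rid, rid, 0, read.sequence[b:e]))
    return out


def circularize(contig: Contig, params: Optional[MitoParams] = None,
                align_params: Optional[AlignParams] = None,
                anchor: Optional[str] = None) -> Contig:
    """Map the contig to itself; if a suffix repeats a prefix with sufficient
    identity and length, trim the redundant copy and flag the contig
    circular.  Optionally rotate the circle to start at ``anchor``."""
    p = params or MitoParams()
    ap = align_params or AlignParams()
    seq = contig.sequence
    n = len(seq)
    margin = max(4 * ap.end_slack, 200)
    hits = []
    if n >= 2 * p.min_circ_overlap:
        for aln in local_align(seq, seq, params=ap, self_pair=True,
                               min_diag_offset=p.min_circ_overlap):
            if aln.orientation != "normal":
                continue
            if aln.a_begin > margin or aln.b_end < n - margin:
                continue
            if aln.b_begin <= aln.a_end:  # must be disjoint prefix vs suffix
                continue
            span = min(aln.a_span, aln.b_span)
            ident = 1.0 - aln.diffs / max(aln.a_span, aln.b_span)
            if span >= p.min_circ_overlap and ident >= p.circ_identity:
                hits.append((span, aln))
    if not hits:
        return contig
    hits.sort(key=lambda h: (-h[0], h[1].a_begin))
    if len(hits) > 1:
        log.warning("multiple self-overlaps on %s; keeping the longest",
                    contig.name)
    aln = hits[0][1]
    circ_seq = seq[aln.a_begin : aln.b_begin]
    out = Contig(contig.name, contig.path, contig.edges, circ_seq, True)
    if anchor:
        out.sequence = rotate_to_anchor(out.sequence, anchor)
    return out


def rotate_to_anchor(circ_seq: str, anchor: str) -> str:
    """Rotate a circular sequence so it starts at the best anchor match."""
    import edlib

    doubled = circ_seq + circ_seq
    res = edlib.align(anchor, doubled, mode="HW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return circ_seq
    start = res["locations"][0][0] % len(circ_seq)
    return circ_seq[start:] + circ_seq[:start]
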