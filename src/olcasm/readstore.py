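"""Read database set-up: parsing, per-ZMW longest-subread selection, length
filtering, and per-read interval tracks.

Single-molecule instruments report several subreads per ZMW (one per polymerase
pass).  Set-up keeps only the longest subread of each ZMW and then drops reads
below a minimum length (4 kb by default), mirroring standard long-read assembly
practice.  The resulting :class:`ReadDB` assigns stable integer indices in
input order and carries named :class:`~olcasm.intervals.IntervalTrack` tracks
(masks, patches, quality segments) for its reads.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

from Bio import SeqIO

from .intervals import IntervalTrack, normalize

log = logging.getLogger(__name__)

_VALID = re.compile(r"^[ACGTN]*$")
#: PacBio-style read name: movie/zmw/first_last
_PB_NAME = re.compile(r"^(?P<movie>[^/]+)/(?P<zmw>\d+)/(?P<first>\d+)_(?P<last>\d+)$")

DEFAULT_MIN_READ_LENGTH = 4000


@dataclass(frozen=True)
class SubRead:
    """A single read with its ZMW identity."""

    read_id: str
    zmw: str
    subread_index: int
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


def parse_read_name(name: str) -> Tuple[str, int]:
    """Derive (zmw, subread_index) from a read name.

    PacBio-style ``movie/zmw/first_last`` names group subreads by movie+ZMW;
    any other name is treated as a singleton ZMW, so arbitrary FASTA can be
    assembled.
    """
    m = _PB_NAME.match(name)
    if m:
        return f"{m.group('movie')}/{m.group('zmw')}", int(m.group("first"))
    return name, 0


class ReadDB:
    """Ordered read collection with stable indices and named interval tracks."""

    def __init__(self, reads: Iterable[SubRead]):
        self.reads: List[SubRead] = list(reads)
        self.tracks: Dict[str, IntervalTrack] = {}
        self._index: Dict[str, int] = {}
        for i, r in enumerate(self.reads):
            if r.read_id in self._index:
                raise ValueError(f"duplicate read_id: {r.read_id}")
            self._index[r.read_id] = i

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def __getitem__(self, key) -> SubRead:
        if isinstance(key, str):
            return self.reads[self._index[key]]
        return self.reads[key]

    def index_of(self, read_id: str) -> int:
        return self._index[read_id]

    def __contains__(self, read_id: str) -> bool:
        return read_id in self._index

    def length_of(self, read_id: str) -> int:
        return len(self[read_id].sequence)

    def total_length(self) -> int:
        return sum(len(r) for r in self.reads)

    def track(self, name: str) -> IntervalTrack:
        return self.tracks.setdefault(name, IntervalTrack())

    def set_track(self, name: str, track: IntervalTrack) -> None:
        validate_track(self, track)
        self.tracks[name] = track


def build_db(subreads: Iterable[SubRead], min_length: int = DEFAULT_MIN_READ_LENGTH) -> ReadDB:
    """Select the longest subread of each ZMW, then apply the length filter.

    The order of selection matters in edge cases: a ZMW whose longest subread
    is below ``min_length`` contributes nothing, even if discarding the filter
    first would have left a different subread.
    """
    best: Dict[str, SubRead] = {}
    order: List[str] = []
    seen_ids = set()
    for r in subreads:
        if not _VALID.match(r.sequence):
            raise ValueError(f"read {r.read_id}: invalid characters in sequence")
        if r.read_id in seen_ids:
            raise ValueError(f"duplicate read_id: {r.read_id}")
        seen_ids.add(r.read_id)
        cur = best.get(r.zmw)
        if cur is None:
            best[r.zmw] = r
            order.append(r.zmw)
        elif len(r) > len(cur):
            best[r.zmw] = r
    kept = [best[z] for z in order if len(best[z]) >= min_length]
    db = ReadDB(kept)
    log.info(
        "build_db: %d subreads in, %d ZMWs, %d reads >= %d b kept (%d bases)",
        len(seen_ids), len(order), len(db), min_length, db.total_length(),
    )
    return db


def merge_track(track_a: IntervalTrack, track_b: IntervalTrack) -> IntervalTrack:
    """Per-read interval union of two tracks, normalized."""
    out = track_a.copy()
    for rid, ivs in track_b.items():
        out.add(rid, ivs)
    return out


def validate_track(db: ReadDB, track: IntervalTrack) -> None:
    for rid, ivs in track.items():
        if rid not in db:
            raise ValueError(f"track refers to unknown read {rid}")
        n = db.length_of(rid)
        for b, e in ivs:
            if not (0 <= b < e <= n):
                raise ValueError(
                    f"interval ({b}, {e}) out of bounds for read {rid} (length {n})"
                )


# ---------------------------------------------------------------------------
# I/O

def read_sequences(path) -> List[SubRead]:
    """Load reads from FASTA or FASTQ (qualities ignored)."""
    p = str(path)
    fmt = "fastq" if p.endswith((".fastq", ".fq")) else "fasta"
    out = []
    for rec in SeqIO.parse(p, fmt):
        zmw, idx = parse_read_name(rec.id)
        out.append(SubRead(rec.id, zmw, idx, str(rec.seq).upper()))
    return out


def write_fasta(reads: Iterable[SubRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n")
            for i in range(0, len(r.sequence), 80):
                fh.write(r.sequence[i : i + 80] + "\n")


def write_track_bed(track: IntervalTrack, path) -> None:
    """Serialize a track as BED3 with the read name in the chromosome column."""
    with open(path, "w") as fh:
        for rid, ivs in track.items():
            for b, e in ivs:
                fh.write(f"{rid}\t{b}\t{e}\n")


def read_track_bed(path) -> IntervalTrack:
    track = IntervalTrack()
    per_read: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            per_read.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
    for rid, ivs in per_read.items():
        track[rid] = normalize(ivs)
    return track
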