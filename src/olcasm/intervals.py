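"""Sorted, non-overlapping half-open interval lists and per-read interval tracks.

Every mask, patch and quality segment in the pipeline is stored as a list of
0-based half-open ``(begin, end)`` intervals attached to a read.  Intervals are
kept *normalized*: sorted by begin, non-overlapping, with adjacent (touching)
intervals merged.  Normalization is idempotent, and unions of normalized lists
are order-independent, which keeps every downstream mask computation
deterministic.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Tuple

Interval = Tuple[int, int]


def normalize(intervals: Iterable[Interval]) -> List[Interval]:
    """Sort, drop empty, and merge overlapping or touching intervals."""
    ivs = sorted((int(b), int(e)) for b, e in intervals if e > b)
    out: List[Interval] = []
    for b, e in ivs:
        if out and b <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((b, e))
    return out


def union(*interval_lists: Iterable[Interval]) -> List[Interval]:
    merged: List[Interval] = []
    for ivs in interval_lists:
        merged.extend(ivs)
    return normalize(merged)


def clip(intervals: Iterable[Interval], lo: int, hi: int) -> List[Interval]:
    """Clip intervals to ``[lo, hi)``."""
    return normalize((max(b, lo), min(e, hi)) for b, e in intervals)


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - b for b, e in intervals)


def contains_point(intervals: Sequence[Interval], pos: int) -> bool:
    """True if ``pos`` falls inside any (normalized) interval."""
    import bisect

    i = bisect.bisect_right([b for b, _ in intervals], pos) - 1
    return i >= 0 and intervals[i][0] <= pos < intervals[i][1]


def covers(intervals: Sequence[Interval], begin: int, end: int) -> bool:
    """True if ``[begin, end)`` is fully covered by a single interval."""
    for b, e in intervals:
        if b <= begin and end <= e:
            return True
        if b > begin:
            break
    return False


def intersect(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    a = normalize(a)
    b = normalize(b)
    out: List[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def complement(intervals: Iterable[Interval], length: int) -> List[Interval]:
    """Intervals of ``[0, length)`` not covered by ``intervals``."""
    out: List[Interval] = []
    pos = 0
    for b, e in normalize(intervals):
        if b > pos:
            out.append((pos, b))
        pos = max(pos, e)
    if pos < length:
        out.append((pos, length))
    return out


class IntervalTrack:
    """Per-read normalized interval lists, keyed by read id.

    Reads without an entry have an empty interval list.  The track does not
    itself know read lengths; bounds are validated where lengths are known
    (see :func:`olcasm.readstore.validate_track`).
    """

    def __init__(self, data: Dict[str, Iterable[Interval]] | None = None):
        self._data: Dict[str, List[Interval]] = {}
        if data:
            for rid, ivs in data.items():
                self[rid] = ivs

    def __getitem__(self, read_id: str) -> List[Interval]:
        return self._data.get(read_id, [])

    def __setitem__(self, read_id: str, intervals: Iterable[Interval]) -> None:
        ivs = normalize(intervals)
        if ivs:
            self._data[read_id] = ivs
        else:
            self._data.pop(read_id, None)

    def __contains__(self, read_id: str) -> bool:
        return read_id in self._data

    def __iter__(self):
        return iter(sorted(self._data))

    def __len__(self) -> int:
        return len(self._data)

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalTrack) and self._data == other._data

    def items(self):
        for rid in sorted(self._data):
            yield rid, self._data[rid]

    def add(self, read_id: str, intervals: Iterable[Interval]) -> None:
        self[read_id] = union(self[read_id], intervals)

    def copy(self) -> "IntervalTrack":
        return IntervalTrack({rid: list(ivs) for rid, ivs in self._data.items()})

    def total_length(self) -> int:
        return sum(total_length(ivs) for ivs in self._data.values())


def merge_tracks(*tracks: IntervalTrack) -> IntervalTrack:
    """Per-read union of any number of tracks (order-independent)."""
    out = IntervalTrack()
    for t in tracks:
        for rid, ivs in t.items():
            out.add(rid, ivs)
    return out
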