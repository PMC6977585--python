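"""Synthetic genomes and noisy long reads with machine-readable ground truth.

The simulator stands in for real single-molecule sequencing data.  It produces

* genomes with planted repeat families (dispersed or tandem, at a controlled
  sequence identity to the family consensus), and
* long reads with an indel-dominated error profile and injected artefacts —
  chimeric joins of unrelated loci, missed-adapter fold-backs, polymerase
  strand jumps, and long low-quality segments —

each annotated with ground truth (:class:`GenomeTruth`, :class:`ReadTruth`)
so that every downstream stage of the assembler can be tested against a known
answer.  All randomness flows from a single :class:`numpy.random.Generator`
seeded once; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .readstore import SubRead

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: Share of insertions / deletions / substitutions in the total error rate.
#: Long-read errors are indel-dominated; this split mimics raw PacBio CLR data.
DEFAULT_ERROR_MIX = (0.55, 0.25, 0.20)


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


@dataclass(frozen=True)
class RepeatSpec:
    """A planted repeat family: ``copies`` copies of a ``unit_length``-base
    consensus, each mutated to the given ``identity``; ``tandem`` places the
    copies head-to-tail instead of dispersing them."""

    family_id: str
    unit_length: int
    copies: int
    identity: float = 0.95
    tandem: bool = False

    def __post_init__(self):
        if self.unit_length < 1 or self.copies < 1:
            raise ValueError("unit_length and copies must be >= 1")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")


@dataclass
class GenomeTruth:
    """A simulated genome plus the coordinates of every planted repeat copy."""

    sequence: str
    circular: bool = False
    #: (family_id, begin, end), 0-based half-open
    repeat_intervals: List[Tuple[str, int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadTruth:
    """Ground truth for one simulated read.

    ``source_intervals`` are ``(genome_begin, genome_end, strand)`` pieces
    whose (strand-applied) concatenation yields the read before errors; for
    circular genomes an interval may run past the genome end, meaning it wraps
    the origin.  ``artefacts`` are ``(kind, position_or_interval)`` records in
    post-error read coordinates.
    """

    read_id: str
    source_intervals: List[Tuple[int, int, str]] = field(default_factory=list)
    artefacts: List[Tuple[str, object]] = field(default_factory=list)

    def artefact_kinds(self) -> List[str]:
        return [k for k, _ in self.artefacts]


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


_BASE_LUT = np.zeros(256, dtype=np.uint8)
_BASE_LUT[_BASES] = np.arange(4)


def _mutate_subs(rng: np.random.Generator, arr: np.ndarray, rate: float) -> np.ndarray:
    """Substitute bases at the given per-base rate (always to a different base)."""
    arr = arr.copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    if hit.size:
        cur = _BASE_LUT[arr[hit]]
        arr[hit] = _BASES[(cur + rng.integers(1, 4, size=hit.size)) % 4]
    return arr


def simulate_genome(
    length: int,
    repeats: Sequence[RepeatSpec] = (),
    circular: bool = False,
    seed: int = 0,
) -> GenomeTruth:
    """Generate a random genome with planted repeat families.

    Repeat copies are derived from one random consensus per family by
    per-base substitution at rate ``1 - identity`` and placed at
    non-overlapping positions (contiguously for tandem families).
    """
    if length < 1:
        raise ValueError("genome length must be >= 1")
    total_repeat = sum(r.unit_length * r.copies for r in repeats)
    if total_repeat >= length:
        raise ValueError(
            f"planted repeats ({total_repeat} b) exceed genome length ({length} b)"
        )
    rng = np.random.default_rng(seed)
    genome = _random_seq(rng, length)
    occupied: List[Tuple[int, int]] = []
    intervals: List[Tuple[str, int, int]] = []

    def _place(span: int) -> int:
        for _ in range(10_000):
            pos = int(rng.integers(0, length - span + 1))
            if all(pos + span <= b or pos >= e for b, e in occupied):
                occupied.append((pos, pos + span))
                return pos
        raise ValueError("could not place repeats; genome too crowded")

    for spec in repeats:
        consensus = _random_seq(rng, spec.unit_length)
        if spec.tandem:
            pos = _place(spec.unit_length * spec.copies)
            for i in range(spec.copies):
                b = pos + i * spec.unit_length
                genome[b : b + spec.unit_length] = _mutate_subs(
                    rng, consensus, 1.0 - spec.identity
                )
                intervals.append((spec.family_id, b, b + spec.unit_length))
        else:
            for _ in range(spec.copies):
                b = _place(spec.unit_length)
                genome[b : b + spec.unit_length] = _mutate_subs(
                    rng, consensus, 1.0 - spec.identity
                )
                intervals.append((spec.family_id, b, b + spec.unit_length))
    intervals.sort(key=lambda t: (t[1], t[2], t[0]))
    return GenomeTruth(genome.tobytes().decode(), circular, intervals)


def _draw_length(rng: np.random.Generator, mean: float, minimum: int) -> int:
    # Log-normal with the requested mean; hard truncation at the minimum.
    sigma = 0.45
    mu = np.log(mean) - sigma * sigma / 2.0
    for _ in range(20):
        val = int(rng.lognormal(mu, sigma))
        if val >= minimum:
            return val
    return minimum


def _apply_errors(
    rng: np.random.Generator,
    pre: str,
    rate: np.ndarray,
    mix: Tuple[float, float, float],
) -> Tuple[str, np.ndarray]:
    """Apply indel/substitution errors; return (read, map pre-pos -> post-pos).

    ``rate`` is a per-base error probability array over ``pre``.  The returned
    map has one entry per pre-error base plus a final entry for the read end.
    """
    n = len(pre)
    arr = np.frombuffer(pre.encode(), dtype=np.uint8).copy()
    if n == 0:
        return "", np.zeros(1, dtype=np.int64)
    err = rng.random(n) < rate
    kind = np.zeros(n, dtype=np.int8)  # 0 none, 1 ins, 2 del, 3 sub
    idx = np.flatnonzero(err)
    if idx.size:
        u = rng.random(idx.size)
        k = np.where(u < mix[0], 1, np.where(u < mix[0] + mix[1], 2, 3))
        kind[idx] = k
    contrib = np.ones(n, dtype=np.int64)
    contrib[kind == 2] = 0
    contrib[kind == 1] = 2
    start = np.concatenate(([0], np.cumsum(contrib)))
    out = np.empty(start[-1], dtype=np.uint8)
    normal = kind == 0
    out[start[:-1][normal]] = arr[normal]
    ins = kind == 1
    if ins.any():
        out[start[:-1][ins]] = _BASES[rng.integers(0, 4, size=int(ins.sum()))]
        out[start[:-1][ins] + 1] = arr[ins]
    sub = kind == 3
    if sub.any():
        cur = arr[sub]
        # map ACGT codes to 0..3 via lookup
        lut = np.zeros(256, dtype=np.uint8)
        lut[_BASES] = np.arange(4)
        out[start[:-1][sub]] = _BASES[(lut[cur] + rng.integers(1, 4, size=int(sub.sum()))) % 4]
    return out.tobytes().decode(), start


def simulate_reads(
    genome: GenomeTruth,
    coverage: float,
    read_length: Tuple[float, int] = (8000.0, 3000),
    error_rate: float = 0.0,
    artefact_rates: Optional[Dict[str, float]] = None,
    seed: int = 0,
    error_mix: Tuple[float, float, float] = DEFAULT_ERROR_MIX,
) -> Tuple[List[SubRead], List[ReadTruth]]:
    """Sample reads from both strands of ``genome`` until the requested
    coverage is reached, injecting artefacts at the given per-read rates.

    ``artefact_rates`` keys: ``chimera``, ``adapter``, ``strand_jump``,
    ``low_quality`` (fractions of reads affected; structural artefacts are
    mutually exclusive per read).  A molecule additionally emits a second,
    shorter subread from the same insert with probability equal to the
    adapter rate, exercising longest-subread selection downstream.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if not 0.0 <= error_rate <= 0.3:
        raise ValueError("error_rate must be in [0, 0.3]")
    rates = {"chimera": 0.0, "adapter": 0.0, "strand_jump": 0.0, "low_quality": 0.0}
    if artefact_rates:
        unknown = set(artefact_rates) - set(rates)
        if unknown:
            raise ValueError(f"unknown artefact kinds: {sorted(unknown)}")
        rates.update(artefact_rates)
    rng = np.random.default_rng(seed)
    mean_len, min_len = read_length
    L = len(genome)
    target = coverage * L
    reads: List[SubRead] = []
    truths: List[ReadTruth] = []
    total = 0
    zmw = 0

    genome2 = genome.sequence + genome.sequence  # for origin-wrapping pieces

    def _piece(gb: int, ge: int, strand: str) -> str:
        s = genome2[gb:ge] if ge <= 2 * L else genome2[gb:ge]  # ge <= 2L by design
        return revcomp(s) if strand == "-" else s

    def _sample_locus(length_wanted: int) -> Tuple[int, int, str]:
        """One contiguous source interval of exactly ``length_wanted`` bases
        (shorter only if the linear genome cannot hold it at the drawn start)."""
        strand = "+" if rng.random() < 0.5 else "-"
        if genome.circular:
            gb = int(rng.integers(0, L))
            ge = gb + min(length_wanted, L)
            return gb, ge, strand
        lw = min(length_wanted, L)
        gb = int(rng.integers(-(lw - 1), L - 1 + 1))
        ge = min(gb + lw, L)
        gb = max(gb, 0)
        return gb, ge, strand

    while total < target:
        zmw += 1
        ell = _draw_length(rng, mean_len, min_len)
        # pick at most one structural artefact
        u = rng.random()
        structural = None
        if u < rates["chimera"]:
            structural = "chimera"
        elif u < rates["chimera"] + rates["adapter"]:
            structural = "adapter"
        elif u < rates["chimera"] + rates["adapter"] + rates["strand_jump"]:
            structural = "strand_jump"

        pieces: List[Tuple[int, int, str]] = []
        boundaries: List[Tuple[str, int]] = []  # (kind, pre-error read pos)
        if structural == "chimera":
            f = 0.3 + 0.4 * rng.random()
            l1 = max(200, int(ell * f))
            l2 = max(200, ell - l1)
            a = _sample_locus(l1)
            for _ in range(100):
                b = _sample_locus(l2)
                # demand unrelated loci: no proximity between the joined ends
                if min(abs(a[0] - b[0]), abs(a[1] - b[1])) > 2 * mean_len:
                    break
            pieces = [a, b]
            boundaries.append(("chimera", a[1] - a[0]))
        elif structural == "adapter":
            a = _sample_locus(ell)
            alen = a[1] - a[0]
            fold = max(200, alen - max(200, int(alen * (0.3 + 0.4 * rng.random()))))
            # read continues with the reverse complement of its preceding tail
            if a[2] == "+":
                back = (a[1] - (alen - fold), a[1], "-")
            else:
                back = (a[0], a[0] + (alen - fold), "+")
            pieces = [a, back]
            boundaries.append(("adapter", alen))
        elif structural == "strand_jump":
            l1 = max(200, int(ell * (0.3 + 0.4 * rng.random())))
            a = _sample_locus(ell)
            alen = a[1] - a[0]
            l1 = min(l1, alen - 200) if alen > 400 else alen // 2
            if a[2] == "+":
                pieces = [(a[0], a[0] + l1, "+"), (a[0] + l1, a[1], "-")]
            else:
                pieces = [(a[1] - l1, a[1], "-"), (a[0], a[1] - l1, "+")]
            boundaries.append(("strand_jump", l1))
        else:
            pieces = [_sample_locus(ell)]

        pre = "".join(_piece(*p) for p in pieces)
        n = len(pre)
        if n < min_len:
            continue
        rate = np.full(n, error_rate)
        lq_span = None
        if rng.random() < rates["low_quality"] and n > 1500:
            qlen = int(rng.integers(500, min(2000, n // 3) + 1))
            q0 = int(rng.integers(200, n - qlen - 200))
            rate[q0 : q0 + qlen] = max(3.0 * error_rate, 0.25)
            lq_span = (q0, q0 + qlen)

        read_seq, posmap = _apply_errors(rng, pre, rate, error_mix)
        artefacts: List[Tuple[str, object]] = []
        for kind, p in boundaries:
            artefacts.append((kind, int(posmap[p])))
        if lq_span is not None:
            artefacts.append(
                ("low_quality", (int(posmap[lq_span[0]]), int(posmap[lq_span[1]])))
            )
        rid = f"sim/{zmw}/0_{len(read_seq)}"
        reads.append(SubRead(rid, str(zmw), 0, read_seq))
        truths.append(ReadTruth(rid, pieces, artefacts))
        total += len(read_seq)

        if rng.random() < rates["adapter"]:
            # second, shorter pass over the same insert
            frac = 0.3 + 0.4 * rng.random()
            cut = max(min(int(n * frac), n), 1)
            sub_pre = pre[:cut]
            sub_pieces: List[Tuple[int, int, str]] = []
            need = cut
            for gb, ge, strand in pieces:
                take = min(need, ge - gb)
                if take <= 0:
                    break
                if strand == "+":
                    sub_pieces.append((gb, gb + take, "+"))
                else:  # '-' pieces are read from the interval's far end
                    sub_pieces.append((ge - take, ge, "-"))
                need -= take
            sub_seq, _ = _apply_errors(rng, sub_pre, np.full(cut, error_rate), error_mix)
            start = len(read_seq) + 50
            rid2 = f"sim/{zmw}/{start}_{start + len(sub_seq)}"
            reads.append(SubRead(rid2, str(zmw), 1, sub_seq))
            truths.append(ReadTruth(rid2, sub_pieces, [("truncated_pass", 0)]))
            total += len(sub_seq)

    return reads, truths


def reconstruct_read(genome: GenomeTruth, truth: ReadTruth) -> str:
    """Error-free reconstruction of a read from its source intervals
    (the conservation oracle used in tests)."""
    genome2 = genome.sequence + genome.sequence
    out = []
    for gb, ge, strand in truth.source_intervals:
        s = genome2[gb:ge]
        out.append(revcomp(s) if strand == "-" else s)
    return "".join(out)


# ---------------------------------------------------------------------------
# serialization

def write_genome_fasta(genome: GenomeTruth, path) -> None:
    with open(path, "w") as fh:
        circ = " circular=true" if genome.circular else ""
        fh.write(f">genome{circ}\n")
        for i in range(0, len(genome.sequence), 80):
            fh.write(genome.sequence[i : i + 80] + "\n")


def write_reads_fasta(reads: Sequence[SubRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n")
            for i in range(0, len(r.sequence), 80):
                fh.write(r.sequence[i : i + 80] + "\n")


def write_truth_json(genome: GenomeTruth, truths: Sequence[ReadTruth], path) -> None:
    doc = {
        "genome": {
            "length": len(genome),
            "circular": genome.circular,
            "repeat_intervals": [list(t) for t in genome.repeat_intervals],
        },
        "reads": [
            {
                "read_id": t.read_id,
                "source_intervals": [list(x) for x in t.source_intervals],
                "artefacts": [
                    {"kind": k, "where": list(w) if isinstance(w, tuple) else w}
                    for k, w in t.artefacts
                ],
            }
            for t in truths
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
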