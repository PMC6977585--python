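# Methods

This note documents the models, parameters and design decisions behind
`olcasm`, in the spirit of an assembler's methods supplement.  Nothing here
states a result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Scope and intent

`olcasm` is a desk-scale re-implementation of the MARVEL/Dazzler family of
overlap–layout–consensus ideas: alignment piles as the central data
structure, repeat masking *before* seeding, read patching before layout, and
a string graph toured into primary contigs.  It is meant to make each stage
inspectable and testable at the 10 kb–1 Mb scale on one CPU; it makes no
claim of handling gigabase genomes, and signal-level polishing (Arrow-class
consumer of raw instrument data) is explicitly out of scope — a deterministic
column-majority consensus stands in for it (see *Consensus*).

## Synthetic data model

The simulator defines the conditions under which the assembler is tested.

* **Genomes** are i.i.d. uniform ACGT sequences with planted repeat
  families: each family has a random consensus of `unit_length` bases;
  copies are mutated from it by per-base substitution at rate
  `1 − identity` and placed without overlap (contiguously for tandem
  families).  Default copy identity 0.95 — typical of young interspersed
  repeat families, and low enough that copies do not merge into one
  alignment at the default divergence ceiling.
* **Reads** are sampled from both strands until the requested coverage is
  reached.  Lengths are log-normal (σ = 0.45, mean as requested, hard
  truncation at the minimum) — long-tailed like real single-molecule data
  without extra parameters.  For linear genomes, reads may overhang the ends
  and are clipped, so genome ends stay covered; for circular genomes reads
  wrap the origin.
* **Errors** are indel-dominated: 55% insertions / 25% deletions / 20%
  substitutions of the total error rate (raw PacBio CLR-like), applied
  per-base.  Error rate 0.10 is used as the standard "noisy" condition;
  two such reads are ~19% divergent from each other.
* **Artefacts** per read (mutually exclusive for the structural kinds):
  *chimera* — blunt join of two unrelated loci (no shared sequence at the
  junction, so a span-based detector can in principle find it); *adapter* —
  the read continues with the reverse complement of its preceding tail
  (fold-back); *strand jump* — continuation on the opposite strand of the
  adjacent locus (two-orientation signature without coordinate mirroring);
  *low quality* — an interval with error rate max(3× baseline, 0.25).  Each
  ZMW emits a second, shorter subread with probability equal to the adapter
  rate, exercising longest-subread selection.  The published protocol this
  follows does not quantify artefact frequencies in its data; defaults of
  1–5% are chosen for test power, not realism.
* All randomness flows from a single `numpy` generator; identical seeds give
  byte-identical outputs.

What the simulator does **not** model: per-base quality values, context-
dependent error profiles (homopolymer-length biases beyond what uniform
indels induce), heterozygosity, and chimera junctions *inside* repeats.
Passing tests therefore demonstrate algorithmic correctness under controlled
conditions, not performance on real instrument data.

## Read database

Longest subread per ZMW first, then the 4-kb minimum length filter (the
protocol's stated order; in edge cases a ZMW whose longest subread is short
contributes nothing).  PacBio-style `movie/zmw/first_last` names are grouped
by ZMW; any other name is a singleton ZMW, so arbitrary FASTA assembles.
All masks/patches/quality segments live in per-read interval tracks:
0-based, half-open, sorted, non-overlapping, adjacent intervals merged —
normalization is idempotent and unions are order-independent, which is what
makes the whole pipeline deterministic.

## Masking

* **DUST-style low complexity**: windowed triplet score
  `sum_t c_t(c_t−1)/2 / (w−2)`, window 64, threshold 2.0 (score ≈ 0.5 on
  random sequence, ≈ 30 on a homopolymer).
* **Tandem**: exact k-mer (k = 8) self-matches at offsets ≤ 500 grouped per
  offset; a run must contain a match about every 10 bases
  (`count ≥ 0.1 × run extent`), extend over at least `max(2k, period/2)`
  bases, and span ≥ 100 bases in total.  The density requirement is what
  separates true tandems (which match at almost every position) from chance
  ~10-bp duplications in random sequence.
* **Coverage mask**: reads are split, in database order, into groups whose
  total length reaches the genome size estimate (1×); within each group all
  reads are aligned all-vs-all and positions covered by ≥ 10 *distinct*
  other reads are masked.  Counting reads rather than alignments is a
  deliberate reading of the rule ("other reads"); the genome size estimate
  is a required configuration input (in the original protocol it came from
  flow cytometry / related genomes), and no estimation from data is
  attempted.

## Overlapper

Seed–cluster–extend with these choices:

* k = 14; seeds must start outside the mask on both reads; seeds are
  subsampled 1-in-4 by a deterministic hash of the k-mer value (applied
  identically on the index and query side, so pairing is never broken).
* Seeds for one read pair and orientation are clustered by diagonal
  (clusters split at diagonal jumps > 100); a cluster needs ≥ 3 seeds.
* Extension is chunked: 1,000-base chunks accepted while the chunk's banded
  edit distance stays within `max_divergence` = 0.30; on rejection the chunk
  halves down to 32 bases, localizing divergence points (chimeric junctions,
  true overlap ends) to a few tens of bases.  The final sub-chunk is forced
  onto a read end when fewer than 32 bases remain, because the dovetail
  classification slack (25 bases) is smaller than the chunk granularity.
* The final segment is re-aligned globally (edlib), so the reported `diffs`
  is *exactly* the edit distance of the reported segments; a max-scoring
  window trim (+1 per matching column, −2 per difference, applied when it
  would remove > 15 bases) removes tails that slid past a divergence point,
  and the trimmed segment is re-aligned again.
* `min_alignment_length` 600, B-coordinates stored on B's forward strand,
  unit-cost edit distance (no affine gaps) — matching the diff-count
  semantics of trace-point-style assemblers without implementing trace
  points.  None of these values come from the published protocol (its
  aligner parameters live in supplementary material not reproduced here);
  they follow common long-read-overlapper practice and are config-exposed.

Chaining maximizes total aligned bases per chain (gap ≤ 1,500 bases in both
reads, members strictly co-linear and non-overlapping; ties: fewer diffs,
then lexicographic coordinates), extracted best-first so each alignment
joins at most one chain.  A chain is **proper** when each end reaches within
25 bases of an end of either read; a failing end inside a repeat interval
makes it **premature-in-repeat**, which triggers mask-free re-alignment of
that read pair (the repcomp analogue); otherwise **improper**.

## Patching

All detection happens per alignment pile:

* **Chimera break**: a position outside masked repeats that no alignment
  spans with ±100-base margin, while ≥ 3 alignment ends lie within 600 bases
  on each side.  No calls within 500 bases of a read end (spanning is
  undefined there).
* **Fold-back / strand jump**: ≥ 2 partners each aligning twice, in opposite
  orientations, to adjacent intervals of the read; mirrored partner
  intervals ⇒ adapter, non-mirrored ⇒ strand jump; break at the median fold
  point.
* **Low quality**: ≥ 400-base runs of 100-base segments whose pile
  divergence exceeds max(1.5 × median, 0.03) at coverage ≥ 3, replaced by
  the lowest-divergence partner's corresponding sequence (mapped through the
  alignment path).  The absolute floor keeps the cutoff meaningful on
  error-free piles, where the median divergence is 0.
* **Repeat re-analysis rule**: on the patched reads, every repeat interval
  ≤ 8,000 bases must be spanned, with ≥ 500 anchored bases on both sides, by
  ≥ 3 proper chains, or the read is excluded outright (not split).  The
  spanning-flank length is not stated in the published protocol; 500 bases
  was chosen because a chain merely touching a repeat cannot certify
  contiguity across it.  Intervals too close to a read end to admit both
  flanks are skipped (they cannot be certified either way).  The 8-kb limit
  is read as the repeat interval length.

Breaks split reads (`<id>.part<i>`); fragments below the minimum read length
are discarded.

## Layout and consensus

Quality track: mean alignment divergence per 100-base segment, distributed
along each alignment's path; sentinel −1 below coverage 2.  The detailed
repeat mask marks regions whose distinct-partner coverage exceeds 2× the
expected coverage (total patched bases / genome size estimate).

Pile filtering keeps proper dovetail chains as edges between oriented reads
(skew-symmetric twin edges maintained), records contained reads separately,
and drops alignments lying entirely within repeats on both reads.
Transitive reduction examines edges weakest-overlap-first and removes an
edge only when a two-edge path of *remaining* edges implies it within a
200-base fuzz — so reachability is preserved by construction (and verified
against a brute-force closure oracle in the tests).  Touring walks maximal
unbranched paths from tips, then cycles; at a branch the extension with the
most aligned bases wins (ties: fewer diffs, then smaller read index).  A
path returning to its start is flagged circular.  Single-read paths whose
read is fully covered by pile alignments are dropped as redundant — they
carry no sequence not already in a longer path.

**Consensus** concatenates the path's oriented reads trimmed at edge
overlaps, then corrects each backbone column by majority vote over all pile
alignments of the path reads: substitutions need a strict majority over the
backbone base, deletions a majority over every base, insertions a majority
of total insertion evidence at the junction (with the plurality sequence
inserted; ties keep the backbone).  A second vote round re-maps all reads
onto the first-round consensus, re-anchoring indel votes (the classic
two-round polishing effect).  On error-free input both rounds are exactly
the identity; at 10% read error and 30× the consensus reaches ~99.2%
identity — the residual is concentrated in homopolymer-length ambiguity that
a signal-level polisher would resolve and a column-majority vote cannot.

## Mitogenome mode

The circular reference is doubled so one pass of the linear aligner finds
origin-wrapping chains (coordinates map back modulo the length).  A read is
kept iff some chain has aligned read length within [4,000, 14,000] bases and
≤ 1,500 unaligned read bases (tails plus internal gaps) — the bounds are read
as *aligned read bases*, which is consistent with the upper bound being the
reference scale.  After patching, reads are split into fragments of half the
reference length sharing exactly 1,500 bases, so the final circle consists of
more than one read.  After assembly the contig is mapped to itself; a
prefix–suffix self-overlap of ≥ 500 bases at ≥ 0.95 identity is trimmed and
the contig flagged circular; an optional anchor sequence rotates the circle.

## Determinism

Single-process execution; every collection is iterated in sorted order;
all tie-breaks are total orders; the simulator uses one seeded generator.
Two runs with identical config and input produce byte-identical FASTA, GFA
and statistics (verified in the tests).

## Problem sizes used in tests and the acceptance script

Chosen so the full suite and the script each run in minutes on one CPU:
error-free reconstruction 100 kb at 30× (8-kb reads); noisy reconstruction
80–100 kb at 30×, 10% error, one 2-kb/2-copy repeat family; chimera study
80 kb at 30× with 5% chimeras; coverage masking 200 kb with a 2-kb/20-copy
family at 30× (the 200-kb genome keeps a 1× group at ~25 reads, enough for
the ≥ 10-read threshold to be attainable on repeats yet far above unique
coverage); mitogenome 15,303 bases at 40×; transitive reduction 100 random
layout graphs of ≤ 12 reads; alignment oracle 80–200 pairs of 0.5–2 kb.

## Known limitations

* All-vs-all alignment is O(pairs); practical up to a few hundred reads per
  group — by design, not a target for optimization.
* No bubble popping, haplotype separation, or scaffolding; heterozygous
  inputs will produce duplicated paths.
* Consensus accuracy saturates near 99.2% at 10% read error; homopolymer
  run lengths are the dominant residual error class.
* The chimera rule cannot certify repeats within 500 bases of a read end;
  junctions hiding there pass through.
* Reads shorter than ~2× `min_alignment_length` contribute little signal and
  are best filtered by the 4-kb set-up threshold.
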