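# olcasm

A desk-scale **overlap–layout–consensus (OLC) assembler for noisy long
reads**, built around the alignment-pile analysis used by MARVEL/Dazzler-style
assemblers: coverage-based repeat masking, read *patching* (detection and
correction of chimeric joins, missed-adapter fold-backs, polymerase strand
jumps, and long low-quality segments), string-graph layout with transitive
reduction, column-majority consensus, and a reference-baited **circular
mitogenome mode**.  A synthetic genome/read simulator with machine-readable
ground truth ships with the package, so every stage is testable without any
external data.

It is written for people who want to *study or teach* how a long-read
assembler works — every stage is an inspectable library function with
standard text formats (FASTA/PAF/BED/GFA/JSON) between stages — not for
assembling real gigabase genomes.

## The method

Given reads `R` from a genome at coverage `c`:

1. **Set-up.** Keep the longest subread of each ZMW, drop reads < 4 kb, store
   the rest in a read database with per-read interval *tracks*.
2. **Repeat masking.** Low-complexity intervals (windowed triplet DUST
   score), tandem repeats (periodic self-matches), and interspersed repeats:
   reads are partitioned into groups of ~1× genome coverage; within each
   group all reads are aligned all-vs-all and every position where ≥ 10
   distinct other reads align is masked — at 1× coverage, unique sequence
   cannot attract that much depth.
3. **Overlap.** k-mer–seeded (k = 14, seeds outside the masks), diagonal-
   clustered, chunk-extended local alignment; the reported `diffs` of every
   alignment equals the exact edit distance of its reported segments.
   Alignments per read pair are chained; a chain is *proper* iff both ends
   reach a read boundary.  Proper chains that end prematurely inside a
   repeat trigger mask-free re-alignment of that pair.
4. **Patching.** From each read's alignment pile: chimera breaks (a position
   spanned by no alignment but flanked by alignment ends on both sides),
   fold-back/strand-jump breaks (partners aligning twice in opposite
   orientations to adjacent intervals), and low-quality patches (segments
   with divergence ≫ the pile median, replaced by the best partner's
   sequence).  Additionally, any read with a repeat interval ≤ 8 kb that is
   not spanned (with 500-b flanks) by **≥ 3 proper chains** is excluded — the
   enhanced chimera rule for junctions hiding inside repeats.
5. **Assembly.** Overlap the patched reads again; compute a per-segment
   quality track and a detailed repeat mask; keep proper dovetail chains as
   string-graph edges, set contained reads aside; transitively reduce; tour
   maximal unbranched paths into primary contigs; polish each contig with a
   deterministic column-majority consensus (two vote rounds).
6. **Statistics.** The N(x) curve — the length of the smallest contig needed,
   taking contigs longest-first, to reach x% of the assembly — and N50 =
   N(50).

The **mito mode** baits reads against a doubled circular reference, keeps
reads with a proper circular alignment chain (aligned length 4–14 kb,
≤ 1,500 unaligned bases), splits them into fragments sharing a 1,500-bp
overlap so the circle closes through > 1 read, assembles, and circularizes by
mapping the contig to itself and trimming the redundant overlap.

## Worked example

```bash
olcasm simulate --length 40000 --coverage 25 --read-mean 7000 --seed 3 \
    --outdir sim
olcasm assemble sim/reads.fasta --genome-size 40000 --outdir asm
```

which prints (reads simulated error-free here):

```
simulated 152 reads from a 40000-b genome
1 contigs, 40000 b, N50 40000
```

i.e. the 152 reads (~25× of a 40-kb genome) assemble into a single contig
whose 40,000-base sequence is exactly the simulated genome (up to strand),
and whose N50 therefore equals the contig length.  `asm/` contains the
contigs (`contigs.fasta`), the reduced string graph (`graph.gfa`), mask
tracks (BED), the patched reads, the event report, and `stats.json` with the
full N(x) curve.

A circular organelle-scale assembly:

```bash
olcasm simulate --length 15303 --circular --coverage 40 --read-mean 8000 \
    --read-min 6000 --seed 5 --outdir msim
olcasm mito msim/reads.fasta --reference msim/genome.fasta --outdir masm
```

prints `{"reads_in": 62, "baited": 62, "kept_after_filter": 53,
"fragments": 89, "length": 15303, "circular": true}` — the 15,303-base
circular genome is recovered at exactly its true length.

The genome size estimate (`--genome-size`, config `genome_size_estimate`)
matters: the 1× read grouping for coverage masking and the expected-coverage
repeat threshold both derive from it, as they would from a flow-cytometry or
related-genome estimate on real data.

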