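"""Pipeline driver: set-up -> patch -> assemble -> consensus (+ mito mode).

The stages mirror a MARVEL-style long-read assembly: set-up builds the read
database (longest subread per ZMW, minimum length); the patch phase masks
repeats, aligns all raw reads, re-aligns mask-free any chain that ends
prematurely in a repeat, and corrects read artefacts (with the additional
repeat re-analysis rule for chimeras hiding in repeats up to 8 kb); the
assembly phase recomputes overlaps on the patched reads, builds quality and
repeat tracks, filters piles to proper dovetail chains, reduces the string
graph, tours primary contigs, and polishes each by column-majority consensus.
Execution is single-process and deterministic for a fixed config and input.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .config import PipelineConfig
from .intervals import IntervalTrack, complement as iv_complement, merge_tracks, total_length
from .layout import (AssemblyStats, Contig, LayoutParams, OverlapEdge,
                     assembly_stats, consensus, detailed_repeat_mask,
                     filter_piles, polish, quality_track, tour,
                     transitive_reduction, write_contigs_fasta, write_gfa,
                     write_stats_json)
from .masking import CoverageMaskParams, DustParams, mask_reads
from .mito import (MitoParams, bait_reads, circularize, filter_circular_chains,
                   split_with_overlap)
from .overlap import (AlignmentChain, LocalAlignment, Pile, PREMATURE_IN_REPEAT,
                      all_vs_all, chain_alignments, classify_chain, local_align,
                      write_paf)
from .patching import (EXCLUDE, apply_chimera_repeat_rule, apply_patches,
                       detect_artefacts)
from .readstore import ReadDB, SubRead, build_db, read_sequences, write_fasta, write_track_bed

log = logging.getLogger(__name__)


@dataclass
class AssemblyResult:
    db: Optional[ReadDB]
    contigs: List[Contig] = field(default_factory=list)
    stats: AssemblyStats = field(default_factory=lambda: assembly_stats([]))
    edges: List[OverlapEdge] = field(default_factory=list)
    reduced_edges: List[OverlapEdge] = field(default_factory=list)
    contained: List[str] = field(default_factory=list)
    excluded: List[str] = field(default_factory=list)
    tracks: Dict[str, IntervalTrack] = field(default_factory=dict)


def _chains_by_read(piles: Sequence[Pile], repeat_track: IntervalTrack,
                    max_gap: int, end_slack: int) -> Dict[str, List[AlignmentChain]]:
    """Classified A-side chains for every pile."""
    out: Dict[str, List[AlignmentChain]] = {}
    for pile in piles:
        chains: List[AlignmentChain] = []
        for key in sorted(pile.by_pair()):
            group = pile.by_pair()[key]
            for chain in chain_alignments(group, max_gap):
                classify_chain(chain, repeat_track, end_slack)
                chains.append(chain)
        out[pile.a_id] = chains
    return out


def _realign_premature(piles: List[Pile], db: ReadDB, repeat_track: IntervalTrack,
                       config: PipelineConfig) -> List[Pile]:
    """Mask-free re-alignment of read pairs whose chains end prematurely in
    repeats (the LAseparate/repcomp step); replaces those pairs' alignments."""
    ap = config.align_params()
    premature: set = set()
    for pile in piles:
        for (b_id, orientation), group in sorted(pile.by_pair().items()):
            if db.index_of(b_id) <= db.index_of(pile.a_id):
                continue
            for chain in chain_alignments(group, ap.max_gap):
                if classify_chain(chain, repeat_track, ap.end_slack) == PREMATURE_IN_REPEAT:
                    premature.add((pile.a_id, b_id))
                    break
    if not premature:
        return piles
    log.info("re-aligning %d read pairs without masks", len(premature))
    replaced: Dict[str, List[LocalAlignment]] = {p.a_id: [] for p in piles}
    drop = premature | {(b, a) for a, b in premature}
    for pile in piles:
        for aln in pile.alignments:
            if (aln.a_id, aln.b_id) not in drop:
                replaced[aln.a_id].append(aln)
    for a_id, b_id in sorted(premature):
        new = local_align(db[a_id].sequence, db[b_id].sequence, (), (),
                          ap, a_id=a_id, b_id=b_id)
        for aln in new:
            replaced[a_id].append(aln)
            replaced[b_id].append(aln.mirrored())
    return [Pile(p.a_id, sorted(replaced[p.a_id], key=LocalAlignment.sort_key))
            for p in piles]


def patch_phase(db: ReadDB, config: PipelineConfig) -> Tuple[ReadDB, Dict[str, IntervalTrack], list]:
    """Masking, raw-read alignment, artefact correction.

    Returns the patched database, the mask tracks, and the patch events.
    """
    ap = config.align_params()
    tracks = mask_reads(
        db,
        DustParams(config.dust_window, config.dust_threshold),
        config.tandem_max_period, config.tandem_min_span,
        CoverageMaskParams(config.genome_size_estimate,
                           config.coverage_mask_threshold),
        ap,
    )
    mask = tracks["mask"]
    log.info("masks: dust %d b, tandem %d b, coverage %d b",
             tracks["dust"].total_length(), tracks["tandem"].total_length(),
             tracks["coverage"].total_length())
    piles = all_vs_all(db, mask, ap)
    piles = _realign_premature(piles, db, mask, config)
    pp = config.patch_params()
    patched: List[SubRead] = []
    events_all = []
    for pile in piles:
        events = detect_artefacts(pile, db, mask, pp)
        events_all.extend(events)
        patched.extend(apply_patches(db[pile.a_id], events, config.min_read_length))
    log.info("patching: %d events, %d reads in, %d patched reads out",
             len(events_all), len(db), len(patched))
    db2 = build_db(patched, config.min_read_length)
    return db2, tracks, events_all


def assembly_phase(db: ReadDB, config: PipelineConfig) -> AssemblyResult:
    """Overlap the patched reads and lay out contigs."""
    ap = config.align_params()
    lp = config.layout_params()
    result = AssemblyResult(db=db)
    if len(db) == 0:
        return result
    base = mask_reads(db, DustParams(config.dust_window, config.dust_threshold),
                      config.tandem_max_period, config.tandem_min_span)
    piles = all_vs_all(db, base["mask"], ap)
    expected_cov = db.total_length() / config.genome_size_estimate
    repeat_track = merge_tracks(
        base["mask"],
        detailed_repeat_mask(piles, db, expected_cov, config.repeat_cov_factor))
    piles = _realign_premature(piles, db, repeat_track, config)

    # enhanced chimera detection: repeats that no three proper chains span
    chains = _chains_by_read(piles, repeat_track, ap.max_gap, ap.end_slack)
    rule = config.chimera_rule_params()
    excluded = sorted(
        rid for rid, ch in chains.items()
        if apply_chimera_repeat_rule(rid, ch, repeat_track, rule,
                                     read_length=db.length_of(rid)) == EXCLUDE)
    if excluded:
        log.info("repeat re-analysis excluded %d reads", len(excluded))
    keep_ids = [r.read_id for r in db if r.read_id not in set(excluded)]
    db3 = ReadDB([db[rid] for rid in keep_ids])
    drop = set(excluded)
    piles = [Pile(p.a_id, [a for a in p.alignments if a.b_id not in drop])
             for p in piles if p.a_id not in drop]

    quality = {p.a_id: quality_track(p, db3.length_of(p.a_id), lp.segment,
                                     lp.min_quality_cov)
               for p in piles}
    edges, contained = filter_piles(piles, db3, repeat_track, quality, ap, lp)
    lengths = {r.read_id: len(r) for r in db3}
    reduced = transitive_reduction(edges, lp.fuzz, lengths)
    contigs = tour(reduced, db3, contained)
    contigs = _drop_redundant_singletons(contigs, piles, db3, lp)
    pile_map = {p.a_id: p for p in piles}
    kept: List[Contig] = []
    for c in contigs:
        c.sequence = consensus(c, db3, pile_map)
        if len(c.path) > 1:
            c.sequence = polish(c.sequence, db3, ap, rounds=1)
        if c.circular:
            c = circularize(c, config.mito_params(), ap)
        kept.append(c)
    kept.sort(key=lambda c: (-len(c), c.name))
    for i, c in enumerate(kept):
        c.name = f"contig_{i + 1}"
    result.contigs = kept
    result.stats = assembly_stats([len(c) for c in kept])
    result.edges = edges
    result.reduced_edges = reduced
    result.contained = contained
    result.excluded = excluded
    result.tracks = {"repeat": repeat_track}
    return result


def _drop_redundant_singletons(contigs: List[Contig], piles: Sequence[Pile],
                               db: ReadDB, lp: LayoutParams) -> List[Contig]:
    """Drop single-read paths whose read is fully covered by its pile — they
    repeat sequence already represented by a longer path."""
    pile_map = {p.a_id: p for p in piles}
    out = []
    for c in contigs:
        if len(c.path) > 1:
            out.append(c)
            continue
        rid = c.path[0][0]
        pile = pile_map.get(rid)
        if pile is None or not pile.alignments:
            out.append(c)
            continue
        n = db.length_of(rid)
        covered = total_length(
            iv_complement([(a.a_begin, a.a_end) for a in pile.alignments], n))
        if covered > 2 * lp.end_slack:
            out.append(c)
    return out


def run_pipeline(reads, config: Optional[PipelineConfig] = None,
                 outdir=None) -> AssemblyResult:
    """Full assembly of a read set (path to FASTA/FASTQ, or SubRead list)."""
    config = config or PipelineConfig()
    if isinstance(reads, (str, os.PathLike)):
        reads = read_sequences(reads)
    for name, value, prov in config.provenance_lines():
        log.info("parameter %s = %r [%s]", name, value, prov)
    db = build_db(reads, config.min_read_length)
    if len(db) == 0:
        log.warning("no reads pass set-up; empty assembly")
        result = AssemblyResult(db=db)
        if outdir:
            _write_outputs(result, config, outdir)
        return result
    db2, mask_tracks, events = patch_phase(db, config)
    result = assembly_phase(db2, config)
    for name in ("dust", "tandem", "coverage", "mask"):
        if name in mask_tracks:
            result.tracks[name] = mask_tracks[name]
    if outdir:
        _write_outputs(result, config, outdir, events)
    return result


def _write_outputs(result: AssemblyResult, config: PipelineConfig, outdir,
                   events: Sequence = ()) -> None:
    os.makedirs(outdir, exist_ok=True)
    join = lambda n: os.path.join(outdir, n)  # noqa: E731
    write_contigs_fasta(result.contigs, join("contigs.fasta"))
    write_gfa(result.reduced_edges, result.db, join("graph.gfa"),
              result.contained) if result.db and len(result.db) else open(
                  join("graph.gfa"), "w").write("H\tVN:Z:1.0\n")
    write_stats_json(result.stats, join("stats.json"))
    config.to_yaml(join("config.yaml"))
    for name, track in result.tracks.items():
        write_track_bed(track, join(f"{name}.bed"))
    if result.db is not None and len(result.db):
        write_fasta(result.db, join("patched_reads.fasta"))
    with open(join("events.tsv"), "w") as fh:
        for ev in events:
            fh.write(f"{ev.read_id}\t{ev.kind}\t{ev.begin}\t{ev.end}\n")


# ---------------------------------------------------------------------------
# mitogenome mode

def assemble_mito(reads, reference: str, config: Optional[PipelineConfig] = None,
                  outdir=None) -> Tuple[Optional[Contig], dict]:
    """Reference-baited circular assembly; returns (contig, report)."""
    config = config or PipelineConfig()
    ap = config.align_params()
    mp = config.mito_params()
    if isinstance(reads, (str, os.PathLike)):
        reads = read_sequences(reads)
    db = build_db(reads, min_length=config.min_read_length)
    candidates = bait_reads(db, reference, ap)
    kept = filter_circular_chains(candidates, mp.chain_filter)
    report = {"reads_in": len(db), "baited": len(candidates),
              "kept_after_filter": len(kept)}
    if not kept:
        return None, report
    mito_db = ReadDB(kept)
    # read patching on the baited set
    piles = all_vs_all(mito_db, None, ap)
    pp = config.patch_params()
    patched: List[SubRead] = []
    for pile in piles:
        evs = detect_artefacts(pile, mito_db, IntervalTrack(), pp)
        patched.extend(apply_patches(mito_db[pile.a_id], evs, min_length=1000))
    target = mp.target_length or max(len(reference) // 2, 2 * mp.split_overlap)
    fragments: List[SubRead] = []
    for r in patched:
        fragments.extend(split_with_overlap(r, target, mp.split_overlap))
    report["fragments"] = len(fragments)
    frag_db = build_db(fragments, min_length=min(1000, target))
    lp = config.layout_params()
    piles = all_vs_all(frag_db, None, ap)
    quality = {p.a_id: quality_track(p, frag_db.length_of(p.a_id), lp.segment)
               for p in piles}
    edges, contained = filter_piles(piles, frag_db, IntervalTrack(), quality, ap, lp)
    lengths = {r.read_id: len(r) for r in frag_db}
    reduced = transitive_reduction(edges, lp.fuzz, lengths)
    contigs = tour(reduced, frag_db, contained)
    contigs = _drop_redundant_singletons(contigs, piles, frag_db, lp)
    pile_map = {p.a_id: p for p in piles}
    best: Optional[Contig] = None
    for c in contigs:
        c.sequence = consensus(c, frag_db, pile_map)
        if len(c.path) > 1:
            c.sequence = polish(c.sequence, frag_db, ap, rounds=1)
        c = circularize(c, mp, ap)
        if best is None or len(c) > len(best):
            best = c
    if best is not None:
        best.name = "mitogenome"
        report["length"] = len(best)
        report["circular"] = best.circular
    if outdir and best is not None:
        os.makedirs(outdir, exist_ok=True)
        write_contigs_fasta([best], os.path.join(outdir, "mito.fasta"))
        import json

        with open(os.path.join(outdir, "mito_report.json"), "w") as fh:
            json.dump(report, fh, indent=1)
    return best, report
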