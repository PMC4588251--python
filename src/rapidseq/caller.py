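"""Haplotype-based small-variant calling.

Stages, per the classic local-reassembly design:

1. **Callable / active regions** - a pileup scan over the sorted,
   duplicate-flagged alignments finds columns with adequate coverage
   from confidently mapped reads, then marks maximal runs of columns
   with a non-trivial fraction of non-reference evidence as active
   regions, padded with flanking context (extra wide when the evidence
   includes indels or long soft clips).
2. **Assembly** - reads overlapping each region (plus unplaced mates
   anchored there) are assembled into a De Bruijn graph over the
   reference backbone, rebuilt with longer k-mers when the graph is
   degenerate (cyclic or with a disconnected backbone); all
   source-to-sink paths become candidate haplotypes, capped at 128
   preferring higher-weight paths.
3. **Events** - each haplotype is aligned globally back to the region
   reference and its variant events are extracted and left-normalized.
4. **Genotyping** - pair-HMM read likelihoods P(r|H) are reduced to
   per-event likelihoods P(r|e) (max over supporting haplotypes),
   multiplied into pileup likelihoods, and combined with a
   heterozygosity prior into diplotype posteriors P(e1 e2|R); the
   winning diplotype is emitted with its genotype quality.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from rapidseq.align import ScoringScheme, encode, global_align
from rapidseq.hmm import HmmParams, pair_hmm
from rapidseq.mapper import AlignmentRecord, FLAG_MATE_REVERSE
from rapidseq.reference import ReferenceGenome, revcomp
from rapidseq.variants import (MAX_INDEL_LEN, VariantCall, VariantEvent,
                               normalize_variant)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CallerParams:
    min_depth: int = 4
    min_mapq: int = 20
    evidence_threshold: float = 0.15
    base_pad: int = 50
    indel_pad: int = 150
    clip_evidence_min: int = 10      # soft clip length counting as indel evidence
    k_schedule: tuple[int, ...] = (10, 25, 40, 55)
    prune_weight: int = 2
    max_haplotypes: int = 128
    max_enumerated_paths: int = 1024
    max_region_len: int = 2500
    theta: float = 0.001             # heterozygosity prior for non-ref diplotypes
    hmm: HmmParams = field(default_factory=HmmParams)
    scheme: ScoringScheme = field(default_factory=ScoringScheme)


@dataclass
class ActiveRegion:
    contig: str
    start: int      # padded, half-open
    end: int
    has_indel: bool = False


@dataclass
class Haplotype:
    sequence: str
    weight: int                    # minimum edge weight along the path
    events: list[VariantEvent] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Region detection
# ---------------------------------------------------------------------------

def _usable(rec: AlignmentRecord, params: CallerParams) -> bool:
    return (not rec.is_unmapped and not rec.is_duplicate
            and not rec.is_supplementary and rec.mapq >= params.min_mapq)


def detect_regions(records: list[AlignmentRecord], ref: ReferenceGenome,
                   params: CallerParams = CallerParams()) -> list[ActiveRegion]:
    """Scan pileup columns for variant evidence and return padded,
    merged active regions within callable territory."""
    regions: list[ActiveRegion] = []
    by_contig: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        if rec.contig is None or rec.is_unmapped or rec.is_duplicate:
            continue
        by_contig.setdefault(rec.contig, []).append(rec)

    for contig, seq in ref.contigs.items():
        recs = by_contig.get(contig, [])
        n = len(seq)
        depth = np.zeros(n + 1, dtype=np.int32)
        nonref = np.zeros(n, dtype=np.int32)
        indel = np.zeros(n, dtype=np.int32)
        ref_codes = encode(seq)
        for rec in recs:
            # indel/clip evidence is collected from every mapped record
            # (junction reads often align with low MAPQ or as
            # supplementaries); depth and mismatch evidence only from
            # confident primary alignments
            confident = _usable(rec, params)
            codes = encode(rec.seq) if confident else None
            rpos, qpos = rec.pos, 0
            first = True
            for op, ln in rec.cigar:
                if op == "M":
                    if confident:
                        depth[rpos] += 1
                        depth[min(n, rpos + ln)] -= 1
                        seg = codes[qpos:qpos + ln]
                        window = ref_codes[rpos:rpos + ln]
                        mism = np.nonzero(seg[:len(window)] != window)[0]
                        if len(mism):
                            np.add.at(nonref, rpos + mism, 1)
                    rpos += ln
                    qpos += ln
                elif op == "I":
                    if 0 <= rpos < n:
                        indel[rpos] += 1
                    qpos += ln
                elif op == "D":
                    if confident:
                        # a deletion-spanning read still covers the column
                        depth[rpos] += 1
                        depth[min(n, rpos + ln)] -= 1
                    indel[rpos:min(n, rpos + ln)] += 1
                    rpos += ln
                elif op == "S":
                    if ln >= params.clip_evidence_min:
                        col = rec.pos if first else rpos
                        if 0 <= col < n:
                            indel[col] += 1
                    qpos += ln
                first = False
        depth = np.cumsum(depth[:-1])
        callable_mask = depth >= params.min_depth
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(depth > 0, (nonref + indel) / np.maximum(depth, 1), 0.0)
        active = callable_mask & (frac >= params.evidence_threshold)

        # runs of active columns -> padded intervals
        idx = np.nonzero(active)[0]
        if len(idx) == 0:
            continue
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(idx) - 1]))
        intervals = []
        for s, e in zip(starts, ends):
            lo, hi = int(idx[s]), int(idx[e]) + 1
            pad = params.indel_pad if indel[lo:hi].any() else params.base_pad
            intervals.append((max(0, lo - pad), min(n, hi + pad),
                              bool(indel[lo:hi].any())))
        merged: list[list] = []
        for lo, hi, has_indel in intervals:
            if merged and lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
                merged[-1][2] = merged[-1][2] or has_indel
            else:
                merged.append([lo, hi, has_indel])
        for lo, hi, has_indel in merged:
            hi = min(hi, lo + params.max_region_len)
            regions.append(ActiveRegion(contig, lo, hi, has_indel))
    return regions


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _kmer_edges(seqs: list[str], k: int) -> dict[tuple[str, str], int]:
    edges: dict[tuple[str, str], int] = {}
    for seq in seqs:
        for i in range(len(seq) - k):
            a = seq[i:i + k]
            b = seq[i + 1:i + k + 1]
            if "N" in a or "N" in b:
                continue
            edges[(a, b)] = edges.get((a, b), 0) + 1
    return edges


def assemble_haplotypes(read_seqs: list[str], ref_seg: str,
                        params: CallerParams = CallerParams()) -> list[Haplotype]:
    """De Bruijn assembly of region reads over the reference backbone.

    Tries each k in the schedule until the graph is non-degenerate:
    backbone k-mers all distinct (else the backbone itself is a cycle),
    graph acyclic, and a source-to-sink path exists.  Read edges seen
    fewer than ``prune_weight`` times are pruned; backbone edges are
    always kept.  Returns at most ``max_haplotypes`` haplotypes,
    preferring higher minimum-edge-weight paths, always including the
    reference itself.  If every k is degenerate the region is skipped
    (reference haplotype only).
    """
    for k in params.k_schedule:
        if len(ref_seg) <= k:
            break
        backbone = [ref_seg[i:i + k] for i in range(len(ref_seg) - k + 1)]
        if len(set(backbone)) != len(backbone):
            continue  # repeat within the region: backbone not a simple path
        backbone_edges = set(zip(backbone[:-1], backbone[1:]))
        edges = _kmer_edges(read_seqs, k)
        graph = nx.DiGraph()
        for (a, b) in backbone_edges:
            graph.add_edge(a, b, weight=edges.get((a, b), 0) + 1)
        for (a, b), w in edges.items():
            if (a, b) in backbone_edges:
                continue
            if w >= params.prune_weight:
                graph.add_edge(a, b, weight=w)
        if not nx.is_directed_acyclic_graph(graph):
            continue
        source, sink = backbone[0], backbone[-1]
        paths = []
        for path in nx.all_simple_paths(graph, source, sink):
            paths.append(path)
            if len(paths) >= params.max_enumerated_paths:
                logger.warning("path enumeration capped in region assembly")
                break
        if not paths:
            continue
        haps = []
        for path in paths:
            seq = path[0] + "".join(node[-1] for node in path[1:])
            weight = min(graph[a][b]["weight"] for a, b in zip(path, path[1:]))
            haps.append(Haplotype(seq, weight))
        haps.sort(key=lambda h: (-h.weight, h.sequence))
        haps = haps[:params.max_haplotypes]
        if not any(h.sequence == ref_seg for h in haps):
            haps.append(Haplotype(ref_seg, 1))
        return haps
    logger.info("assembly degenerate at all k; using reference haplotype only")
    return [Haplotype(ref_seg, 1)]


def haplotype_events(hap: Haplotype, ref_seg: str, contig: str,
                     region_start: int, contig_seq: str,
                     scheme: ScoringScheme = ScoringScheme()) -> list[VariantEvent]:
    """Align a haplotype globally back to the region reference and
    extract left-normalized variant events."""
    if hap.sequence == ref_seg:
        return []
    _, cigar = global_align(hap.sequence, ref_seg, scheme)
    events: list[VariantEvent] = []
    rpos, hpos = region_start, 0
    for op, ln in cigar:
        if op == "M":
            for off in range(ln):
                r = contig_seq[rpos + off]
                a = hap.sequence[hpos + off]
                if r != a:
                    events.append(VariantEvent(contig, rpos + off, r, a))
            rpos += ln
            hpos += ln
        elif op == "I":
            anchor_pos = rpos - 1
            if anchor_pos >= 0 and ln <= MAX_INDEL_LEN:
                anchor = contig_seq[anchor_pos]
                p, r, a = normalize_variant(contig_seq, anchor_pos, anchor,
                                            anchor + hap.sequence[hpos:hpos + ln])
                events.append(VariantEvent(contig, p, r, a))
            hpos += ln
        elif op == "D":
            anchor_pos = rpos - 1
            if anchor_pos >= 0 and ln <= MAX_INDEL_LEN:
                anchor = contig_seq[anchor_pos]
                p, r, a = normalize_variant(contig_seq, anchor_pos,
                                            anchor + contig_seq[rpos:rpos + ln],
                                            anchor)
                events.append(VariantEvent(contig, p, r, a))
            rpos += ln
    return events


# ---------------------------------------------------------------------------
# Genotyping
# ---------------------------------------------------------------------------

@dataclass
class RegionRead:
    """A read prepared for HMM evaluation within one region."""

    codes: np.ndarray
    quals: np.ndarray
    mapq: int
    span: tuple[int, int]   # contig interval the read can inform


def _trim_to_region(rec: AlignmentRecord, region: ActiveRegion) -> RegionRead | None:
    """Clip the read to the region using unclipped coordinate projection
    (soft-clipped bases near an insertion stay available to assembly and
    the HMM; genuine overhang beyond the region is removed)."""
    ustart, uend = rec.unclipped_start(), rec.unclipped_end()
    cut_left = max(0, region.start - ustart)
    cut_right = max(0, uend - region.end)
    L = len(rec.seq)
    if cut_left + cut_right >= L:
        return None
    seq = rec.seq[cut_left:L - cut_right]
    quals = rec.quals[cut_left:L - cut_right]
    span = (max(rec.pos, region.start), min(rec.ref_end, region.end))
    if span[1] <= span[0]:
        return None
    return RegionRead(encode(seq), np.asarray(quals), rec.mapq, span)


def _region_reads(records: list[AlignmentRecord], region: ActiveRegion,
                  params: CallerParams) -> list[RegionRead]:
    out = []
    for rec in records:
        if rec.contig != region.contig:
            continue
        if rec.is_unmapped:
            # unplaced mate anchored in the region: orientation implied
            # by the FR layout (opposite of its mapped mate)
            if not rec.is_duplicate and region.start <= rec.pos < region.end:
                seq = rec.seq
                if not (rec.flag & FLAG_MATE_REVERSE):
                    seq = revcomp(seq)
                    quals = rec.quals[::-1]
                else:
                    quals = rec.quals
                out.append(RegionRead(encode(seq), np.asarray(quals), 60,
                                      (region.start, region.end)))
            continue
        if not _usable(rec, params):
            continue
        if rec.pos < region.end and rec.ref_end > region.start:
            trimmed = _trim_to_region(rec, region)
            if trimmed is not None:
                out.append(trimmed)
    return out


def _phred_cap(p: float, cap: float) -> float:
    if p <= 0:
        return cap
    return min(cap, -10.0 * np.log10(p))


def diplotype_posteriors(per_allele: np.ndarray, theta: float
                         ) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Posterior over diplotypes from per-read, per-allele log
    likelihoods (allele 0 = reference).

    Candidates are all unordered allele pairs; a diplotype's per-read
    likelihood is the even mixture (P(r|e1) + P(r|e2)) / 2, multiplied
    over reads; the prior is 1 - theta for homozygous reference and
    theta split evenly over the non-reference diplotypes.  The returned
    posteriors are normalized (they sum to 1).
    """
    n_alleles = per_allele.shape[1]
    combos = list(itertools.combinations_with_replacement(range(n_alleles), 2))
    n_nonref = len(combos) - 1
    log_post = np.empty(len(combos))
    for ci, (a1, a2) in enumerate(combos):
        mix = np.logaddexp(per_allele[:, a1] + np.log(0.5),
                           per_allele[:, a2] + np.log(0.5))
        prior = (1.0 - theta) if (a1 == 0 and a2 == 0) else theta / n_nonref
        log_post[ci] = mix.sum() + np.log(prior)
    log_post -= log_post.max()
    post = np.exp(log_post)
    post /= post.sum()
    return combos, post


def genotype_region(region: ActiveRegion, haplotypes: list[Haplotype],
                    reads: list[RegionRead], ref: ReferenceGenome,
                    params: CallerParams = CallerParams()) -> list[VariantCall]:
    """Bayesian diplotype genotyping at every event position in the region."""
    positions: dict[int, list[VariantEvent]] = {}
    for hap in haplotypes:
        for ev in hap.events:
            positions.setdefault(ev.position, [])
            if ev not in positions[ev.position]:
                positions[ev.position].append(ev)
    if not positions or not reads:
        return []

    hap_codes = [encode(h.sequence) for h in haplotypes]
    loglik = np.empty((len(reads), len(haplotypes)))
    for i, read in enumerate(reads):
        for j, codes in enumerate(hap_codes):
            loglik[i, j] = pair_hmm(read.codes, read.quals, read.mapq,
                                    codes, params.hmm)

    calls: list[VariantCall] = []
    NEG = -1e9
    for pos in sorted(positions):
        events = sorted(positions[pos])
        alleles: list[VariantEvent | None] = [None] + events  # None = reference
        support = []
        for allele in alleles:
            if allele is None:
                cols = [j for j, h in enumerate(haplotypes)
                        if not any(ev.position == pos for ev in h.events)]
            else:
                cols = [j for j, h in enumerate(haplotypes) if allele in h.events]
            support.append(cols)
        if not support[0]:
            # no purely-reference haplotype at this position; the
            # reference allele is still a formal candidate with zero
            # haplotype support
            pass

        overlap = [i for i, r in enumerate(reads)
                   if r.span[0] <= pos < r.span[1]]
        if not overlap:
            continue
        # per-read, per-allele log likelihood: max over supporting haplotypes
        per_allele = np.full((len(overlap), len(alleles)), NEG)
        for ai, cols in enumerate(support):
            if cols:
                per_allele[:, ai] = loglik[np.ix_(overlap, cols)].max(axis=1)

        combos, post = diplotype_posteriors(per_allele, params.theta)
        winner = int(np.argmax(post))
        a1, a2 = combos[winner]
        if a1 == 0 and a2 == 0:
            continue
        p_win = float(post[winner])
        gq = int(min(99, round(_phred_cap(1.0 - p_win, 99.0))))
        qual = _phred_cap(float(post[0]), 999.0)

        # report alleles present in the winning diplotype
        used = sorted({a for a in (a1, a2) if a != 0})
        alts = [alleles[a].alt for a in used]
        ref_allele = alleles[used[0]].ref
        # harmonize multi-allelic representation on the longer ref allele
        for a in used[1:]:
            ev = alleles[a]
            if len(ev.ref) > len(ref_allele):
                ref_allele = ev.ref
        harm_alts = []
        for a in used:
            ev = alleles[a]
            harm_alts.append(ev.alt + ref_allele[len(ev.ref):])
        index_of = {0: 0}
        for gi, a in enumerate(used, start=1):
            index_of[a] = gi
        genotype = tuple(sorted((index_of[a1], index_of[a2])))

        assign = per_allele.argmax(axis=1)
        allele_depths = [int((assign == 0).sum())]
        for a in used:
            allele_depths.append(int((assign == a).sum()))
        calls.append(VariantCall(
            contig=region.contig, position=pos, ref=ref_allele,
            alts=harm_alts, genotype=genotype, qual=qual, gq=gq,
            depth=len(overlap), allele_depths=allele_depths))
    return calls


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def call_variants(records: list[AlignmentRecord], ref: ReferenceGenome,
                  params: CallerParams = CallerParams()) -> list[VariantCall]:
    """Full calling pass: regions -> assembly -> events -> genotypes.

    ``records`` must be coordinate-sorted with duplicates flagged.
    Calls are independent of read input order within each region.
    """
    regions = detect_regions(records, ref, params)
    logger.info("detected %d active regions", len(regions))
    calls: list[VariantCall] = []
    for region in regions:
        region_recs = [r for r in records if r.contig == region.contig
                       and ((not r.is_unmapped and r.pos < region.end
                             and r.ref_end > region.start)
                            or (r.is_unmapped
                                and region.start <= r.pos < region.end))]
        reads = _region_reads(region_recs, region, params)
        if not reads:
            continue
        # assembly uses full read sequences (soft-clipped bases carry the
        # evidence for insertions); unplaced mates contribute in the
        # orientation implied by the FR pair layout
        seqs = []
        for rec in region_recs:
            if rec.is_unmapped:
                if not rec.is_duplicate:
                    seq = rec.seq
                    if not (rec.flag & FLAG_MATE_REVERSE):
                        seq = revcomp(seq)
                    seqs.append(seq)
            elif _usable(rec, params):
                seqs.append(rec.seq)
        seqs.sort()

        ref_seg = ref.fetch(region.contig, region.start, region.end)
        haplotypes = assemble_haplotypes(seqs, ref_seg, params)
        contig_seq = ref.contigs[region.contig]
        for hap in haplotypes:
            hap.events = haplotype_events(hap, ref_seg, region.contig,
                                          region.start, contig_seq,
                                          params.scheme)
        calls.extend(genotype_region(region, haplotypes, reads, ref, params))

    # deduplicate identical sites that can arise from adjacent regions
    seen: dict[tuple, VariantCall] = {}
    for call in calls:
        key = call.key()
        if key not in seen or call.qual > seen[key].qual:
            seen[key] = call
    return sorted(seen.values(), key=lambda c: (c.contig, c.position))
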