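"""Paired-end read mapping.

Pipeline per read pair: extract overlapping seeds at every even offset,
look them up in the hash index (following EXTEND chains), group hits on
shared alignment diagonals into seed chains, filter chains dominated by
much longer overlapping chains, pair chains across mates by insert-size
geometry (with a k-mer rescue scan of the expected mate window when one
mate fails to seed), align each surviving candidate gaplessly and - when
heuristics suggest an indel or heavy clipping - by Smith-Waterman, then
pick the best-scoring pair, assign MAPQ from the best/second-best score
margin, and emit SAM-style records (plus up to three supplementary
alignments for chimeric reads).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from rapidseq.align import (GaplessResult, LocalAlignment, ScoringScheme,
                            cigar_read_len, cigar_ref_len, encode,
                            gapless_align, smith_waterman)
from rapidseq.index import (FORWARD, REVERSE, HashIndex, HighFrequency,
                            IndexParams, SeedHit, query_seed)
from rapidseq.reference import ReferenceGenome, revcomp

logger = logging.getLogger(__name__)

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80
FLAG_DUPLICATE = 0x400
FLAG_SUPPLEMENTARY = 0x800


@dataclass
class Read:
    """A sequencing read with per-base Phred qualities."""

    id: str
    sequence: str
    base_qualities: np.ndarray  # uint8, same length as sequence

    def __post_init__(self) -> None:
        self.base_qualities = np.asarray(self.base_qualities, dtype=np.uint8)
        if len(self.sequence) != len(self.base_qualities):
            raise ValueError("sequence and quality lengths differ")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class InsertModel:
    """Expected fragment (outer insert) size distribution."""

    mean: float = 350.0
    sd: float = 50.0
    window: float = 4.0  # proper-pair window, in multiples of sd

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")


@dataclass(frozen=True)
class RescueParams:
    kmer_len: int = 24
    max_hamming: int = 3


@dataclass(frozen=True)
class MapperParams:
    """Mapper heuristics; all overridable, defaults stated here."""

    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    trigger_fraction: float = 0.9   # gapless score below this x perfect -> gapped
    clip_trigger: int = 5           # gapless clip longer than this -> gapped
    sw_pad: int = 32                # ref window slack around the chain diagonal
    mapq_coeff: float = 60.0        # alpha(L) = mapq_coeff / L
    mapq_beta: float = 2.0          # weight of the near-second-best count
    near_window: int = 2            # "very close to second best" margin
    cover_fraction: float = 0.8     # below this, try supplementary alignments
    pair_pen_coeff: float = 1.0     # pairing penalty per sd of insert deviation
    pair_pen_cap: int = 40
    max_candidates: int = 20        # per mate, kept for pairing
    chain_filter_ratio: float = 4.0
    chain_overlap_fraction: float = 0.5


# ---------------------------------------------------------------------------
# Seeding and chaining
# ---------------------------------------------------------------------------

def extract_seeds(read: Read, params: IndexParams) -> list[tuple[int, str]]:
    """Seeds of ``primary_seed_len`` at every ``seed_stride``-th offset
    (default: every even offset, 50% density); N-containing seeds are
    omitted."""
    k = params.primary_seed_len
    seq = read.sequence
    out = []
    for off in range(0, len(seq) - k + 1, params.seed_stride):
        seed = seq[off:off + k]
        if "N" not in seed:
            out.append((off, seed))
    return out


@dataclass
class SeedChain:
    """Seed hits sharing one alignment diagonal (one candidate placement).

    ``diagonal`` is reference position minus read offset, with the read
    offset taken in reverse-complement coordinates for reverse-strand
    hits, so the diagonal is also the implied leftmost reference
    position of the read."""

    contig: str
    orientation: str
    diagonal: int
    read_start: int
    read_end: int
    n_hits: int = 1

    @property
    def length(self) -> int:
        return self.read_end - self.read_start


def build_chains(hits: list[tuple[int, SeedHit]], seed_len: int,
                 ratio: float = 4.0, overlap_fraction: float = 0.5) -> list[SeedChain]:
    """Group same-orientation hits by exact diagonal, then drop chains
    mostly overlapped in the read by a chain at least ``ratio`` times
    longer.

    Offsets must already be in the hit orientation's read coordinates.
    """
    by_diag: dict[tuple[str, str, int], SeedChain] = {}
    for off, hit in hits:
        diag = hit.position - off
        key = (hit.contig, hit.orientation, diag)
        chain = by_diag.get(key)
        if chain is None:
            by_diag[key] = SeedChain(hit.contig, hit.orientation, diag,
                                     off, off + seed_len)
        else:
            chain.read_start = min(chain.read_start, off)
            chain.read_end = max(chain.read_end, off + seed_len)
            chain.n_hits += 1

    chains = sorted(by_diag.values(),
                    key=lambda c: (-c.length, c.contig, c.diagonal))
    kept: list[SeedChain] = []
    for c in chains:
        dominated = False
        for big in kept:
            if big.length >= ratio * c.length:
                ov = min(big.read_end, c.read_end) - max(big.read_start, c.read_start)
                if ov > overlap_fraction * c.length:
                    dominated = True
                    break
        if not dominated:
            kept.append(c)
    return kept


def _collect_chains(read: Read, idx: HashIndex,
                    params: MapperParams) -> list[SeedChain]:
    """Seed, query (both strands) and chain one read."""
    k = idx.params.primary_seed_len
    L = len(read)
    fwd_hits: list[tuple[int, SeedHit]] = []
    rev_hits: list[tuple[int, SeedHit]] = []
    for off, _seed in extract_seeds(read, idx.params):
        res = query_seed(idx, read.sequence, off)
        if isinstance(res, HighFrequency):
            continue
        for hit in res:
            if hit.orientation == FORWARD:
                fwd_hits.append((off, hit))
            else:
                rev_hits.append((L - off - k, hit))  # rc-read coordinates
    chains = build_chains(fwd_hits, k, params.chain_filter_ratio,
                          params.chain_overlap_fraction)
    chains += build_chains(rev_hits, k, params.chain_filter_ratio,
                           params.chain_overlap_fraction)
    return chains


# ---------------------------------------------------------------------------
# Candidate alignment
# ---------------------------------------------------------------------------

@dataclass
class Candidate:
    """A scored placement of one (oriented) read."""

    contig: str
    orientation: str
    pos: int                       # leftmost aligned reference base
    cigar: list[tuple[str, int]]
    score: int

    @property
    def ref_end(self) -> int:
        return self.pos + cigar_ref_len(self.cigar)

    def read_interval(self) -> tuple[int, int]:
        """Aligned (non-clipped) read interval, in oriented coordinates."""
        start = self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0
        end = cigar_read_len(self.cigar)
        if self.cigar and self.cigar[-1][0] == "S":
            end -= self.cigar[-1][1]
        return start, end


def _window_codes(ref: ReferenceGenome, contig: str, start: int, end: int) -> np.ndarray:
    """Encoded reference window; positions outside the contig become N."""
    seq = ref.contigs[contig]
    codes = np.full(end - start, 4, dtype=np.uint8)
    lo, hi = max(0, start), min(len(seq), end)
    if hi > lo:
        codes[lo - start:hi - start] = encode(seq[lo:hi])
    return codes


def align_candidate(oriented_codes: np.ndarray, ref: ReferenceGenome,
                    contig: str, orientation: str, diagonal: int,
                    params: MapperParams) -> Candidate | None:
    """Gapless alignment at the chain diagonal, escalated to
    Smith-Waterman when the heuristics fire."""
    L = len(oriented_codes)
    scheme = params.scheme
    window = _window_codes(ref, contig, diagonal, diagonal + L)
    gl: GaplessResult = gapless_align(oriented_codes, window, scheme,
                                      params.trigger_fraction, params.clip_trigger)
    if not gl.needs_gapped:
        cigar = []
        if gl.clip_left:
            cigar.append(("S", gl.clip_left))
        cigar.append(("M", L - gl.clip_left - gl.clip_right))
        if gl.clip_right:
            cigar.append(("S", gl.clip_right))
        return Candidate(contig, orientation, diagonal + gl.clip_left,
                         cigar, gl.score)

    pad = params.sw_pad
    win_start = diagonal - pad
    window = _window_codes(ref, contig, win_start, diagonal + L + pad)
    sw: LocalAlignment = smith_waterman(oriented_codes, window, scheme)
    if sw.score <= 0:
        return None
    bonus = scheme.unclipped_bonus
    score = sw.score
    if not (sw.cigar and sw.cigar[0][0] == "S"):
        score += bonus
    if not (sw.cigar and sw.cigar[-1][0] == "S"):
        score += bonus
    pos = win_start + sw.ref_start
    if pos < 0:
        return None
    cand = Candidate(contig, orientation, pos, sw.cigar, score)
    # keep gapless if SW did not actually improve
    if gl.score >= score:
        cigar = []
        if gl.clip_left:
            cigar.append(("S", gl.clip_left))
        cigar.append(("M", L - gl.clip_left - gl.clip_right))
        if gl.clip_right:
            cigar.append(("S", gl.clip_right))
        return Candidate(contig, orientation, diagonal + gl.clip_left,
                         cigar, gl.score)
    return cand


def _dedupe(cands: list[Candidate], read_len: int) -> list[Candidate]:
    """Collapse candidates that are really the same placement.

    Chains split by an indel sit on nearby diagonals and converge to
    overlapping reference intervals after gapped alignment; keeping both
    would make the second-best score artificially close to the best and
    wreck MAPQ.  Candidates on one contig/orientation whose reference
    intervals overlap are merged, keeping the best score.
    """
    out: list[Candidate] = []
    for c in sorted(cands, key=lambda c: (-c.score, c.contig, c.pos)):
        dup = False
        for kept in out:
            if (kept.contig == c.contig and kept.orientation == c.orientation
                    and c.pos < kept.ref_end and kept.pos < c.ref_end):
                dup = True
                break
        if not dup:
            out.append(c)
    return out


def _candidates_for_read(read: Read, oriented_codes: dict[str, np.ndarray],
                         idx: HashIndex, ref: ReferenceGenome,
                         params: MapperParams) -> list[Candidate]:
    chains = _collect_chains(read, idx, params)
    cands = []
    for chain in chains:
        cand = align_candidate(oriented_codes[chain.orientation], ref,
                               chain.contig, chain.orientation,
                               chain.diagonal, params)
        if cand is not None:
            cands.append(cand)
    cands = _dedupe(cands, len(read))
    return cands[:params.max_candidates]


# ---------------------------------------------------------------------------
# Pairing and rescue
# ---------------------------------------------------------------------------

def _implied_insert(c1: Candidate, c2: Candidate) -> int | None:
    """Outer fragment span for a forward/reverse candidate pair on one
    contig; None when the geometry is not FR."""
    if c1.contig != c2.contig or c1.orientation == c2.orientation:
        return None
    fwd, rev = (c1, c2) if c1.orientation == FORWARD else (c2, c1)
    insert = rev.ref_end - fwd.pos
    if insert <= 0 or rev.pos < fwd.pos - 5:
        return None
    return insert


def pairing_penalty(insert: int | None, model: InsertModel,
                    params: MapperParams) -> int:
    if insert is None:
        return params.pair_pen_cap
    dev = abs(insert - model.mean) / model.sd
    return min(params.pair_pen_cap, round(params.pair_pen_coeff * dev))


def hamming_scan(window_codes: np.ndarray, kmer_codes: np.ndarray,
                 max_hamming: int) -> list[int]:
    """All window offsets where the k-mer matches within ``max_hamming``
    mismatches (N counts as a mismatch)."""
    k = len(kmer_codes)
    n = len(window_codes) - k + 1
    if n <= 0:
        return []
    strided = np.lib.stride_tricks.sliding_window_view(window_codes, k)
    mism = (strided != kmer_codes) | (strided >= 4)
    counts = mism.sum(axis=1)
    return list(np.nonzero(counts <= max_hamming)[0])


def rescue_scan(anchor: Candidate, mate_codes: dict[str, np.ndarray],
                ref: ReferenceGenome, model: InsertModel,
                rescue: RescueParams, params: MapperParams) -> list[Candidate]:
    """Scan the expected mate window for approximate k-mer matches of
    the mate and align at each match."""
    w = model.window * model.sd
    L = len(mate_codes[FORWARD])
    if anchor.orientation == FORWARD:
        mate_orient = REVERSE
        lo = int(anchor.pos + model.mean - w) - L
        hi = int(anchor.pos + model.mean + w)
    else:
        mate_orient = FORWARD
        frag_end = anchor.ref_end
        lo = int(frag_end - model.mean - w)
        hi = int(frag_end - model.mean + w) + L
    codes = mate_codes[mate_orient]
    kmer = codes[:rescue.kmer_len]
    window = _window_codes(ref, anchor.contig, lo, hi)
    out = []
    for off in hamming_scan(window, kmer, rescue.max_hamming):
        cand = align_candidate(codes, ref, anchor.contig, mate_orient,
                               lo + off, params)
        if cand is not None:
            out.append(cand)
    return _dedupe(out, L)


# ---------------------------------------------------------------------------
# Records and finalization
# ---------------------------------------------------------------------------

@dataclass
class AlignmentRecord:
    """SAM-style alignment record (0-based position internally)."""

    qname: str
    flag: int
    contig: str | None
    pos: int
    mapq: int
    cigar: list[tuple[str, int]]
    seq: str                      # reference-oriented, as in SAM
    quals: np.ndarray
    rnext: str | None = None
    pnext: int = 0
    tlen: int = 0
    score: int = 0
    pair_score: int = 0

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flag & FLAG_DUPLICATE)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & FLAG_SUPPLEMENTARY)

    @property
    def ref_end(self) -> int:
        return self.pos + cigar_ref_len(self.cigar)

    def unclipped_start(self) -> int:
        clip = self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0
        return self.pos - clip

    def unclipped_end(self) -> int:
        clip = self.cigar[-1][1] if self.cigar and self.cigar[-1][0] == "S" else 0
        return self.ref_end + clip


def compute_mapq(scores: list[int], chosen: int, read_len: int,
                 params: MapperParams) -> int:
    """MAPQ from the margin between best and second-best scores.

    mapq = clamp(round(alpha(L) * (S1 - S2)) - beta * log2(1 + N2), 0, 60)
    with alpha(L) = mapq_coeff / L and N2 the number of additional
    candidates scoring within ``near_window`` of the second best.  A
    read with a single candidate placement gets the cap.
    """
    others = sorted(scores, reverse=True)
    others.remove(chosen)
    if not others:
        return 60
    s2 = max(others)
    n2 = sum(1 for s in others if s >= s2 - params.near_window) - 1
    alpha = params.mapq_coeff / read_len
    raw = round(alpha * (chosen - s2)) - params.mapq_beta * math.log2(1 + n2)
    return int(max(0, min(60, raw)))


def _oriented_seq_quals(read: Read, orientation: str) -> tuple[str, np.ndarray]:
    if orientation == FORWARD:
        return read.sequence, read.base_qualities
    return revcomp(read.sequence), read.base_qualities[::-1]


def _record_from_candidate(read: Read, cand: Candidate, mapq: int,
                           base_flag: int) -> AlignmentRecord:
    seq, quals = _oriented_seq_quals(read, cand.orientation)
    flag = base_flag | (FLAG_REVERSE if cand.orientation == REVERSE else 0)
    return AlignmentRecord(read.id, flag, cand.contig, cand.pos, mapq,
                           cand.cigar, seq, quals, score=cand.score)


def _unmapped_record(read: Read, base_flag: int) -> AlignmentRecord:
    return AlignmentRecord(read.id, base_flag | FLAG_UNMAPPED, None, 0, 0,
                           [], read.sequence, read.base_qualities)


def _supplementaries(read: Read, primary: Candidate, cands: list[Candidate],
                     params: MapperParams) -> list[Candidate]:
    """Other-segment alignments for a chimeric read (primary covers less
    than ``cover_fraction`` of it); at most three."""
    L = len(read)
    pstart, pend = primary.read_interval()
    if primary.orientation == REVERSE:
        pstart, pend = L - pend, L - pstart
    if pend - pstart >= params.cover_fraction * L:
        return []
    out = []
    for cand in sorted(cands, key=lambda c: -c.score):
        if cand is primary:
            continue
        s, e = cand.read_interval()
        if cand.orientation == REVERSE:
            s, e = L - e, L - s
        covered = min(e, pend) - max(s, pstart)
        if covered < 0.5 * (e - s):       # mostly covers new read sequence
            out.append(cand)
            pstart, pend = min(pstart, s), max(pend, e)
        if len(out) == 3:
            break
    return out


def finalize_pair(read1: Read, read2: Read, cands1: list[Candidate],
                  cands2: list[Candidate], model: InsertModel,
                  params: MapperParams) -> list[AlignmentRecord]:
    """Choose the best candidate pair, set flags/MAPQ/TLEN, and emit
    primary plus supplementary records for both mates."""
    base1 = FLAG_PAIRED | FLAG_FIRST
    base2 = FLAG_PAIRED | FLAG_SECOND

    best: tuple[int, Candidate | None, Candidate | None, bool] = (-10**9, None, None, False)
    if cands1 and cands2:
        for c1 in cands1:
            for c2 in cands2:
                insert = _implied_insert(c1, c2)
                pen = pairing_penalty(insert, model, params)
                score = c1.score + c2.score - pen
                proper = (insert is not None
                          and abs(insert - model.mean) <= model.window * model.sd)
                if score > best[0]:
                    best = (score, c1, c2, proper)
    elif cands1:
        c1 = max(cands1, key=lambda c: c.score)
        best = (c1.score - params.pair_pen_cap, c1, None, False)
    elif cands2:
        c2 = max(cands2, key=lambda c: c.score)
        best = (c2.score - params.pair_pen_cap, None, c2, False)

    pair_score, c1, c2, proper = best
    records: list[AlignmentRecord] = []

    recs: list[AlignmentRecord | None] = [None, None]
    for i, (read, cand, cands, base) in enumerate(
            [(read1, c1, cands1, base1), (read2, c2, cands2, base2)]):
        if cand is None:
            recs[i] = _unmapped_record(read, base)
        else:
            mapq = compute_mapq([c.score for c in cands], cand.score,
                                len(read), params)
            flag = base | (FLAG_PROPER if proper else 0)
            recs[i] = _record_from_candidate(read, cand, mapq, flag)
            recs[i].pair_score = pair_score

    r1, r2 = recs
    _cross_link(r1, r2)
    _cross_link(r2, r1)
    if c1 is not None and c2 is not None and c1.contig == c2.contig:
        left = min(c1.pos, c2.pos)
        right = max(c1.ref_end, c2.ref_end)
        tlen = right - left
        r1.tlen = tlen if c1.pos <= c2.pos else -tlen
        r2.tlen = -r1.tlen
    records.extend(recs)  # type: ignore[arg-type]

    for read, cand, cands, base, rec in [(read1, c1, cands1, base1, r1),
                                         (read2, c2, cands2, base2, r2)]:
        if cand is None:
            continue
        for sup in _supplementaries(read, cand, cands, params):
            srec = _record_from_candidate(read, sup, rec.mapq,
                                          base | FLAG_SUPPLEMENTARY)
            other = r2 if base == base1 else r1
            _cross_link(srec, other)
            records.append(srec)
    return records


def _cross_link(rec: AlignmentRecord, mate: AlignmentRecord) -> None:
    if mate.is_unmapped:
        rec.flag |= FLAG_MATE_UNMAPPED
        # SAM convention: unmapped mate is placed with its mapped mate
        rec.rnext, rec.pnext = rec.contig, rec.pos
    else:
        rec.rnext, rec.pnext = mate.contig, mate.pos
        if mate.is_reverse:
            rec.flag |= FLAG_MATE_REVERSE
    if rec.is_unmapped and not mate.is_unmapped:
        rec.contig, rec.pos = mate.contig, mate.pos


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def fit_insert_model(pairs: list[tuple[Read, Read]], idx: HashIndex,
                     params: MapperParams | None = None,
                     fallback: InsertModel = InsertModel(),
                     max_pairs: int = 10000) -> InsertModel:
    """Estimate the insert distribution from pairs where both mates have
    a single, opposite-orientation seed chain (no alignment, no rescue);
    falls back to the configured model when too few pairs qualify."""
    if params is None:
        params = MapperParams()
    inserts = []
    for read1, read2 in pairs[:max_pairs]:
        ch1 = _collect_chains(read1, idx, params)
        ch2 = _collect_chains(read2, idx, params)
        if len(ch1) != 1 or len(ch2) != 1:
            continue
        a, b = ch1[0], ch2[0]
        if a.contig != b.contig or a.orientation == b.orientation:
            continue
        fwd, rev = (a, b) if a.orientation == FORWARD else (b, a)
        L = len(read1) if rev is ch1[0] else len(read2)
        insert = (rev.diagonal + L) - fwd.diagonal
        if insert > 0:
            inserts.append(insert)
    if len(inserts) < 50:
        logger.info("insert fit: only %d informative pairs, using fallback model",
                    len(inserts))
        return fallback
    arr = np.asarray(inserts, dtype=float)
    model = InsertModel(float(arr.mean()), float(max(arr.std(), 1.0)),
                        fallback.window)
    logger.info("insert fit: mean=%.1f sd=%.1f from %d pairs",
                model.mean, model.sd, len(arr))
    return model


def map_read_pairs(pairs: list[tuple[Read, Read]], idx: HashIndex,
                   ref: ReferenceGenome,
                   params: MapperParams | None = None,
                   insert_model: InsertModel | None = None,
                   rescue: RescueParams = RescueParams()) -> list[AlignmentRecord]:
    """Map read pairs; returns unsorted SAM-style records."""
    if params is None:
        params = MapperParams()
    if insert_model is None:
        insert_model = fit_insert_model(pairs, idx, params)

    records: list[AlignmentRecord] = []
    n_proper = n_rescued = 0
    for read1, read2 in pairs:
        codes1 = {FORWARD: encode(read1.sequence),
                  REVERSE: encode(revcomp(read1.sequence))}
        codes2 = {FORWARD: encode(read2.sequence),
                  REVERSE: encode(revcomp(read2.sequence))}
        c1 = _candidates_for_read(read1, codes1, idx, ref, params)
        c2 = _candidates_for_read(read2, codes2, idx, ref, params)

        have_proper = any(
            _implied_insert(a, b) is not None
            and abs(_implied_insert(a, b) - insert_model.mean)
            <= insert_model.window * insert_model.sd
            for a in c1 for b in c2)
        if not have_proper:
            rescued = False
            if c1:
                anchor = max(c1, key=lambda c: c.score)
                extra = rescue_scan(anchor, codes2, ref, insert_model,
                                    rescue, params)
                if extra:
                    c2 = _dedupe(c2 + extra, len(read2))[:params.max_candidates]
                    rescued = True
            if c2 and not c1:
                anchor = max(c2, key=lambda c: c.score)
                extra = rescue_scan(anchor, codes1, ref, insert_model,
                                    rescue, params)
                if extra:
                    c1 = _dedupe(extra, len(read1))[:params.max_candidates]
                    rescued = True
            n_rescued += rescued

        recs = finalize_pair(read1, read2, c1, c2, insert_model, params)
        n_proper += bool(recs and recs[0].flag & FLAG_PROPER)
        records.extend(recs)

    logger.info("mapped %d pairs: %.2f%% proper, %d rescued",
                len(pairs), 100.0 * n_proper / max(1, len(pairs)), n_rescued)
    return records
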