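"""Gapless and gapped (affine Smith-Waterman) alignment.

Scoring convention: a gap of length L costs ``gap_open + L * gap_extend``
(the opening charge is paid once, on top of the per-base extension), the
same convention as the common seed-and-extend mappers.  The
``unclipped_bonus`` rewards alignments that reach a read end without
soft clipping; it is applied per unclipped end, outside the DP kernels,
so that gapless and gapped candidate scores stay comparable.

The Smith-Waterman here is a plain full-matrix dynamic program; the
hardware wavefront arrangement used by production aligners changes only
throughput, not the recurrence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """2-bit-style encoding; N and anything unknown -> 4 (never matches)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring constants (positive penalties)."""

    match: int = 2
    mismatch: int = 3
    gap_open: int = 5
    gap_extend: int = 1
    unclipped_bonus: int = 5

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if min(self.mismatch, self.gap_open, self.gap_extend,
               self.unclipped_bonus) < 0:
            raise ValueError("penalties must be non-negative")


# ---------------------------------------------------------------------------
# CIGAR helpers
# ---------------------------------------------------------------------------

def cigar_to_str(cigar: list[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar) if cigar else "*"

def cigar_read_len(cigar: list[tuple[str, int]]) -> int:
    return sum(n for op, n in cigar if op in "MIS")

def cigar_ref_len(cigar: list[tuple[str, int]]) -> int:
    return sum(n for op, n in cigar if op in "MD")

def parse_cigar(text: str) -> list[tuple[str, int]]:
    if text == "*":
        return []
    out, num = [], ""
    for ch in text:
        if ch.isdigit():
            num += ch
        else:
            out.append((ch, int(num)))
            num = ""
    return out

def _compact(cigar: list[tuple[str, int]]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op, n in cigar:
        if n == 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


# ---------------------------------------------------------------------------
# Gapless (fixed-diagonal) alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaplessResult:
    score: int
    clip_left: int
    clip_right: int
    needs_gapped: bool


def gapless_align(read_codes: np.ndarray, ref_codes: np.ndarray,
                  scheme: ScoringScheme = ScoringScheme(),
                  trigger_fraction: float = 0.9,
                  clip_trigger: int = 5) -> GaplessResult:
    """Score a read against the same-length reference slice at a fixed
    diagonal, choosing the best prefix/suffix soft clips.

    Per-base scores are +match / -mismatch; clipping is free but
    forfeits the per-end ``unclipped_bonus``.  The optimal clip pair is
    found in one pass over prefix sums.  ``needs_gapped`` flags
    alignments a gapped pass could plausibly improve: score below
    ``trigger_fraction`` of the perfect score, or a clip longer than
    ``clip_trigger``.
    """
    L = len(read_codes)
    if len(ref_codes) != L:
        raise ValueError("gapless alignment requires a window equal to read length")
    per_base = np.where(read_codes == ref_codes, scheme.match, -scheme.mismatch)
    per_base[read_codes >= 4] = -scheme.mismatch  # N never matches
    prefix = np.concatenate(([0], np.cumsum(per_base)))  # prefix[i] = score of first i bases

    bonus = scheme.unclipped_bonus
    # score(i, j) = prefix[j] - prefix[i] + bonus*(i == 0) + bonus*(j == L)
    best = -10**9
    best_i = best_j = 0
    run_min = 10**9
    run_min_i = 0
    for j in range(1, L + 1):
        cand = prefix[j - 1] - (bonus if j - 1 == 0 else 0)
        if cand < run_min:
            run_min, run_min_i = cand, j - 1
        score = prefix[j] - run_min + (bonus if j == L else 0)
        if score > best:
            best, best_i, best_j = score, run_min_i, j
    perfect = scheme.match * L + 2 * bonus
    clip_l, clip_r = best_i, L - best_j
    needs = best < trigger_fraction * perfect or max(clip_l, clip_r) > clip_trigger
    return GaplessResult(int(best), clip_l, clip_r, bool(needs))


# ---------------------------------------------------------------------------
# Affine-gap dynamic programs (numba kernels)
# ---------------------------------------------------------------------------

_NEG = -(10**7)


@njit(cache=True)
def _sw_fill(q, r, match, mismatch, gap_open, gap_extend):
    m, n = q.shape[0], r.shape[0]
    H = np.zeros((m + 1, n + 1), np.int32)
    E = np.full((m + 1, n + 1), _NEG, np.int32)   # gap in read (deletion)
    F = np.full((m + 1, n + 1), _NEG, np.int32)   # gap in ref (insertion)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e = E[i, j - 1] - gap_extend
            h_open = H[i, j - 1] - gap_open - gap_extend
            if h_open > e:
                e = h_open
            E[i, j] = e
            f = F[i - 1, j] - gap_extend
            v_open = H[i - 1, j] - gap_open - gap_extend
            if v_open > f:
                f = v_open
            F[i, j] = f
            s = match if (qi == r[j - 1] and qi < 4) else -mismatch
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            # keep earliest reference column, then earliest read row, on ties
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


@njit(cache=True)
def _nw_fill(q, r, match, mismatch, gap_open, gap_extend):
    """Global (both-ends-anchored) affine DP."""
    m, n = q.shape[0], r.shape[0]
    H = np.full((m + 1, n + 1), _NEG, np.int32)
    E = np.full((m + 1, n + 1), _NEG, np.int32)
    F = np.full((m + 1, n + 1), _NEG, np.int32)
    H[0, 0] = 0
    for j in range(1, n + 1):
        E[0, j] = -gap_open - gap_extend * j
        H[0, j] = E[0, j]
    for i in range(1, m + 1):
        F[i, 0] = -gap_open - gap_extend * i
        H[i, 0] = F[i, 0]
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e = E[i, j - 1] - gap_extend
            h_open = H[i, j - 1] - gap_open - gap_extend
            if h_open > e:
                e = h_open
            E[i, j] = e
            f = F[i - 1, j] - gap_extend
            v_open = H[i - 1, j] - gap_open - gap_extend
            if v_open > f:
                f = v_open
            F[i, j] = f
            s = match if (qi == r[j - 1] and qi < 4) else -mismatch
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, j] = h
    return H, E, F


def _traceback(H, E, F, q, r, i, j, scheme: ScoringScheme,
               local: bool) -> tuple[list[tuple[str, int]], int, int]:
    """Walk back from (i, j), preferring diagonal moves on ties.

    Returns (reversed-op list, start_i, start_j).
    """
    ops: list[tuple[str, int]] = []
    match, mismatch = scheme.match, scheme.mismatch
    go, ge = scheme.gap_open, scheme.gap_extend
    while i > 0 or j > 0:
        h = H[i, j]
        if local and h == 0:
            break
        if i > 0 and j > 0:
            qi, rj = q[i - 1], r[j - 1]
            s = match if (qi == rj and qi < 4) else -mismatch
            if h == H[i - 1, j - 1] + s:
                ops.append(("M", 1))
                i -= 1
                j -= 1
                continue
        if j > 0 and h == E[i, j]:
            # deletion run: walk E back to its opening
            while j > 0 and E[i, j] != H[i, j - 1] - go - ge:
                ops.append(("D", 1))
                j -= 1
            ops.append(("D", 1))
            j -= 1
            continue
        if i > 0 and h == F[i, j]:
            while i > 0 and F[i, j] != H[i - 1, j] - go - ge:
                ops.append(("I", 1))
                i -= 1
            ops.append(("I", 1))
            i -= 1
            continue
        if not local:
            # boundary rows/cols of the global matrix
            if i == 0:
                ops.append(("D", 1))
                j -= 1
                continue
            if j == 0:
                ops.append(("I", 1))
                i -= 1
                continue
        raise RuntimeError("traceback failed")  # pragma: no cover
    return ops, i, j


@dataclass(frozen=True)
class LocalAlignment:
    score: int
    ref_start: int                 # 0-based within the reference window
    cigar: list[tuple[str, int]]   # includes soft clips covering the read


def smith_waterman(read_seq: str | np.ndarray, ref_window: str | np.ndarray,
                   scheme: ScoringScheme = ScoringScheme()) -> LocalAlignment:
    """Local affine-gap alignment with full-matrix DP and traceback.

    Unaligned read ends become soft clips.  A pair with no positive-
    scoring local alignment returns score 0 and a fully clipped CIGAR.
    """
    q = encode(read_seq) if isinstance(read_seq, str) else read_seq
    r = encode(ref_window) if isinstance(ref_window, str) else ref_window
    if len(q) == 0 or len(r) == 0:
        raise ValueError("empty sequence")
    H, E, F, best, bi, bj = _sw_fill(q, r, scheme.match, scheme.mismatch,
                                     scheme.gap_open, scheme.gap_extend)
    if best <= 0:
        return LocalAlignment(0, 0, [("S", len(q))])
    ops, si, sj = _traceback(H, E, F, q, r, bi, bj, scheme, local=True)
    cigar = []
    if si > 0:
        cigar.append(("S", si))
    cigar.extend(reversed(ops))
    if bi < len(q):
        cigar.append(("S", len(q) - bi))
    return LocalAlignment(int(best), int(sj), _compact(cigar))


def global_align(query: str | np.ndarray, ref: str | np.ndarray,
                 scheme: ScoringScheme = ScoringScheme()) -> tuple[int, list[tuple[str, int]]]:
    """Both-ends-anchored affine alignment (used to read variant events
    off assembled haplotypes)."""
    q = encode(query) if isinstance(query, str) else query
    r = encode(ref) if isinstance(ref, str) else ref
    if len(q) == 0 or len(r) == 0:
        raise ValueError("empty sequence")
    H, E, F = _nw_fill(q, r, scheme.match, scheme.mismatch,
                       scheme.gap_open, scheme.gap_extend)
    ops, _, _ = _traceback(H, E, F, q, r, len(q), len(r), scheme, local=False)
    return int(H[len(q), len(r)]), _compact(list(reversed(ops)))
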