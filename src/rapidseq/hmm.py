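"""Pair hidden Markov model for read-given-haplotype likelihoods.

P(r|H) is the probability of observing read ``r`` assuming haplotype
``H`` is the true sample sequence, so only sequencing and sample-prep
errors contribute.  It is computed with the forward algorithm over a
three-state (match / insert / delete) affine-gap HMM - the same dynamic
program shape as Smith-Waterman, but summing rather than maximizing
path probabilities:

* match emissions come from the base quality, capped by the read's
  MAPQ: ``p_err = 10**(-min(Q, MAPQ)/10)``, emitting ``1 - p_err`` on a
  match and ``p_err / 3`` on a mismatch;
* gap-open probabilities come from a PCR stutter model keyed to the
  homopolymer run length at each haplotype position,
  ``10**-(4 - 0.5 * min(run, 6))``, and gap extension is a constant;
* read start is uniform over haplotype positions and the read end is
  free (sum over all end columns), so partial overlap of read and
  haplotype is handled naturally.

The forward pass runs in linear space with per-row rescaling and
returns log P(r|H).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit


@dataclass(frozen=True)
class HmmParams:
    """Pair-HMM error model parameters."""

    gap_extend: float = 0.1
    gap_open_base_exponent: float = 4.0   # run length 1 -> 10**-(4 - 0.5)
    gap_open_run_coeff: float = 0.5
    gap_open_max_run: int = 6
    mapq_cap: bool = True

    def gap_open(self, run_length: int) -> float:
        run = min(run_length, self.gap_open_max_run)
        return 10.0 ** -(self.gap_open_base_exponent
                         - self.gap_open_run_coeff * run)


def homopolymer_runs(seq_codes: np.ndarray) -> np.ndarray:
    """Length of the homopolymer run containing each position."""
    n = len(seq_codes)
    runs = np.empty(n, dtype=np.int64)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and seq_codes[j + 1] == seq_codes[i]:
            j += 1
        runs[i:j + 1] = j - i + 1
        i = j + 1
    return runs


def gap_open_profile(hap_codes: np.ndarray, params: HmmParams) -> np.ndarray:
    runs = np.minimum(homopolymer_runs(hap_codes), params.gap_open_max_run)
    return 10.0 ** -(params.gap_open_base_exponent
                     - params.gap_open_run_coeff * runs)


def error_probs(quals: np.ndarray, mapq: int, params: HmmParams) -> np.ndarray:
    q = np.asarray(quals, dtype=np.float64)
    if params.mapq_cap:
        q = np.minimum(q, float(mapq))
    return 10.0 ** (-q / 10.0)


@njit(cache=True)
def _forward(read_codes, p_err, hap_codes, delta, eps):
    """Scaled forward pass; returns log P(r|H)."""
    m = read_codes.shape[0]
    n = hap_codes.shape[0]
    M_prev = np.zeros(n + 1)
    I_prev = np.zeros(n + 1)
    D_prev = np.zeros(n + 1)
    M_cur = np.zeros(n + 1)
    I_cur = np.zeros(n + 1)
    D_cur = np.zeros(n + 1)
    log_scale = 0.0
    start = 1.0 / n
    for i in range(1, m + 1):
        pe = p_err[i - 1]
        rb = read_codes[i - 1]
        M_cur[0] = 0.0
        I_cur[0] = 0.0
        D_cur[0] = 0.0
        for j in range(1, n + 1):
            hb = hap_codes[j - 1]
            e_m = (1.0 - pe) if (rb == hb and rb < 4) else (pe / 3.0)
            # transition parameters at the previous column (j-1 in hap)
            d_prev_col = delta[j - 2] if j >= 2 else delta[0]
            t_mm = 1.0 - 2.0 * d_prev_col
            if i == 1:
                path = start
            else:
                path = (t_mm * M_prev[j - 1]
                        + (1.0 - eps) * (I_prev[j - 1] + D_prev[j - 1]))
            M_cur[j] = e_m * path
            # insertion: consume read base, stay at column j
            d_col = delta[j - 1]
            I_cur[j] = d_col * M_prev[j] + eps * I_prev[j]
            # deletion: consume hap base within the same read row
            D_cur[j] = d_prev_col * M_cur[j - 1] + eps * D_cur[j - 1]
        total = 0.0
        for j in range(n + 1):
            total += M_cur[j] + I_cur[j] + D_cur[j]
        if total > 0.0 and (total < 1e-100 or total > 1e100):
            inv = 1.0 / total
            for j in range(n + 1):
                M_cur[j] *= inv
                I_cur[j] *= inv
                D_cur[j] *= inv
            log_scale += np.log(total)
        M_prev, M_cur = M_cur, M_prev
        I_prev, I_cur = I_cur, I_prev
        D_prev, D_cur = D_cur, D_prev
    final = 0.0
    for j in range(1, n + 1):
        final += M_prev[j] + I_prev[j]
    if final <= 0.0:
        return -745.0  # log of smallest positive double, effectively zero
    return np.log(final) + log_scale


def pair_hmm(read_codes: np.ndarray, quals: np.ndarray, mapq: int,
             hap_codes: np.ndarray, params: HmmParams = HmmParams()) -> float:
    """log P(r|H) for one read against one haplotype."""
    if len(read_codes) == 0 or len(hap_codes) == 0:
        raise ValueError("read and haplotype must be non-empty")
    p_err = error_probs(quals, mapq, params)
    delta = gap_open_profile(np.asarray(hap_codes), params)
    return float(_forward(np.asarray(read_codes), p_err,
                          np.asarray(hap_codes), delta, float(params.gap_extend)))
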