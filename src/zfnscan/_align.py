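"""Global (Needleman-Wunsch) alignment with affine gap penalties.

Three-state Gotoh dynamic programming, jitted with numba.  A gap of length L
costs ``gap_open + L * gap_extend`` (the open term is a pure surcharge), so
with the default scores (+2 match, -2 mismatch, -6 open, -1 extend) one
consolidated 2-nt gap always beats two separate 1-nt gaps.  Ties are broken
deterministically, preferring diagonal > deletion (gap in the read) >
insertion (extra read bases), both at the final cell and throughout the
traceback.  `N` (or any non-ACGT byte) always scores as a mismatch.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1.0e30


@njit(cache=True)
def _fill(q, r, match, mismatch, gap_open, gap_extend):
    n, m = q.shape[0], r.shape[0]
    M = np.full((n + 1, m + 1), NEG_INF)
    D = np.full((n + 1, m + 1), NEG_INF)  # ends consuming reference (gap in read)
    I = np.full((n + 1, m + 1), NEG_INF)  # ends consuming read (gap in reference)
    PM = np.zeros((n + 1, m + 1), dtype=np.uint8)
    PD = np.zeros((n + 1, m + 1), dtype=np.uint8)
    PI = np.zeros((n + 1, m + 1), dtype=np.uint8)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        D[0, j] = gap_open + gap_extend * j
        PD[0, j] = 0 if j == 1 else 1
    for i in range(1, n + 1):
        I[i, 0] = gap_open + gap_extend * i
        PI[i, 0] = 0 if i == 1 else 2
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            s = match if (qi == r[j - 1] and qi < 4) else mismatch
            best = M[i - 1, j - 1]
            p = 0
            if D[i - 1, j - 1] > best:
                best = D[i - 1, j - 1]
                p = 1
            if I[i - 1, j - 1] > best:
                best = I[i - 1, j - 1]
                p = 2
            M[i, j] = best + s
            PM[i, j] = p

            best = M[i, j - 1] + gap_open + gap_extend
            p = 0
            if D[i, j - 1] + gap_extend > best:
                best = D[i, j - 1] + gap_extend
                p = 1
            if I[i, j - 1] + gap_open + gap_extend > best:
                best = I[i, j - 1] + gap_open + gap_extend
                p = 2
            D[i, j] = best
            PD[i, j] = p

            best = M[i - 1, j] + gap_open + gap_extend
            p = 0
            if D[i - 1, j] + gap_open + gap_extend > best:
                best = D[i - 1, j] + gap_open + gap_extend
                p = 1
            if I[i - 1, j] + gap_extend > best:
                best = I[i - 1, j] + gap_extend
                p = 2
            I[i, j] = best
            PI[i, j] = p
    return M, D, I, PM, PD, PI


def align_moves(q_codes: np.ndarray, r_codes: np.ndarray, match: float, mismatch: float, gap_open: float, gap_extend: float) -> tuple[float, list[str]]:
    """Return (score, column moves) where moves are 'M' (aligned pair),
    'D' (reference base skipped by the read) or 'I' (read base inserted)."""
    M, D, I, PM, PD, PI = _fill(q_codes, r_codes, match, mismatch, gap_open, gap_extend)
    n, m = q_codes.shape[0], r_codes.shape[0]
    score = M[n, m]
    state = 0
    if D[n, m] > score:
        score, state = D[n, m], 1
    if I[n, m] > score:
        score, state = I[n, m], 2
    moves: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            moves.append("M")
            state = PM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            moves.append("D")
            state = PD[i, j]
            j -= 1
        else:
            moves.append("I")
            state = PI[i, j]
            i -= 1
    moves.reverse()
    return float(score), moves


def align_score(q_codes: np.ndarray, r_codes: np.ndarray, match: float, mismatch: float, gap_open: float, gap_extend: float) -> float:
    """Alignment score only (no traceback)."""
    M, D, I, _, _, _ = _fill(q_codes, r_codes, match, mismatch, gap_open, gap_extend)
    n, m = q_codes.shape[0], r_codes.shape[0]
    return float(max(M[n, m], D[n, m], I[n, m]))


def left_normalize(moves: list[str], read: str, ref: str) -> list[str]:
    """Shift every gap run to its smallest reference coordinate that keeps
    the aligned sequences and score identical (VCF-style left alignment).

    A deletion of ref[j:j+L] can shift left past a preceding aligned column
    when ref[j-1] == ref[j+L-1]; an insertion of read[i:i+L] can shift when
    read[i-1] == read[i+L-1].  Shifts stop at another gap run.
    """
    out = list(moves)
    pos = 0
    i = j = 0  # read / reference consumed before column `pos`
    while pos < len(out):
        op = out[pos]
        if op == "M":
            i += 1
            j += 1
            pos += 1
            continue
        end = pos
        while end < len(out) and out[end] == op:
            end += 1
        L = end - pos
        if op == "D":
            while pos > 0 and out[pos - 1] == "M" and j > 0 and ref[j - 1] == ref[j + L - 1]:
                out[pos - 1], out[end - 1] = "D", "M"
                pos -= 1
                end -= 1
                i -= 1
                j -= 1
            j += L
        else:  # "I"
            while pos > 0 and out[pos - 1] == "M" and i > 0 and read[i - 1] == read[i + L - 1]:
                out[pos - 1], out[end - 1] = "I", "M"
                pos -= 1
                end -= 1
                i -= 1
                j -= 1
            i += L
        pos = end
    return out
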