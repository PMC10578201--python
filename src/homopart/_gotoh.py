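"""Numba kernels for global affine-gap (Gotoh) alignment.

Three-state DP: M (residue aligned to residue), Ix (gap in the second
sequence, i.e. a column consuming a residue of `a`), Iy (gap in the first
sequence). A gap of length L costs gap_open + L * gap_extend; end gaps are
penalized (true global alignment). Traceback tie-breaking prefers the
diagonal, then the vertical (Ix), then the horizontal (Iy) move, giving one
canonical optimal path per (ordered) input pair.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1.0e30
# Score grids are multiples of gap_extend / matrix entries; true ties are
# exact in float64 for the magnitudes involved, so a small epsilon suffices.
_EPS = 1.0e-6


@njit(cache=True)
def gotoh_matrices(a, b, sub, gap_open, gap_extend):
    m, n = len(a), len(b)
    M = np.full((m + 1, n + 1), NEG_INF)
    Ix = np.full((m + 1, n + 1), NEG_INF)
    Iy = np.full((m + 1, n + 1), NEG_INF)
    M[0, 0] = 0.0
    for j in range(1, n + 1):
        Iy[0, j] = -(gap_open + j * gap_extend)
    open_cost = gap_open + gap_extend
    for i in range(1, m + 1):
        Ix[i, 0] = -(gap_open + i * gap_extend)
        ai = a[i - 1]
        for j in range(1, n + 1):
            s = sub[ai, b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(
                max(M[i - 1, j], Iy[i - 1, j]) - open_cost,
                Ix[i - 1, j] - gap_extend,
            )
            Iy[i, j] = max(
                max(M[i, j - 1], Ix[i, j - 1]) - open_cost,
                Iy[i, j - 1] - gap_extend,
            )
    return M, Ix, Iy


@njit(cache=True)
def traceback_counts(a, b, M, Ix, Iy, sub, gap_open, gap_extend):
    """Follow the canonical optimal path; return (n_identical, alignment_length)."""
    m, n = len(a), len(b)
    i, j = m, n
    best = M[m, n]
    state = 0  # 0 = M, 1 = Ix (up), 2 = Iy (left)
    if Ix[m, n] > best + _EPS:
        best = Ix[m, n]
        state = 1
    if Iy[m, n] > best + _EPS:
        state = 2
    open_cost = gap_open + gap_extend
    n_identical = 0
    length = 0
    while i > 0 or j > 0:
        length += 1
        if state == 0:
            if a[i - 1] == b[j - 1]:
                n_identical += 1
            v = M[i, j] - sub[a[i - 1], b[j - 1]]
            i -= 1
            j -= 1
            if abs(M[i, j] - v) < _EPS:
                state = 0
            elif abs(Ix[i, j] - v) < _EPS:
                state = 1
            else:
                state = 2
        elif state == 1:
            v = Ix[i, j]
            i -= 1
            if abs(M[i, j] - (v + open_cost)) < _EPS:
                state = 0
            elif abs(Ix[i, j] - (v + gap_extend)) < _EPS:
                state = 1
            else:
                state = 2
        else:
            v = Iy[i, j]
            j -= 1
            if abs(M[i, j] - (v + open_cost)) < _EPS:
                state = 0
            elif abs(Ix[i, j] - (v + open_cost)) < _EPS:
                state = 1
            else:
                state = 2
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    return n_identical, length


@njit(cache=True)
def align_pair(a, b, sub, gap_open, gap_extend):
    """Score + canonical-path identity counts in one call.

    Returns (score, n_identical, alignment_length).
    """
    M, Ix, Iy = gotoh_matrices(a, b, sub, gap_open, gap_extend)
    score = max(M[-1, -1], Ix[-1, -1], Iy[-1, -1])
    n_identical, length = traceback_counts(a, b, M, Ix, Iy, sub, gap_open, gap_extend)
    return score, n_identical, length
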