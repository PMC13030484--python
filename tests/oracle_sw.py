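"""Exhaustive local-alignment oracle, independent of the package under test.

A plain full-matrix Smith-Waterman with the same scoring the internal
aligner documents (match +1, mismatch -2, gap -2), used to verify the
seed-and-extend aligner's block coordinates.  numba keeps the O(n*m) fill
fast enough for hundreds of desk-scale instances.
"""

from __future__ import annotations

import numba
import numpy as np

MATCH = 1
MISMATCH = -2
GAP = -2


@numba.njit(cache=False)
def _fill(q: np.ndarray, t: np.ndarray, match: int, mismatch: int, gap: int):
    n = q.shape[0]
    m = t.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if q[i - 1] == t[j - 1] else mismatch
            v = H[i - 1, j - 1] + s
            v2 = H[i - 1, j] + gap
            if v2 > v:
                v = v2
            v3 = H[i, j - 1] + gap
            if v3 > v:
                v = v3
            if v < 0:
                v = 0
            H[i, j] = v
            if v > best:
                best = v
                bi = i
                bj = j
    return H, best, bi, bj


def smith_waterman(
    query: str, target: str, match: int = MATCH, mismatch: int = MISMATCH, gap: int = GAP
) -> tuple[int, tuple[int, int], tuple[int, int]]:
    """Best local alignment: (score, query interval, target interval).

    Intervals are 0-based half-open.  The traceback prefers diagonal moves,
    so for instances with a unique optimum the coordinates are exact.
    """
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    H, best, bi, bj = _fill(q, t, match, mismatch, gap)
    i, j = bi, bj
    while H[i, j] > 0:
        s = match if q[i - 1] == t[j - 1] else mismatch
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + s:
            i -= 1
            j -= 1
        elif i > 0 and H[i, j] == H[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
    return int(best), (i, bi), (j, bj)
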