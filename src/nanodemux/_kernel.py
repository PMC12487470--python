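"""Numba-compiled Smith-Waterman scoring kernel for batch read scanning.

Score-and-coordinate only (no traceback): the demultiplexing decision needs
each barcode's best score plus the winner's start/end on the read, so the
full operation string is computed lazily elsewhere.  The kernel reproduces
the reference dynamic program's tie-break exactly — maximum score, then
smallest read start, then smallest read end — which the test suite checks by
direct equivalence against the reference implementation.

Only linear-gap schemes (run_bonus == 0) go through this kernel; the
non-linear run-bonus mode falls back to the reference DP.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["sw_best"]


@njit(cache=True, nogil=True)
def sw_best(q, t, match, mismatch, gap):  # pragma: no cover - exercised via wrapper
    """Best local alignment of query codes ``q`` in target codes ``t``.

    Returns ``(score, read_start, read_end)`` with 1-based inclusive read
    coordinates, or ``(0, 0, 0)`` when no alignment scores above zero.

    ``O`` rows carry, per cell, the smallest 1-based start column of any
    optimal path into the cell; an empty path at column j is encoded with
    the sentinel start ``j + 1`` (a fresh alignment launched from it first
    consumes column j + 1).
    """
    m = q.shape[0]
    n = t.shape[0]
    Hp = np.zeros(n + 1, dtype=np.int64)
    Op = np.empty(n + 1, dtype=np.int64)
    Hc = np.zeros(n + 1, dtype=np.int64)
    Oc = np.empty(n + 1, dtype=np.int64)
    for j in range(n + 1):
        Op[j] = j + 1
    best_v = 0
    best_o = 0
    best_j = 0
    best_i = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        Hc[0] = 0
        Oc[0] = 1
        for j in range(1, n + 1):
            s = match if qi == t[j - 1] else mismatch
            v = Hp[j - 1] + s
            o = Op[j - 1]
            # gap transitions may only extend real paths (an alignment never
            # starts with a gap); empty cells carry the sentinel start col+1
            if Op[j] <= j:
                v2 = Hp[j] + gap
                if v2 > v or (v2 == v and Op[j] < o):
                    v = v2
                    o = Op[j]
            if Oc[j - 1] <= j - 1:
                v2 = Hc[j - 1] + gap
                if v2 > v or (v2 == v and Oc[j - 1] < o):
                    v = v2
                    o = Oc[j - 1]
            if 0 > v or (0 == v and j + 1 < o):
                v = 0
                o = j + 1
            Hc[j] = v
            Oc[j] = o
            if v > 0:
                if v > best_v or (
                    v == best_v
                    and (o < best_o or (o == best_o and j < best_j))
                ):
                    best_v = v
                    best_o = o
                    best_j = j
                    best_i = i
        for j in range(n + 1):
            Hp[j] = Hc[j]
            Op[j] = Oc[j]
    if best_v <= 0:
        return 0, 0, 0
    return best_v, best_o, best_j
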