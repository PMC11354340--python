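"""Affine-gap Smith-Waterman DP kernel.

Gap-cost convention: a gap of length g costs gap_open + g * gap_extend
(so the first gapped column costs gap_open + gap_extend).

The kernel works on integer-encoded sequences (indices into a matrix
alphabet) and returns the optimal local alignment score, its end cell and
the traceback operations.  Tie-breaking is deterministic: the first best
cell in row-major scan order wins, and traceback prefers diagonal moves
over gaps (minimizing gap count among co-optimal paths through that cell).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


# Traceback op codes (emitted in alignment order):
OP_MATCH = 0  # consume one query + one subject column
OP_GAP_Q = 1  # gap in query ('-' in qseq), consume one subject residue
OP_GAP_S = 2  # gap in subject ('-' in sseq), consume one query residue

NEG_INF = np.int32(-(2**30))


@njit(cache=False)
def _sw_core(q, s, mat, gap_open, gap_extend):  # pragma: no cover - jitted
    m = q.shape[0]
    n = s.shape[0]
    open_cost = gap_open + gap_extend
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG_INF, dtype=np.int32)
    F = np.full((m + 1, n + 1), NEG_INF, dtype=np.int32)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = max(H[i, j - 1] - open_cost, E[i, j - 1] - gap_extend)
            f = max(H[i - 1, j] - open_cost, F[i - 1, j] - gap_extend)
            d = H[i - 1, j - 1] + mat[q[i - 1], s[j - 1]]
            h = max(0, d, e, f)
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    if best == 0:
        return 0, 0, 0, 0, 0, np.empty(0, dtype=np.int8)
    # Traceback from (bi, bj), preferring diagonal, then subject-gap, then
    # query-gap re-open; extension continues within E/F states.
    ops = np.empty(m + n, dtype=np.int8)
    k = m + n
    i = bi
    j = bj
    state = 0  # 0=H, 1=E, 2=F
    while i > 0 and j > 0:
        if state == 0:
            h = H[i, j]
            if h == 0:
                break
            if h == H[i - 1, j - 1] + mat[q[i - 1], s[j - 1]]:
                k -= 1
                ops[k] = OP_MATCH
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = 2
            else:
                state = 1
        elif state == 1:  # gap in query, consuming subject
            k -= 1
            ops[k] = OP_GAP_Q
            if H[i, j - 1] - open_cost >= E[i, j - 1] - gap_extend:
                state = 0
            j -= 1
        else:  # gap in subject, consuming query
            k -= 1
            ops[k] = OP_GAP_S
            if H[i - 1, j] - open_cost >= F[i - 1, j] - gap_extend:
                state = 0
            i -= 1
    return int(best), i + 1, bi, j + 1, bj, ops[k:]


def sw_align_encoded(
    q: np.ndarray,
    s: np.ndarray,
    mat: np.ndarray,
    gap_open: int,
    gap_extend: int,
) -> tuple[int, int, int, int, int, np.ndarray]:
    """Best local affine-gap alignment of encoded query vs subject.

    Returns (score, qstart, qend, sstart, send, ops); coordinates are
    1-based inclusive in the respective sequences, all zero when no
    positive-scoring alignment exists.
    """
    return _sw_core(
        np.ascontiguousarray(q, dtype=np.int16),
        np.ascontiguousarray(s, dtype=np.int16),
        np.ascontiguousarray(mat, dtype=np.int16),
        np.int32(gap_open),
        np.int32(gap_extend),
    )
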