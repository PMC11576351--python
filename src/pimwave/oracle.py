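"""Brute-force Needleman–Wunsch dynamic programming.

Computes the full (n+1) x (m+1) DP matrix of optimal prefix-alignment
costs under match-cost-zero edit penalties and recovers one optimal
transcript by traceback. It is the independent correctness oracle against
which every wavefront-based aligner in this package is tested; it makes no
attempt at being fast or memory-frugal beyond row vectorisation.

Recurrence: ``M[i,j] = min(M[i-1,j-1] + (0 if Q[i-1]==R[j-1] else X),
M[i-1,j] + I, M[i,j-1] + D)`` with ``M[i,0] = i*I`` and ``M[0,j] = j*D``.
"""

from __future__ import annotations

import numpy as np

from .core import UNIT, Alignment, Penalties, SequencePair, SizeError

__all__ = ["nw_matrix", "nw_align", "MAX_CELLS"]

#: Guard on n*m so the dense matrix stays within desk memory.
MAX_CELLS = 10**8


def nw_matrix(pair: SequencePair, penalties: Penalties = UNIT) -> np.ndarray:
    """Full DP matrix of shape (n+1, m+1), dtype int64.

    The serial in-row dependency introduced by deletions (horizontal moves)
    is resolved with a prefix-minimum: ``M[i,j] = min_{j' <= j} t[j'] +
    (j - j') * D`` where ``t`` collects the diagonal and vertical candidates.
    """
    n, m = pair.n, pair.m
    if n * m > MAX_CELLS:
        raise SizeError(f"DP matrix of {n}x{m} cells exceeds guard {MAX_CELLS}")
    X, I, D = penalties.mismatch, penalties.insertion, penalties.deletion
    qa = pair.query_array().astype(np.int16)
    ra = pair.reference_array().astype(np.int16)
    cells = np.empty((n + 1, m + 1), dtype=np.int64)
    jd = np.arange(m + 1, dtype=np.int64) * D
    cells[0] = jd
    for i in range(1, n + 1):
        sub = np.where(ra == qa[i - 1], 0, X)
        t = np.empty(m + 1, dtype=np.int64)
        t[0] = i * I
        np.minimum(cells[i - 1, :-1] + sub, cells[i - 1, 1:] + I, out=t[1:])
        cells[i] = np.minimum.accumulate(t - jd) + jd
    return cells


def nw_align(pair: SequencePair, penalties: Penalties = UNIT,
             max_cells: int = MAX_CELLS) -> Alignment:
    """Optimal global alignment by dense DP with traceback.

    Tie-breaking prefers the diagonal move (M/X), then deletion, then
    insertion, so the returned transcript is deterministic; any optimal
    transcript is equally valid, and score is what other aligners are
    compared on.
    """
    n, m = pair.n, pair.m
    if n * m > max_cells:
        raise SizeError(f"DP matrix of {n}x{m} cells exceeds guard {max_cells}")
    X, I, D = penalties.mismatch, penalties.insertion, penalties.deletion
    cells = nw_matrix(pair, penalties)
    q, r = pair.query, pair.reference
    ops: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        here = cells[i, j]
        if i > 0 and j > 0:
            match = q[i - 1] == r[j - 1]
            if here == cells[i - 1, j - 1] + (0 if match else X):
                ops.append("M" if match else "X")
                i -= 1
                j -= 1
                continue
        if j > 0 and here == cells[i, j - 1] + D:
            ops.append("D")
            j -= 1
            continue
        ops.append("I")
        i -= 1
    ops.reverse()
    cigar = []
    for op in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1][1] += 1
        else:
            cigar.append([op, 1])
    return Alignment(score=int(cells[n, m]),
                     cigar=tuple((op, ln) for op, ln in cigar))
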