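"""Wavefront alignment (WFA) primitives.

The WFA computes DP cells in increasing order of alignment score, keeping
only the furthest-reaching cell per diagonal per score. Two operations
alternate:

* **compute** — derive the furthest-reaching offsets of the next score from
  the wavefronts one penalty back: on diagonal ``k``, the best of a
  mismatch (same diagonal, offset+1), a deletion (from ``k-1``, offset+1)
  and an insertion (from ``k+1``, offset unchanged);
* **extend** — advance every offset by the longest common prefix of the
  remaining query/reference suffixes (matches are free).

Both operations are offered separately and as a fused single pass. Fusion
changes nothing semantically; it halves the modeled bulk-memory traffic
(2 reads + 1 write instead of 3 reads + 2 writes per element) because the
intermediate computed-but-unextended wavefront is never written back.

``wfa_align`` retains every wavefront (O(s^2) elements for optimal score
s) and recovers the transcript by traceback — the base-case mode of the
unrolled pipeline. The streaming mode that keeps O(1) live wavefronts
lives in :mod:`pimwave.biwfa`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np

from .core import (SENTINEL, UNIT, Alignment, Cigar, Penalties, SequencePair,
                   Wavefront)
from .memory import AccessLedger, TransferPolicy, adaptive_transfer_size

__all__ = [
    "WavefrontSet",
    "initial_wavefront",
    "extend_wavefront",
    "compute_wavefront",
    "fused_compute_extend",
    "wfa_align",
    "KernelStats",
]


@dataclass
class WavefrontSet:
    """Wavefronts indexed by score, as retained for traceback."""

    wavefronts: Dict[int, Wavefront] = field(default_factory=dict)
    direction: str = "forward"

    def __getitem__(self, score: int) -> Wavefront:
        return self.wavefronts[score]

    def get(self, score: int) -> Optional[Wavefront]:
        return self.wavefronts.get(score)

    @property
    def max_score(self) -> int:
        return max(self.wavefronts)

    def element_count(self) -> int:
        return sum(wf.width for wf in self.wavefronts.values())


def _oriented_arrays(pair: SequencePair, direction: str):
    """Byte arrays in kernel orientation; backward = reversed sequences."""
    qa, ra = pair.query_array(), pair.reference_array()
    if direction == "backward":
        return qa[::-1], ra[::-1]
    if direction != "forward":
        raise ValueError(f"bad direction {direction!r}")
    return qa, ra


def initial_wavefront(pair: SequencePair) -> Wavefront:
    """The score-0 wavefront: diagonal 0, offset 0, not yet extended."""
    offsets = np.zeros(1, dtype=np.int32)
    return Wavefront(0, 0, 0, offsets, offsets.copy())


def _extend_inplace(offsets: np.ndarray, lo: int,
                    qa: np.ndarray, ra: np.ndarray) -> None:
    """LCP-extend every reachable offset along its diagonal, in place.

    Vectorised over diagonals: each pass advances all still-matching
    diagonals by one; the active set shrinks geometrically with the match
    run lengths, so the pass count is the maximum LCP, not the sum.
    """
    n, m = len(qa), len(ra)
    ks = np.arange(lo, lo + len(offsets), dtype=np.int64)
    idx = np.nonzero(offsets >= 0)[0]
    while idx.size:
        off = offsets[idx].astype(np.int64)
        q = off - ks[idx]
        inb = (off < m) & (q < n)
        idx = idx[inb]
        if not idx.size:
            break
        off = off[inb]
        q = q[inb]
        hit = qa[q] == ra[off]
        idx = idx[hit]
        offsets[idx] += 1


def extend_wavefront(wf: Wavefront, pair: SequencePair,
                     direction: str = "forward") -> Wavefront:
    """LCP-extension of a wavefront (functional; input left untouched).

    Backward direction extends along the reversed sequences, i.e. by the
    longest common *suffix* of the remaining prefixes.
    """
    qa, ra = _oriented_arrays(pair, direction)
    out = wf.copy()
    _extend_inplace(out.offsets, out.lo, qa, ra)
    return out


def _gather(wf: Optional[Wavefront], ks: np.ndarray) -> np.ndarray:
    """Offsets of ``wf`` on diagonals ``ks`` (SENTINEL outside/unreachable)."""
    out = np.full(len(ks), SENTINEL, dtype=np.int64)
    if wf is None:
        return out
    idx = ks - wf.lo
    mask = (idx >= 0) & (idx < wf.width)
    out[mask] = wf.offsets[idx[mask]]
    return out


def _compute_next(wfs: Mapping[int, Wavefront], score: int, n: int, m: int,
                  penalties: Penalties) -> Optional[Wavefront]:
    """Furthest-reaching offsets at ``score`` from the retained wavefronts.

    Sources: mismatch from ``score - X`` (same diagonal, offset+1),
    deletion from ``score - D`` (diagonal k-1, offset+1), insertion from
    ``score - I`` (diagonal k+1, offset unchanged). Candidates that would
    leave the DP matrix are discarded per candidate, before the max.
    Returns None when no diagonal is reachable at this score.
    """
    wx = wfs.get(score - penalties.mismatch)
    wd = wfs.get(score - penalties.deletion)
    wi = wfs.get(score - penalties.insertion)
    if wx is None and wd is None and wi is None:
        return None
    los = [w.lo + d for w, d in ((wx, 0), (wd, 1), (wi, -1)) if w is not None]
    his = [w.hi + d for w, d in ((wx, 0), (wd, 1), (wi, -1)) if w is not None]
    lo = max(min(los), -n)
    hi = min(max(his), m)
    if lo > hi:
        return None
    ks = np.arange(lo, hi + 1, dtype=np.int64)

    cand_x = _gather(wx, ks) + 1
    ok = (cand_x > 0) & (cand_x <= m) & (cand_x - ks <= n)
    cand_x[~ok] = SENTINEL

    cand_d = _gather(wd, ks - 1) + 1
    ok = (cand_d > 0) & (cand_d <= m)
    cand_d[~ok] = SENTINEL

    cand_i = _gather(wi, ks + 1)
    ok = (cand_i >= 0) & (cand_i - ks <= n)
    cand_i[~ok] = SENTINEL

    best = np.maximum(np.maximum(cand_x, cand_d), cand_i)
    valid = np.nonzero(best >= 0)[0]
    if not valid.size:
        return None
    first, last = int(valid[0]), int(valid[-1])
    offsets = best[first:last + 1].astype(np.int32)
    return Wavefront(score, lo + first, lo + last, offsets, offsets.copy())


def compute_wavefront(prev: Wavefront, penalties: Penalties = UNIT,
                      pair: SequencePair | None = None) -> Wavefront:
    """One compute step under unit penalties: the score+1 wavefront.

    With unit penalties all three sources are the previous wavefront; this
    is the single-step primitive the fused operation builds on. Without a
    ``pair`` the step is bound-agnostic (the diagonal range grows by one on
    each side); with one, candidates leaving the DP matrix are discarded,
    exactly as inside ``wfa_align`` and the fused operation.
    """
    if not penalties.is_unit:
        raise ValueError("single-predecessor compute requires unit penalties")
    n = m = 2**30
    if pair is not None:
        n, m = pair.n, pair.m
    wf = _compute_next({prev.score: prev}, prev.score + 1, n, m, penalties)
    if wf is None:
        raise ValueError("no reachable diagonal at the next score")
    return wf


def fused_compute_extend(prev: Wavefront, pair: SequencePair,
                         penalties: Penalties = UNIT,
                         ledger: AccessLedger | None = None,
                         direction: str = "forward") -> Wavefront:
    """Compute then extend in one pass; bitwise-identical to the two-step
    composition, charged at the fused bulk-access rate (2 reads + 1 write
    per element) instead of the separate-pass rate (3 + 2)."""
    wf = compute_wavefront(prev, penalties, pair)
    qa, ra = _oriented_arrays(pair, direction)
    _extend_inplace(wf.offsets, wf.lo, qa, ra)
    if ledger is not None:
        ledger.charge_fused(wf.width)
    return wf


@dataclass
class KernelStats:
    """Instrumentation filled by ``wfa_align`` when requested."""

    steps: int = 0
    elements_computed: int = 0
    peak_retained_elements: int = 0


def _is_terminal(wf: Wavefront, n: int, m: int) -> bool:
    k_end = m - n
    off = wf.offset(k_end)
    return off is not None and off >= m


def _traceback(wfs: Dict[int, Wavefront], score: int, n: int, m: int,
               penalties: Penalties) -> Cigar:
    """Recover one optimal transcript from the retained wavefronts.

    At (score, diagonal), the pre-extension offset marks where an edit
    entered the diagonal; everything between it and the current offset is
    free matches. Ties prefer mismatch, then deletion, then insertion.
    """
    X, I, D = penalties.mismatch, penalties.insertion, penalties.deletion
    ops: list[str] = []
    s, k = score, m - n
    o = m
    while s > 0:
        wf = wfs[s]
        base = wf.base_offset(k)
        if base is None:
            raise RuntimeError("traceback fell off the wavefront set")
        wx = wfs.get(s - X)
        wd = wfs.get(s - D)
        wi = wfs.get(s - I)
        ops.extend("M" * (o - base))
        vx = None if wx is None else wx.offset(k)
        if vx is not None and vx + 1 == base:
            ops.append("X")
            s, o = s - X, vx
            continue
        vd = None if wd is None else wd.offset(k - 1)
        if vd is not None and vd + 1 == base:
            ops.append("D")
            s, k, o = s - D, k - 1, vd
            continue
        vi = None if wi is None else wi.offset(k + 1)
        if vi is not None and vi == base:
            ops.append("I")
            s, k, o = s - I, k + 1, vi
            continue
        raise RuntimeError("no predecessor explains the wavefront offset")
    if k != 0:
        raise RuntimeError("traceback did not reach diagonal 0 at score 0")
    ops.extend("M" * o)
    ops.reverse()
    cigar: list[list] = []
    for op in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1][1] += 1
        else:
            cigar.append([op, 1])
    return tuple((op, ln) for op, ln in cigar)


def wfa_align(pair: SequencePair, penalties: Penalties = UNIT,
              score_cap: int | None = None,
              ledger: AccessLedger | None = None,
              fused: bool = True,
              wavefront_tier: str = "bulk",
              policy: TransferPolicy | None = None,
              fast_buffer_bytes: int = 65536,
              element_bytes: int = 4,
              stats: KernelStats | None = None) -> Alignment:
    """Full WFA with traceback (base-case mode: all wavefronts retained).

    Returns the optimal alignment if its score is within ``score_cap``,
    else an ``interrupted`` alignment whose score is the last score
    examined (a lower bound). ``wavefront_tier`` selects the accounting
    regime: ``"bulk"`` streams wavefronts through the bulk tier (charged
    per element, fused or unfused), ``"fast"`` keeps them entirely in
    fast memory (no bulk wavefront traffic — the base-case regime).
    """
    if score_cap is not None and score_cap < 0:
        raise ValueError("score_cap must be >= 0")
    if wavefront_tier not in ("bulk", "fast"):
        raise ValueError("wavefront_tier must be 'bulk' or 'fast'")
    n, m = pair.n, pair.m
    qa, ra = _oriented_arrays(pair, "forward")
    policy = policy or TransferPolicy()

    def charge(width: int, step: int, transfer_size: int) -> int:
        if ledger is not None:
            if wavefront_tier == "fast":
                ledger.charge_fast(width)
            elif fused:
                ledger.charge_fused(width)
            else:
                ledger.charge_unfused(width)
            demand = max(1, width * element_bytes)
            transfer_size = max(
                transfer_size,
                adaptive_transfer_size(demand, policy, fast_buffer_bytes))
            ledger.log_transfer(step, transfer_size)
        return transfer_size

    wf0 = initial_wavefront(pair)
    _extend_inplace(wf0.offsets, wf0.lo, qa, ra)
    wfs: Dict[int, Wavefront] = {0: wf0}
    retained = wf0.width
    transfer_size = charge(wf0.width, 0, 0)
    if stats is not None:
        stats.steps = 0
        stats.elements_computed = wf0.width
        stats.peak_retained_elements = retained

    s = 0
    limit = penalties.max_penalty * (n + m) + 1
    while not (s in wfs and _is_terminal(wfs[s], n, m)):
        s += 1
        if score_cap is not None and s > score_cap:
            return Alignment(score=s - 1, cigar=(), status="interrupted")
        if s > limit:
            raise RuntimeError("score exceeded the worst-case bound")
        wf = _compute_next(wfs, s, n, m, penalties)
        if wf is None:
            continue
        _extend_inplace(wf.offsets, wf.lo, qa, ra)
        wfs[s] = wf
        retained += wf.width
        transfer_size = charge(wf.width, s, transfer_size)
        if stats is not None:
            stats.steps += 1
            stats.elements_computed += wf.width
            stats.peak_retained_elements = max(
                stats.peak_retained_elements, retained)
        if _is_terminal(wf, n, m):
            break

    cigar = _traceback(wfs, s, n, m, penalties)
    return Alignment(score=s, cigar=cigar)
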