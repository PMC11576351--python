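"""Bidirectional WFA: optimal score and a breakpoint in O(s) memory.

Two wavefront searches advance simultaneously — one from the start of the
pair, one from the end (realised as a forward search over the reversed
sequences) — until their frontiers overlap on a diagonal. The meeting
point is a *breakpoint*: a coordinate on an optimal alignment path, and
the two frontier scores already sum to the optimal alignment score. Only
a constant number of wavefronts per direction stays live (two per
direction under unit penalties), so peak memory is O(s) wavefront
elements instead of the O(s^2) a full traceback would need.

Overlap rule (resolved here; calibrated against the brute-force DP oracle
on exhaustive small inputs and large random suites): after each advance,
a diagonal ``k`` overlaps when ``forward_offset(k) + backward_offset(k')
>= m`` with ``k' = (m - n) - k`` the same diagonal in the reversed frame.
The combined score is ``s_forward + s_backward`` with no correction term.
The breakpoint is placed inside the intersection of the two frontiers'
match runs when they intersect (which guarantees the split is on an
optimal path); otherwise at the forward furthest-reaching point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .core import UNIT, Penalties, SequencePair, Wavefront
from .kernel import (_compute_next, _extend_inplace, _oriented_arrays,
                     initial_wavefront)
from .memory import AccessLedger, TransferPolicy, adaptive_transfer_size

__all__ = ["Breakpoint", "BiwfaStats", "BiwfaSearch", "biwfa_find_breakpoint"]


@dataclass(frozen=True)
class Breakpoint:
    """A split point on an optimal alignment path.

    Aligning ``Q[:q_pos]`` to ``R[:r_pos]`` optimally costs
    ``forward_score`` and the remainder costs ``backward_score``; the two
    sum to the optimal score of the whole pair.
    """

    q_pos: int
    r_pos: int
    forward_score: int
    backward_score: int

    @property
    def score(self) -> int:
        return self.forward_score + self.backward_score


@dataclass
class BiwfaStats:
    """Instrumentation of one bidirectional search."""

    steps: int = 0
    peak_live_wavefronts: int = 0
    peak_live_elements: int = 0
    peak_fast_bytes: int = 0


class BiwfaSearch:
    """Stateful bidirectional search; step-wise for instrumentation.

    Alternation policy: advance whichever direction has the lower score,
    ties advance forward. Wavefronts older than the largest penalty are
    pruned, so under unit penalties each direction keeps exactly two live
    wavefronts once it has advanced (the stated minimum of four overall).
    """

    def __init__(self, pair: SequencePair, penalties: Penalties = UNIT,
                 score_cap: int | None = None,
                 ledger: AccessLedger | None = None,
                 fused: bool = True,
                 budget=None,
                 policy: TransferPolicy | None = None):
        self.pair = pair
        self.penalties = penalties
        self.score_cap = score_cap
        self.ledger = ledger
        self.fused = fused
        self.budget = budget
        self.policy = policy or TransferPolicy()
        self.stats = BiwfaStats()
        n, m = pair.n, pair.m
        self._fwd_seqs = _oriented_arrays(pair, "forward")
        self._bwd_seqs = _oriented_arrays(pair, "backward")
        self._transfer_size = 0
        self._step_index = 0
        self.sf = 0
        self.sb = 0
        wf_f = initial_wavefront(pair)
        _extend_inplace(wf_f.offsets, wf_f.lo, *self._fwd_seqs)
        wf_b = initial_wavefront(pair)
        _extend_inplace(wf_b.offsets, wf_b.lo, *self._bwd_seqs)
        self.fwd: Dict[int, Wavefront] = {0: wf_f}
        self.bwd: Dict[int, Wavefront] = {0: wf_b}
        self._charge(wf_f.width)
        self._charge(wf_b.width)
        self._note_memory()

    # -- instrumentation -------------------------------------------------

    def live_wavefront_count(self) -> int:
        """Number of live wavefronts across both directions."""
        return len(self.fwd) + len(self.bwd)

    def live_element_count(self) -> int:
        return (sum(wf.width for wf in self.fwd.values())
                + sum(wf.width for wf in self.bwd.values()))

    def _note_memory(self) -> None:
        st = self.stats
        st.peak_live_wavefronts = max(st.peak_live_wavefronts,
                                      self.live_wavefront_count())
        st.peak_live_elements = max(st.peak_live_elements,
                                    self.live_element_count())
        if self.budget is not None:
            eb = self.budget.wavefront_element_bytes
            slot = self.budget.wavefront_slot_bytes
            resident = sum(min(wf.width * eb, slot)
                           for wfs in (self.fwd, self.bwd)
                           for wf in wfs.values())
            st.peak_fast_bytes = max(st.peak_fast_bytes, resident)

    def _charge(self, width: int) -> None:
        if self.ledger is None:
            return
        if self.fused:
            self.ledger.charge_fused(width)
        else:
            self.ledger.charge_unfused(width)
        eb = (self.budget.wavefront_element_bytes
              if self.budget is not None else 4)
        buffer_bytes = (self.budget.wavefront_slot_bytes
                        if self.budget is not None else 65536)
        demand = max(1, width * eb)
        self._transfer_size = max(
            self._transfer_size,
            adaptive_transfer_size(demand, self.policy, buffer_bytes))
        self.ledger.log_transfer(self._step_index, self._transfer_size)

    # -- search ----------------------------------------------------------

    def _overlap_between(self, fw: Wavefront, bw: Wavefront
                         ) -> Optional[Breakpoint]:
        """Breakpoint where these two wavefronts meet, if they do."""
        n, m = self.pair.n, self.pair.m
        delta = m - n
        # Backward diagonals kb map to forward diagonals k = delta - kb.
        lo = max(fw.lo, delta - bw.hi)
        hi = min(fw.hi, delta - bw.lo)
        if lo > hi:
            return None
        ks = np.arange(lo, hi + 1, dtype=np.int64)
        rf = fw.offsets[ks - fw.lo].astype(np.int64)
        ef = fw.base_offsets[ks - fw.lo].astype(np.int64)
        idx_b = (delta - ks) - bw.lo
        rb = bw.offsets[idx_b].astype(np.int64)
        eb = bw.base_offsets[idx_b].astype(np.int64)
        simple = (rf >= 0) & (rb >= 0) & (rf + rb >= m)
        if not simple.any():
            return None
        # Backward coverage on diagonal k in the forward frame: reference
        # positions [m - rb, m - eb]; forward match run covers [ef, rf].
        rb_min = m - rb
        eb_orig = m - eb
        strict = simple & (np.maximum(ef, rb_min) <= np.minimum(rf, eb_orig))
        if strict.any():
            i = int(np.nonzero(strict)[0][0])
            r_bp = int(max(ef[i], rb_min[i]))
        else:
            i = int(np.nonzero(simple)[0][0])
            r_bp = int(rf[i])
        k = int(ks[i])
        return Breakpoint(q_pos=r_bp - k, r_pos=r_bp,
                          forward_score=fw.score, backward_score=bw.score)

    def _check_overlap(self, forward: Optional[bool] = None
                       ) -> Optional[Breakpoint]:
        """Best meeting of the newest wavefront(s) with the other frontier.

        With non-unit penalties the split of the optimal score between the
        two directions is only penalty-granular, so the newly advanced
        wavefront must be compared against *every* retained wavefront of
        the opposite direction, not just its newest one.
        """
        if forward is None:
            news, olds = [self.fwd[max(self.fwd)]], self.bwd
        elif forward:
            wf = self.fwd.get(self.sf)
            if wf is None:
                return None
            news, olds = [wf], self.bwd
        else:
            wf = self.bwd.get(self.sb)
            if wf is None:
                return None
            news, olds = [wf], self.fwd
        best = None
        for new_wf in news:
            for other in olds.values():
                fw, bw = ((new_wf, other) if olds is self.bwd
                          else (other, new_wf))
                bp = self._overlap_between(fw, bw)
                if bp is not None and (best is None or
                                       (bp.score, bp.backward_score)
                                       < (best.score, best.backward_score)):
                    best = bp
        return best

    def _advance(self, forward: bool) -> None:
        n, m = self.pair.n, self.pair.m
        wfs = self.fwd if forward else self.bwd
        score = (self.sf if forward else self.sb) + 1
        self._step_index += 1
        wf = _compute_next(wfs, score, n, m, self.penalties)
        if wf is not None:
            seqs = self._fwd_seqs if forward else self._bwd_seqs
            _extend_inplace(wf.offsets, wf.lo, *seqs)
            wfs[score] = wf
            self._charge(wf.width)
        if forward:
            self.sf = score
        else:
            self.sb = score
        # Keep the source window [score - max_penalty, score]: the new
        # wavefront plus what the next compute step can still reference —
        # two per direction under unit penalties.
        horizon = score - self.penalties.max_penalty
        for old in [key for key in wfs if key < horizon]:
            del wfs[old]
        self.stats.steps += 1
        self._note_memory()

    def run(self) -> Optional[Breakpoint]:
        """Search to completion; None when the score cap interrupts.

        A first detected meeting need not be the best one when penalties
        are non-unit: the search continues until no future pairing of a
        frontier with a retained opposite wavefront could beat the best
        meeting found, i.e. until ``best.score <= sf + sb + 1 - max_penalty``.
        Under unit penalties this stops at the first detection.
        """
        n, m = self.pair.n, self.pair.m
        if n == 0 or m == 0:
            # Backward frontier is degenerate on an empty side; the whole
            # pair is indels and (0, 0) lies trivially on the optimal path.
            cost = m * self.penalties.deletion + n * self.penalties.insertion
            if self.score_cap is not None and cost > self.score_cap:
                return None
            return Breakpoint(0, 0, 0, cost)
        maxpen = self.penalties.max_penalty
        limit = maxpen * (n + m) + 2
        best = self._check_overlap()
        while best is None or best.score > self.sf + self.sb + 1 - maxpen:
            if self.score_cap is not None:
                if best is not None and best.score <= self.score_cap:
                    pass  # already good enough; keep refining below the cap
                elif self.sf + self.sb + 1 - maxpen > self.score_cap:
                    return None if best is None or best.score > self.score_cap \
                        else best
            if self.sf + self.sb > limit:
                raise RuntimeError("bidirectional search exceeded the "
                                   "worst-case score bound")
            forward = self.sf <= self.sb
            self._advance(forward=forward)
            bp = self._check_overlap(forward=forward)
            if bp is not None and (best is None or
                                   (bp.score, bp.backward_score)
                                   < (best.score, best.backward_score)):
                best = bp
        if self.score_cap is not None and best.score > self.score_cap:
            return None
        return best


def biwfa_find_breakpoint(pair: SequencePair, penalties: Penalties = UNIT,
                          score_cap: int | None = None,
                          ledger: AccessLedger | None = None,
                          fused: bool = True,
                          budget=None,
                          stats: BiwfaStats | None = None
                          ) -> Optional[Breakpoint]:
    """Optimal score and a breakpoint using O(s) live wavefront memory.

    Returns None when the combined score would exceed ``score_cap``
    (interruption; the caller flags the pair for recovery).
    """
    if score_cap is not None and score_cap < 0:
        raise ValueError("score_cap must be >= 0")
    search = BiwfaSearch(pair, penalties, score_cap=score_cap, ledger=ledger,
                         fused=fused, budget=budget)
    bp = search.run()
    if stats is not None:
        stats.steps = search.stats.steps
        stats.peak_live_wavefronts = search.stats.peak_live_wavefronts
        stats.peak_live_elements = search.stats.peak_live_elements
        stats.peak_fast_bytes = search.stats.peak_fast_bytes
    return bp
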