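"""The breakpoint-unrolled alignment pipeline.

Instead of recursing on the two halves of each bidirectional split — a
poor fit for workers with tiny stacks — the pipeline keeps an explicit
work queue of *segments*. Each segment either (a) is a base case whose
score bound is small enough that a full WFA with traceback fits the fast
memory tier, in which case it is solved in place, or (b) is split at a
fresh breakpoint into two children that inherit their side's exact score
as bound. Base-case transcripts carry an order index and are written
consecutively, so the final CIGAR is a plain in-order concatenation with
no reshuffling.

The base-case rule: a score-``s`` WFA retains wavefronts ``0..s`` and the
wavefront at score ``t`` spans ``2t + 1`` diagonals, so the full set holds
``(s + 1)^2`` offsets. A segment of bound ``s`` is a base case when a WFA
allowed to run up to ``4 * s`` — a 4x safety factor over the inherited
bound — still fits the fast tier: ``(4s + 1)^2 * element_bytes <=
fast_capacity_bytes``. Under the 64 KB default this admits bounds up to 31.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from typing import Iterable, List, Tuple

from .biwfa import BiwfaStats, biwfa_find_breakpoint
from .core import (UNIT, Alignment, AssemblyError, Cigar, Penalties,
                   SequencePair, cigar_concat, cigar_score)
from .kernel import KernelStats, wfa_align
from .memory import AccessLedger

__all__ = [
    "MemoryBudget",
    "Segment",
    "SegmentResult",
    "DriverStats",
    "base_case_threshold",
    "assemble_output",
    "align_unrolled",
]


@dataclass(frozen=True)
class MemoryBudget:
    """Fast-tier capacity and wavefront element size of one worker.

    Defaults mirror a 64 KB working memory with 32-bit signed offsets.
    A quarter of the capacity is the per-wavefront slot for the four live
    bidirectional wavefronts; base cases repurpose the whole allocation.
    """

    fast_capacity_bytes: int = 65536
    wavefront_element_bytes: int = 4

    def __post_init__(self) -> None:
        if self.fast_capacity_bytes < 1 or self.wavefront_element_bytes < 1:
            raise ValueError("capacities must be positive")
        if self.base_case_max_score < 1:
            raise ValueError(
                "fast capacity too small to hold any base-case wavefront set")

    @property
    def wavefront_slot_bytes(self) -> int:
        return self.fast_capacity_bytes // 4

    @property
    def base_case_max_score(self) -> int:
        """Largest segment bound s with (4s+1)^2 elements in fast capacity."""
        cells = self.fast_capacity_bytes // self.wavefront_element_bytes
        return (math.isqrt(cells) - 1) // 4


def base_case_threshold(budget: MemoryBudget, current_biwfa_score: int) -> bool:
    """True iff a WFA capped at 4x the inherited bound fits the fast tier."""
    if current_biwfa_score < 0:
        raise ValueError("score must be non-negative")
    side = 4 * current_biwfa_score + 1
    return side * side * budget.wavefront_element_bytes <= budget.fast_capacity_bytes


@dataclass
class Segment:
    """A sub-problem: half-open windows of Q and R plus a score bound."""

    q_start: int
    q_end: int
    r_start: int
    r_end: int
    bound_score: int | None
    order_index: Tuple[int, ...] = ()

    @property
    def q_len(self) -> int:
        return self.q_end - self.q_start

    @property
    def r_len(self) -> int:
        return self.r_end - self.r_start


@dataclass(frozen=True)
class SegmentResult:
    order_index: Tuple[int, ...] | int
    cigar: Cigar


@dataclass
class DriverStats:
    """Instrumentation of one unrolled alignment."""

    splits: int = 0
    base_cases: int = 0
    segments: int = 0
    peak_fast_bytes: int = 0
    peak_live_elements: int = 0
    base_case_bulk_accesses: int = 0
    max_child_bound: int = 0


def assemble_output(parts: Iterable[SegmentResult],
                    penalties: Penalties = UNIT) -> Alignment:
    """Concatenate base-case outputs in order-index order.

    Arrival order is irrelevant; the order index governs. Raises
    AssemblyError when an index is missing or duplicated.
    """
    items = sorted(parts, key=lambda p: p.order_index)
    if not items:
        raise AssemblyError("no parts to assemble")
    keys = [p.order_index for p in items]
    if len(set(keys)) != len(keys):
        raise AssemblyError("duplicate order_index among parts")
    if all(isinstance(key, int) for key in keys):
        if keys != list(range(len(keys))):
            raise AssemblyError(f"order indices {keys} do not tile 0..{len(keys) - 1}")
    cigar = cigar_concat([p.cigar for p in items])
    return Alignment(score=cigar_score(cigar, penalties), cigar=cigar)


def align_unrolled(pair: SequencePair, penalties: Penalties = UNIT,
                   budget: MemoryBudget | None = None,
                   score_cap: int | None = None,
                   ledger: AccessLedger | None = None,
                   fused: bool = True,
                   stats: DriverStats | None = None) -> Alignment:
    """Optimal global alignment via iterative breakpoint unrolling.

    Bidirectional splits run in the streaming (bulk-charged) regime; base
    cases run entirely in the fast tier and incur no bulk wavefront
    traffic. Returns an ``interrupted`` alignment when the optimal score
    exceeds ``score_cap`` (the pair is then a candidate for recovery on an
    unconstrained path).
    """
    budget = budget or MemoryBudget()
    stats = stats if stats is not None else DriverStats()
    q, r = pair.query, pair.reference
    parts: List[SegmentResult] = []
    queue = deque([Segment(0, pair.n, 0, pair.m, None, ())])

    while queue:
        seg = queue.popleft()
        stats.segments += 1
        qs = q[seg.q_start:seg.q_end]
        rs = r[seg.r_start:seg.r_end]
        # Degenerate and zero-score segments emit their transcript directly.
        if seg.q_len == 0 and seg.r_len == 0:
            parts.append(SegmentResult(seg.order_index, ()))
            continue
        if seg.q_len == 0:
            parts.append(SegmentResult(seg.order_index, (("D", seg.r_len),)))
            continue
        if seg.r_len == 0:
            parts.append(SegmentResult(seg.order_index, (("I", seg.q_len),)))
            continue
        if qs == rs:
            parts.append(SegmentResult(seg.order_index, (("M", len(qs)),)))
            continue

        sub = SequencePair(qs, rs, pair.pair_id)
        if seg.bound_score is not None and base_case_threshold(budget, seg.bound_score):
            before = 0 if ledger is None else ledger.bulk_accesses
            kstats = KernelStats()
            res = wfa_align(sub, penalties,
                            score_cap=4 * seg.bound_score,
                            ledger=ledger, fused=fused,
                            wavefront_tier="fast",
                            fast_buffer_bytes=budget.fast_capacity_bytes,
                            element_bytes=budget.wavefront_element_bytes,
                            stats=kstats)
            if res.status != "complete":
                raise RuntimeError(
                    "base case exceeded 4x its inherited score bound")
            stats.base_cases += 1
            stats.base_case_bulk_accesses += (
                0 if ledger is None else ledger.bulk_accesses - before)
            fast_bytes = (kstats.peak_retained_elements
                          * budget.wavefront_element_bytes)
            stats.peak_fast_bytes = max(stats.peak_fast_bytes, fast_bytes)
            stats.peak_live_elements = max(stats.peak_live_elements,
                                           kstats.peak_retained_elements)
            parts.append(SegmentResult(seg.order_index, res.cigar))
            continue

        bstats = BiwfaStats()
        remaining_cap = score_cap if seg.bound_score is None else None
        bp = biwfa_find_breakpoint(sub, penalties, score_cap=remaining_cap,
                                   ledger=ledger, fused=fused, budget=budget,
                                   stats=bstats)
        stats.peak_fast_bytes = max(stats.peak_fast_bytes,
                                    bstats.peak_fast_bytes)
        stats.peak_live_elements = max(stats.peak_live_elements,
                                       bstats.peak_live_elements)
        if bp is None:
            return Alignment(score=0, cigar=(), status="interrupted")
        stats.splits += 1
        stats.max_child_bound = max(stats.max_child_bound,
                                    bp.forward_score, bp.backward_score)
        queue.append(Segment(seg.q_start, seg.q_start + bp.q_pos,
                             seg.r_start, seg.r_start + bp.r_pos,
                             bp.forward_score, seg.order_index + (0,)))
        queue.append(Segment(seg.q_start + bp.q_pos, seg.q_end,
                             seg.r_start + bp.r_pos, seg.r_end,
                             bp.backward_score, seg.order_index + (1,)))

    assembled = assemble_output(parts, penalties)
    if score_cap is not None and assembled.score > score_cap:
        return Alignment(score=assembled.score, cigar=(), status="interrupted")
    return assembled
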