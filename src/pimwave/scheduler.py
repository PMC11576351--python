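"""Batch execution across simulated worker slots with hybrid recovery.

Pairs are dealt to worker slots dynamically from a shared monotone pair-id
counter — the minimal-synchronization scheme that keeps irregular
workloads balanced — and executed in batches. A worker aligns its pair
with the memory-budgeted unrolled pipeline under an optional *nominal
score limit*: pairs whose optimal score exceeds the limit are interrupted
and flagged. Flagged pairs are then re-aligned from scratch on an
unconstrained fallback path (plain WFA with full traceback), modeling the
host-CPU recovery that overlaps with the next batch's computation. Workers
are deterministic sequential slots in round-robin event order; the
contract is scheduling semantics, not concurrency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .core import UNIT, Alignment, Penalties, SequencePair
from .driver import MemoryBudget, align_unrolled
from .kernel import wfa_align
from .memory import AccessLedger

__all__ = ["BatchPlan", "RecoveryReport", "dynamic_assign", "run_batches"]


@dataclass
class BatchPlan:
    """Worker slots, batch size and the nominal score limit."""

    workers: int = 4
    batch_size: int = 64
    score_cap: Optional[int] = None  # None = unlimited
    next_pair_id: int = 0
    total_pairs: Optional[int] = None

    def __post_init__(self) -> None:
        if self.workers < 1 or self.batch_size < 1:
            raise ValueError("workers and batch_size must be positive")
        if self.score_cap is not None and self.score_cap < 0:
            raise ValueError("score_cap must be >= 0 or None")


def dynamic_assign(plan: BatchPlan) -> Optional[int]:
    """Issue the next unassigned pair id; None when work is exhausted."""
    if plan.total_pairs is not None and plan.next_pair_id >= plan.total_pairs:
        return None
    issued = plan.next_pair_id
    plan.next_pair_id += 1
    return issued


@dataclass
class RecoveryReport:
    """Outcome bookkeeping of one batched run."""

    total_pairs: int = 0
    recovered_pairs: int = 0
    paths: List[str] = field(default_factory=list)  # per pair: worker|recovery
    events: List[str] = field(default_factory=list)
    batch_count: int = 0

    @property
    def recovered_fraction(self) -> float:
        if self.total_pairs == 0:
            return 0.0
        return self.recovered_pairs / self.total_pairs

    def as_dict(self) -> dict:
        return {
            "total_pairs": self.total_pairs,
            "recovered_pairs": self.recovered_pairs,
            "recovered_fraction": self.recovered_fraction,
            "batch_count": self.batch_count,
        }


def run_batches(pairs: Sequence[SequencePair], penalties: Penalties = UNIT,
                plan: BatchPlan | None = None,
                budget: MemoryBudget | None = None,
                ledger: AccessLedger | None = None,
                fused: bool = True
                ) -> Tuple[List[Alignment], RecoveryReport]:
    """Align every pair exactly once via the worker or the recovery path.

    Results are returned in input order. The event log interleaves the
    recovery of batch ``i`` with the computation of batch ``i + 1``,
    modeling the overlap of host-side recovery with the next kernel batch.
    """
    if not pairs:
        raise ValueError("pairs must be nonempty")
    plan = plan or BatchPlan()
    plan.total_pairs = len(pairs)
    plan.next_pair_id = 0
    budget = budget or MemoryBudget()
    report = RecoveryReport(total_pairs=len(pairs),
                            paths=["pending"] * len(pairs))
    results: List[Optional[Alignment]] = [None] * len(pairs)

    batches: List[List[Tuple[int, int]]] = []  # [(worker, pair_id)]
    while True:
        batch: List[Tuple[int, int]] = []
        for slot in range(plan.batch_size):
            worker = slot % plan.workers
            pair_id = dynamic_assign(plan)
            if pair_id is None:
                break
            batch.append((worker, pair_id))
        if not batch:
            break
        batches.append(batch)
    report.batch_count = len(batches)

    pending_recovery: List[Tuple[int, int]] = []  # (batch, pair_id)
    for batch_index, batch in enumerate(batches):
        # Recovery of the previous batch overlaps this batch's computation.
        overlapped = pending_recovery
        pending_recovery = []
        for position, (worker, pair_id) in enumerate(batch):
            if overlapped and position % 2 == 1:
                prev_batch, rec_id = overlapped.pop(0)
                _recover(pairs[rec_id], rec_id, prev_batch, penalties,
                         results, report)
            alignment = align_unrolled(pairs[pair_id], penalties,
                                       budget=budget,
                                       score_cap=plan.score_cap,
                                       ledger=ledger, fused=fused)
            report.events.append(
                f"compute batch={batch_index} worker={worker} "
                f"pair={pair_id} status={alignment.status}")
            if alignment.status == "complete":
                results[pair_id] = alignment
                report.paths[pair_id] = "worker"
            else:
                pending_recovery.append((batch_index, pair_id))
        for prev_batch, rec_id in overlapped:
            _recover(pairs[rec_id], rec_id, prev_batch, penalties,
                     results, report)
    for prev_batch, rec_id in pending_recovery:
        _recover(pairs[rec_id], rec_id, prev_batch, penalties,
                 results, report)

    assert all(res is not None for res in results)
    assert all(path in ("worker", "recovery") for path in report.paths)
    return results, report  # type: ignore[return-value]


def _recover(pair: SequencePair, pair_id: int, batch_index: int,
             penalties: Penalties, results: List[Optional[Alignment]],
             report: RecoveryReport) -> None:
    alignment = wfa_align(pair, penalties)  # unconstrained fallback
    results[pair_id] = alignment
    report.paths[pair_id] = "recovery"
    report.recovered_pairs += 1
    report.events.append(
        f"recover batch={batch_index} pair={pair_id} status=complete")
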