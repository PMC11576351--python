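"""Two-tier memory model: a fast scratch tier and a bulk tier.

Models the memory hierarchy of a processing-in-memory worker — a small
fast working memory (64 KB by default) next to a large bulk DRAM bank
(64 MB) — as *logical access counting*, not latency simulation. The
counters make the package's access-reduction claims measurable:

* streaming a wavefront through the bulk tier costs 3 reads + 2 writes
  per element when compute and extend run as separate passes, and
  2 reads + 1 write when they are fused into one pass (a 40% reduction);
* block transfers between tiers are 8-byte aligned, sized in powers of
  two between 8 and 2048 bytes, and grown adaptively as wavefronts widen;
* sequence data is read from the bulk tier in chunks of at most 16
  characters, forward or reverse, without keeping a reversed copy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .core import AddressError, CapacityError, Wavefront

__all__ = [
    "AccessLedger",
    "TransferPolicy",
    "charge_unfused",
    "charge_fused",
    "adaptive_transfer_size",
    "BulkSequenceStore",
    "reverse_block_read",
    "spill_wavefront",
]

UNFUSED_READS_PER_ELEMENT = 3
UNFUSED_WRITES_PER_ELEMENT = 2
FUSED_READS_PER_ELEMENT = 2
FUSED_WRITES_PER_ELEMENT = 1


@dataclass
class TransferPolicy:
    """Block-transfer sizing rules between the bulk and fast tiers."""

    initial_bytes: int = 8
    max_bytes: int = 2048
    alignment: int = 8
    sequence_chunk: int = 16  # characters per modeled sequence transfer

    def __post_init__(self) -> None:
        for name in ("initial_bytes", "max_bytes", "alignment"):
            v = getattr(self, name)
            if v < 1 or v & (v - 1):
                raise ValueError(f"{name} must be a positive power of two")
        if self.sequence_chunk < 1:
            raise ValueError("sequence_chunk must be positive")


@dataclass
class AccessLedger:
    """Monotone counters of modeled memory traffic.

    ``bulk_reads``/``bulk_writes`` count wavefront *element* touches in the
    bulk tier; ``block_reads``/``block_writes`` count aligned block
    transfers (sequence and CIGAR traffic); ``fast_elements`` counts
    wavefront elements computed entirely in the fast tier (base cases).
    """

    bulk_reads: int = 0
    bulk_writes: int = 0
    block_reads: int = 0
    block_writes: int = 0
    elements_computed: int = 0
    fast_elements: int = 0
    spilled_elements: int = 0
    sequence_bytes_read: int = 0
    transfer_size_log: List[Tuple[int, int]] = field(default_factory=list)

    def charge_unfused(self, elements: int) -> "AccessLedger":
        if elements < 0:
            raise ValueError("elements must be non-negative")
        self.bulk_reads += UNFUSED_READS_PER_ELEMENT * elements
        self.bulk_writes += UNFUSED_WRITES_PER_ELEMENT * elements
        self.elements_computed += elements
        return self

    def charge_fused(self, elements: int) -> "AccessLedger":
        if elements < 0:
            raise ValueError("elements must be non-negative")
        self.bulk_reads += FUSED_READS_PER_ELEMENT * elements
        self.bulk_writes += FUSED_WRITES_PER_ELEMENT * elements
        self.elements_computed += elements
        return self

    def charge_fast(self, elements: int) -> "AccessLedger":
        """Account elements computed wholly in the fast tier (no bulk traffic)."""
        if elements < 0:
            raise ValueError("elements must be non-negative")
        self.fast_elements += elements
        return self

    def log_transfer(self, iteration: int, nbytes: int) -> None:
        self.transfer_size_log.append((iteration, nbytes))

    @property
    def bulk_accesses(self) -> int:
        return self.bulk_reads + self.bulk_writes

    def accesses_per_element(self) -> float:
        if self.elements_computed == 0:
            return 0.0
        return self.bulk_accesses / self.elements_computed

    def as_dict(self) -> dict:
        return {
            "bulk_reads": self.bulk_reads,
            "bulk_writes": self.bulk_writes,
            "bulk_accesses": self.bulk_accesses,
            "block_reads": self.block_reads,
            "block_writes": self.block_writes,
            "elements_computed": self.elements_computed,
            "fast_elements": self.fast_elements,
            "spilled_elements": self.spilled_elements,
            "sequence_bytes_read": self.sequence_bytes_read,
            "transfers_logged": len(self.transfer_size_log),
        }

    def render_text(self) -> str:
        return "\n".join(f"{key}\t{value}" for key, value in self.as_dict().items())

    def merge(self, other: "AccessLedger") -> "AccessLedger":
        self.bulk_reads += other.bulk_reads
        self.bulk_writes += other.bulk_writes
        self.block_reads += other.block_reads
        self.block_writes += other.block_writes
        self.elements_computed += other.elements_computed
        self.fast_elements += other.fast_elements
        self.spilled_elements += other.spilled_elements
        self.sequence_bytes_read += other.sequence_bytes_read
        self.transfer_size_log.extend(other.transfer_size_log)
        return self


def charge_unfused(ledger: AccessLedger, elements: int) -> AccessLedger:
    """Separate compute + extend: 3 reads and 2 writes per wavefront element."""
    return ledger.charge_unfused(elements)


def charge_fused(ledger: AccessLedger, elements: int) -> AccessLedger:
    """Fused compute+extend: 2 reads and 1 write per wavefront element."""
    return ledger.charge_fused(elements)


def _next_pow2(value: int) -> int:
    return 1 << max(0, (value - 1).bit_length())


def _prev_pow2(value: int) -> int:
    if value < 1:
        raise ValueError("value must be positive")
    return 1 << (value.bit_length() - 1)


def adaptive_transfer_size(iteration_wavefront_bytes: int,
                           policy: TransferPolicy,
                           fast_buffer_bytes: int) -> int:
    """Current transfer size for a wavefront of the given footprint.

    Smallest power of two >= demand, never below ``policy.initial_bytes``
    and never above ``min(policy.max_bytes, fast buffer allocation)``.
    Callers enforce monotone growth across the iterations of one alignment
    by keeping the running maximum.
    """
    if iteration_wavefront_bytes < 1 or fast_buffer_bytes < 1:
        raise ValueError("inputs must be positive")
    cap = min(policy.max_bytes, _prev_pow2(fast_buffer_bytes))
    size = max(policy.initial_bytes, _next_pow2(iteration_wavefront_bytes))
    return max(policy.initial_bytes, min(size, cap))


#: Default bulk-tier capacity per worker (bytes).
BULK_CAPACITY_DEFAULT = 64 * 1024 * 1024


class BulkSequenceStore:
    """A sequence resident in the bulk tier, padded for aligned reads.

    The store is padded up to a transfer-alignment multiple at both ends so
    that aligned forward *and reverse* reads near the boundaries never
    address outside physical limits, without keeping a duplicated reversed
    copy of the sequence.
    """

    def __init__(self, data: bytes, policy: TransferPolicy | None = None,
                 capacity_bytes: int = BULK_CAPACITY_DEFAULT):
        self.policy = policy or TransferPolicy()
        if len(data) > capacity_bytes:
            raise CapacityError(
                f"sequence of {len(data)} bytes exceeds bulk capacity "
                f"{capacity_bytes}")
        self.length = len(data)
        align = self.policy.alignment
        pad = (-self.length) % align
        self._buffer = np.frombuffer(data + b"\0" * pad, dtype=np.uint8)

    def _charge(self, ledger: AccessLedger | None, start: int, end: int) -> None:
        """Charge chunked, 8-byte-aligned block reads covering [start, end)."""
        if ledger is None:
            return
        align = self.policy.alignment
        chunk = self.policy.sequence_chunk
        pos = start
        while pos < end:
            stop = min(pos + chunk, end)
            a = (pos // align) * align
            b = -((-stop) // align) * align  # round up to alignment
            ledger.block_reads += (b - a) // align
            ledger.sequence_bytes_read += b - a
            pos = stop

    def read_forward(self, start: int, length: int,
                     ledger: AccessLedger | None = None) -> bytes:
        end = start + length
        if start < 0 or end > len(self._buffer):
            raise AddressError(f"read [{start}, {end}) outside padded store")
        self._charge(ledger, start, end)
        return self._buffer[start:end].tobytes()

    def read_reverse(self, start: int, length: int,
                     ledger: AccessLedger | None = None) -> bytes:
        """Bytes of [start, start+length) delivered last-to-first."""
        end = start + length
        if start < 0 or end > len(self._buffer):
            raise AddressError(f"read [{start}, {end}) outside padded store")
        self._charge(ledger, start, end)
        return self._buffer[start:end][::-1].tobytes()


def reverse_block_read(bulk: BulkSequenceStore, start: int, length: int,
                       policy: TransferPolicy | None = None,
                       ledger: AccessLedger | None = None) -> bytes:
    """Read a window of a bulk-resident sequence in reverse order.

    Equivalent to ``data[start:start+length][::-1]``; the ledger is charged
    with 8-byte-aligned block transfers in chunks of at most
    ``policy.sequence_chunk`` characters.
    """
    if policy is not None:
        bulk.policy = policy
    return bulk.read_reverse(start, length, ledger)


def spill_wavefront(wf: Wavefront, budget, ledger: AccessLedger | None = None,
                    bulk_capacity_bytes: int = BULK_CAPACITY_DEFAULT) -> str:
    """Place a wavefront in the fast or bulk tier under a memory budget.

    ``budget`` provides ``wavefront_slot_bytes`` (per-wavefront fast-tier
    allocation) and ``wavefront_element_bytes``. Elements beyond the fast
    allocation spill to the bulk tier and are charged to the ledger.
    Returns ``"fast"`` or ``"bulk"``.
    """
    element_bytes = budget.wavefront_element_bytes
    nbytes = wf.width * element_bytes
    if nbytes > bulk_capacity_bytes:
        raise CapacityError(
            f"wavefront of {nbytes} bytes exceeds bulk capacity "
            f"{bulk_capacity_bytes}")
    if nbytes <= budget.wavefront_slot_bytes:
        return "fast"
    overflow = wf.width - budget.wavefront_slot_bytes // element_bytes
    if ledger is not None:
        ledger.spilled_elements += overflow
        ledger.bulk_writes += overflow
    return "bulk"
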