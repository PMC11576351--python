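"""Access ledger, transfer sizing, aligned sequence reads, spilling."""

import numpy as np
import pytest

from pimwave import (AccessLedger, BulkSequenceStore, MemoryBudget,
                     SequencePair, TransferPolicy, adaptive_transfer_size,
                     charge_fused, charge_unfused, reverse_block_read,
                     spill_wavefront, wfa_align)
from pimwave.core import AddressError, CapacityError, Wavefront


def make_wavefront(width: int) -> Wavefront:
    offsets = np.zeros(width, dtype=np.int32)
    return Wavefront(0, 0, width - 1, offsets, offsets.copy())


class TestCharging:
    def test_zero_elements_leaves_ledger_unchanged(self):
        ledger = AccessLedger()
        charge_unfused(ledger, 0)
        charge_fused(ledger, 0)
        assert ledger.bulk_accesses == 0 and ledger.elements_computed == 0

    def test_per_element_rates(self):
        ledger = AccessLedger()
        charge_unfused(ledger, 1)
        assert (ledger.bulk_reads, ledger.bulk_writes) == (3, 2)
        ledger = AccessLedger()
        charge_fused(ledger, 1)
        assert (ledger.bulk_reads, ledger.bulk_writes) == (2, 1)

    def test_linear_accumulation(self, rng):
        total = 0
        ledger = AccessLedger()
        for _ in range(20):
            n = rng.randint(0, 500)
            charge_unfused(ledger, n)
            total += n
        assert ledger.bulk_accesses == 5 * total
        ledger = AccessLedger()
        for _ in range(20):
            charge_fused(ledger, 7)
        assert ledger.bulk_accesses == 3 * 7 * 20

    def test_fused_is_forty_percent_cheaper_for_same_elements(self):
        a, b = AccessLedger(), AccessLedger()
        charge_unfused(a, 1234)
        charge_fused(b, 1234)
        assert b.bulk_accesses / a.bulk_accesses == pytest.approx(0.6)

    def test_negative_elements_rejected(self):
        with pytest.raises(ValueError):
            charge_fused(AccessLedger(), -1)


class TestAdaptiveTransfer:
    def test_starts_at_eight_bytes(self):
        assert adaptive_transfer_size(4, TransferPolicy(), 65536) == 8

    def test_caps_at_platform_limit(self):
        assert adaptive_transfer_size(100000, TransferPolicy(), 10**9) == 2048

    def test_least_power_of_two_at_least_demand(self):
        policy = TransferPolicy()
        for demand in range(1, 5000, 7):
            size = adaptive_transfer_size(demand, policy, 65536)
            # direct enumeration of admissible sizes
            admissible = [2**e for e in range(3, 12)]
            wanted = [s for s in admissible if s >= demand]
            expected = wanted[0] if wanted else admissible[-1]
            assert size == expected

    def test_fast_buffer_bounds_the_size(self):
        assert adaptive_transfer_size(900, TransferPolicy(), 1000) == 512

    def test_sizes_logged_during_alignment_are_valid_and_monotone(self, rng):
        from tests.conftest import random_pair
        for _ in range(10):
            pair = random_pair(rng, max_len=300)
            ledger = AccessLedger()
            wfa_align(pair, ledger=ledger)
            sizes = [nbytes for _it, nbytes in ledger.transfer_size_log]
            assert sizes, "alignment logged no transfers"
            assert all(8 <= s <= 2048 and s & (s - 1) == 0 for s in sizes)
            assert all(a <= b for a, b in zip(sizes, sizes[1:]))


class TestSequenceStore:
    def test_reverse_read_is_reversal_of_forward(self, rng):
        for _ in range(25):
            data = bytes(rng.getrandbits(8) for _ in range(rng.randint(1, 200)))
            store = BulkSequenceStore(data)
            start = rng.randint(0, len(data) - 1)
            length = rng.randint(0, len(data) - start)
            fwd = store.read_forward(start, length)
            rev = reverse_block_read(store, start, length)
            assert rev == fwd[::-1] == data[start:start + length][::-1]

    def test_whole_sequence_reverse(self):
        store = BulkSequenceStore(b"ACGTACGTA")
        assert store.read_reverse(0, 9) == b"ATGCATGCA"

    def test_unaligned_read_charges_rounded_down_block(self):
        store = BulkSequenceStore(b"A" * 64)
        ledger = AccessLedger()
        store.read_forward(5, 3, ledger)  # bytes [5,8) -> one block [0,8)
        assert ledger.block_reads == 1
        assert ledger.sequence_bytes_read == 8

    def test_chunking_limits_each_transfer_to_sixteen_characters(self):
        store = BulkSequenceStore(b"A" * 64)
        ledger = AccessLedger()
        store.read_forward(0, 48, ledger)  # 3 chunks x 2 blocks
        assert ledger.block_reads == 6

    def test_out_of_bounds_beyond_padding(self):
        store = BulkSequenceStore(b"ACGTA")  # padded to 8
        store.read_forward(0, 8)  # padding is addressable
        with pytest.raises(AddressError):
            store.read_forward(0, 9)

    def test_capacity_guard(self):
        with pytest.raises(CapacityError):
            BulkSequenceStore(b"A" * 100, capacity_bytes=64)


class TestSpill:
    def test_small_wavefront_stays_fast(self):
        ledger = AccessLedger()
        placement = spill_wavefront(make_wavefront(10), MemoryBudget(), ledger)
        assert placement == "fast" and ledger.spilled_elements == 0

    def test_oversized_wavefront_spills_and_charges(self):
        budget = MemoryBudget()
        slot_elements = budget.wavefront_slot_bytes // 4
        ledger = AccessLedger()
        placement = spill_wavefront(make_wavefront(slot_elements + 100),
                                    budget, ledger)
        assert placement == "bulk"
        assert ledger.spilled_elements == 100

    def test_bulk_capacity_guard(self):
        with pytest.raises(CapacityError):
            spill_wavefront(make_wavefront(100), MemoryBudget(),
                            AccessLedger(), bulk_capacity_bytes=64)

    def test_bulk_charges_nondecreasing_in_error_rate(self, rng):
        """Graded error rates: more score, never fewer bulk charges."""
        from tests.conftest import mutate
        import random as _random
        reference = "".join(rng.choice("ACGT") for _ in range(3000))
        previous = -1
        for error in (0.0, 0.05, 0.1, 0.2):
            query = mutate(reference, error, _random.Random(5))
            ledger = AccessLedger()
            wfa_align(SequencePair(query.encode(), reference.encode()),
                      ledger=ledger)
            assert ledger.bulk_accesses >= previous
            previous = ledger.bulk_accesses
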