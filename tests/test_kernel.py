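"""WFA primitives: extend, compute, fusion, full base-case aligner."""

import numpy as np
import pytest

from pimwave import (AccessLedger, KernelStats, Penalties, SequencePair,
                     check_alignment, compute_wavefront, extend_wavefront,
                     fused_compute_extend, nw_align, wfa_align)
from pimwave.core import Wavefront
from pimwave.kernel import initial_wavefront
from tests.conftest import random_pair

UNIT = Penalties()


def make_wavefront(score, offsets_by_k):
    ks = sorted(offsets_by_k)
    lo, hi = ks[0], ks[-1]
    offsets = np.full(hi - lo + 1, -(2**28), dtype=np.int32)
    for k, off in offsets_by_k.items():
        offsets[k - lo] = off
    return Wavefront(score, lo, hi, offsets, offsets.copy())


class TestExtend:
    def test_full_length_lcp_of_identical_strings(self):
        pair = SequencePair(b"AAAA", b"AAAA")
        wf = extend_wavefront(make_wavefront(0, {0: 0}), pair)
        assert wf.offset(0) == 4

    def test_immediate_mismatch_does_not_advance(self):
        pair = SequencePair(b"TAAA", b"AAAA")
        wf = extend_wavefront(make_wavefront(0, {0: 0}), pair)
        assert wf.offset(0) == 0

    def test_backward_extends_common_suffix(self):
        pair = SequencePair(b"TTAC", b"GGAC")
        wf = extend_wavefront(make_wavefront(0, {0: 0}), pair, "backward")
        assert wf.offset(0) == 2  # common suffix "AC"

    def test_matches_naive_per_character_scan(self, rng):
        for _ in range(40):
            pair = random_pair(rng, max_len=60, max_error=0.5)
            n, m = pair.n, pair.m
            offsets = {}
            for k in range(-min(n, 4), min(m, 4) + 1):
                base = rng.randint(0, min(m, m - k) if k < 0 else m)
                off = min(max(base, k if k > 0 else 0), m)
                if 0 <= off - k <= n:
                    offsets[k] = off
            if not offsets:
                continue
            wf = extend_wavefront(make_wavefront(0, offsets), pair)
            for k, off in offsets.items():
                expected = off
                while (expected < m and expected - k < n
                       and pair.query[expected - k] == pair.reference[expected]):
                    expected += 1
                assert wf.offset(k) == expected

    def test_no_offset_decreases(self, rng):
        for _ in range(20):
            pair = random_pair(rng, max_len=50)
            wf0 = make_wavefront(0, {0: 0})
            wf = extend_wavefront(wf0, pair)
            assert wf.offset(0) >= 0


class TestCompute:
    def test_range_grows_by_one_on_each_side(self):
        wf = compute_wavefront(make_wavefront(0, {0: 0}), UNIT)
        assert (wf.lo, wf.hi) == (-1, 1)
        assert wf.offset(-1) == 0   # insertion: offset unchanged
        assert wf.offset(0) == 1    # mismatch: offset + 1
        assert wf.offset(1) == 1    # deletion: offset + 1

    def test_single_substitution_terminates_at_score_one(self):
        pair = SequencePair(b"A", b"G")
        alignment = wfa_align(pair, UNIT)
        assert (alignment.score, alignment.cigar) == (1, (("X", 1),))

    def test_first_covering_score_equals_oracle(self, rng):
        for _ in range(30):
            pair = random_pair(rng, max_len=48)
            assert wfa_align(pair, UNIT).score == nw_align(pair, UNIT).score

    def test_requires_unit_penalties(self):
        with pytest.raises(ValueError):
            compute_wavefront(make_wavefront(0, {0: 0}), Penalties(2, 1, 1))


class TestFusion:
    def test_equals_unfused_two_step_composition(self, rng):
        for _ in range(100):
            pair = random_pair(rng, max_len=40, max_error=0.5)
            prev = extend_wavefront(initial_wavefront(pair), pair)
            if prev.offset(pair.m - pair.n) == pair.m:
                continue  # already terminal at score 0; no next wavefront
            fused = fused_compute_extend(prev, pair, UNIT)
            unfused = extend_wavefront(compute_wavefront(prev, UNIT, pair),
                                       pair)
            assert (fused.lo, fused.hi) == (unfused.lo, unfused.hi)
            assert (fused.offsets == unfused.offsets).all()

    def test_ledger_charges_three_accesses_per_element(self):
        pair = SequencePair(b"ACGTACGT", b"ACGAACGA")
        ledger = AccessLedger()
        alignment = wfa_align(pair, UNIT, ledger=ledger, fused=True)
        assert alignment.status == "complete"
        assert ledger.bulk_accesses == 3 * ledger.elements_computed
        assert ledger.bulk_reads == 2 * ledger.elements_computed
        assert ledger.bulk_writes == ledger.elements_computed

    def test_fused_and_unfused_alignments_identical(self, rng):
        for _ in range(25):
            pair = random_pair(rng, max_len=64)
            assert wfa_align(pair, UNIT, fused=True) == \
                wfa_align(pair, UNIT, fused=False)


class TestWfaAlign:
    def test_identity_long(self):
        pair = SequencePair(b"G" * 150, b"G" * 150)
        alignment = wfa_align(pair, UNIT, score_cap=1000)
        assert (alignment.score, alignment.cigar) == (0, (("M", 150),))

    def test_empty_sequences(self):
        assert wfa_align(SequencePair(b"", b""), UNIT).cigar == ()
        assert wfa_align(SequencePair(b"", b"AAA"), UNIT).cigar == (("D", 3),)
        assert wfa_align(SequencePair(b"AAA", b""), UNIT).cigar == (("I", 3),)

    def test_score_cap_interrupts(self):
        pair = SequencePair(b"A" * 12, b"C" * 12)  # true score 12
        alignment = wfa_align(pair, UNIT, score_cap=5)
        assert alignment.status == "interrupted"
        assert alignment.cigar == ()

    def test_random_pairs_equal_oracle_and_replay(self, rng):
        for trial in range(60):
            pair = random_pair(rng, max_len=256)
            pen = (UNIT if trial % 3 else
                   Penalties(rng.randint(1, 3), rng.randint(1, 3),
                             rng.randint(1, 3)))
            alignment = wfa_align(pair, pen)
            assert alignment.score == nw_align(pair, pen).score
            check_alignment(pair, alignment, pen)

    def test_offsets_monotone_in_score_in_the_interior(self, rng):
        """Furthest-reaching offsets per diagonal never regress as score
        grows, wherever the diagonal has room left (at the matrix boundary
        a clipped mismatch candidate may leave a smaller valid source)."""
        from pimwave.kernel import _compute_next, _extend_inplace
        for _ in range(10):
            pair = random_pair(rng, max_len=60)
            n, m = pair.n, pair.m
            qa, ra = pair.query_array(), pair.reference_array()
            wf = extend_wavefront(initial_wavefront(pair), pair)
            wfs = {0: wf}
            for s in range(1, 25):
                nxt = _compute_next(wfs, s, n, m, UNIT)
                if nxt is None:
                    break
                _extend_inplace(nxt.offsets, nxt.lo, qa, ra)
                prev = wfs[s - 1]
                for k in range(nxt.lo, nxt.hi + 1):
                    before, after = prev.offset(k), nxt.offset(k)
                    interior = (before is not None and before < m
                                and before - k < n)
                    if interior and after is not None:
                        assert after >= before
                wfs[s] = nxt

    def test_retained_memory_grows_quadratically(self):
        """Base-case mode keeps all wavefronts: elements ~ (s+1)^2."""
        stats = KernelStats()
        ref = ("ACGT" * 300)
        query = "".join(c if i % 30 else "T" for i, c in enumerate(ref))
        pair = SequencePair(query.encode(), ref.encode())
        alignment = wfa_align(pair, UNIT, stats=stats)
        s = alignment.score
        assert stats.peak_retained_elements <= (s + 1) ** 2
        assert stats.peak_retained_elements > s ** 2 / 2
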