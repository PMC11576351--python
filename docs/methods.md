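# Methods

This note documents the models, conventions and design choices behind
pimwave, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the tests do and do not demonstrate.

## Alignment model

All aligners compute *global* pairwise alignment under match-cost-zero
edit penalties `{X, I, D}` (each a positive integer; the default
`X=I=D=1` is edit distance). Gap-affine and two-piece gap models, protein
scoring matrices, and heuristic wavefront pruning are out of scope.

Coordinates are 0-based half-open throughout. A diagonal is
`k = r - q` (reference position minus query position) and the stored
wavefront offset is the reference position of the furthest-reaching cell.
The terminal cell is `(k, offset) = (m - n, m)`. CIGAR semantics follow
SAM extended CIGAR: `M` match, `X` mismatch (both consume one base of
each sequence), `I` consumes query only, `D` consumes reference only.
Every alignment the package emits satisfies three replay invariants,
enforced by `check_alignment`: the transcript consumes exactly `(n, m)`
bases, `M`/`X` runs cover only matching/mismatching positions, and the
reported score equals the penalty-weighted transcript cost.

## Wavefront recurrence and traceback

The next wavefront at score `s` takes, per diagonal, the maximum of the
mismatch source (`s - X`, same diagonal, offset + 1), the deletion source
(`s - D`, diagonal `k - 1`, offset + 1) and the insertion source
(`s - I`, diagonal `k + 1`, offset unchanged), discarding per candidate
anything that would leave the DP matrix; extension then advances each
offset by the longest common prefix of the remaining suffixes. Unreachable
diagonals carry a sentinel ordered below every valid offset, so the
maximum is branch-free. Note one consequence of per-candidate bound
clipping: at the matrix boundary a stored offset can be smaller than its
predecessor's (the mismatch candidate fell off the matrix and a shorter
indel source won). This does not affect correctness — the terminal cell is
still reached exactly at the optimal score — and the monotonicity tests
assert non-regression only in the matrix interior, where it holds.

`wfa_align` retains every wavefront together with its *pre-extension*
offsets. Traceback walks from the terminal cell: the pre-extension offset
marks where an edit entered the diagonal, everything above it is free
matches, and the entering edit is identified by exact arithmetic against
the candidate sources, with ties broken mismatch > deletion > insertion
(the DP oracle breaks ties diagonally first as well, but aligners are
compared on score, never on transcript identity — any optimal transcript
is valid).

## Bidirectional search: overlap rule and breakpoint placement

The backward search is the forward kernel run on the reversed sequences;
a backward diagonal `kb` corresponds to forward diagonal `(m - n) - kb`.
The alternation policy advances whichever direction has the lower score,
ties forward. After each advance, the new wavefront is compared against
**every retained wavefront of the opposite direction** (the retained
window is the last `max_penalty + 1` scores, which is also all a future
compute step can reference). This matters for non-unit penalties: the
optimal score's split between the two directions is only
penalty-granular, and comparing newest-against-newest provably misses
meetings (it did, in early exhaustive testing).

Overlap on a shared diagonal holds when `forward_offset + backward_offset
>= m`; the combined score is the plain sum of the two wavefront scores,
with no correction term. The search keeps the best meeting found and
stops once no future pairing can beat it (`best <= sf + sb + 1 -
max_penalty`), which under unit penalties degenerates to stopping at the
first detection. The breakpoint is placed inside the intersection of the
two frontiers' match runs whenever the runs intersect (pre-extension
offsets delimit the runs); such a point provably lies on an optimal path,
since both half-paths pass through it at their frontier scores. If the
runs do not intersect the forward furthest-reaching point is used. This
resolved rule was calibrated empirically, as no operational rule is fixed
a priori: exhaustive enumeration over all pairs of `{A,C}`-strings up to
length 5 under four penalty sets, plus hundreds of random pairs with
random penalties, shows (a) combined score always equals the brute-force
DP optimum and (b) the two side scores equal the exact optima of the
prefix and suffix sub-problems. Property (b) is what lets the driver
trust inherited bounds without re-measuring.

Degenerate inputs (`n = 0` or `m = 0`) bypass the search: the pair is all
indels and `(0, 0)` is trivially on the optimal path.

## Unrolled driver

Recursion is replaced by an explicit segment queue. A segment whose
inherited bound `s` satisfies `(4s + 1)^2 * element_bytes <=
fast_capacity_bytes` is a base case: a full WFA with traceback, allowed to
run to `4s`, fits the fast tier even in the worst case — the 4x factor is
the safety margin that makes the fit unconditional. With the 64 KB / 4
byte defaults this admits bounds up to 31. A score-`s` WFA retains
`(s+1)^2` offsets (wavefront `t` spans `2t + 1` diagonals); this exact
tiling is the element-count formula behind the threshold. Segments with
bound 0, or with an empty side, emit their transcript directly without
invoking any kernel. Children inherit their side's breakpoint score as
bound; balanced alternation guarantees both children of a bound-`s >= 2`
segment have bounds `<= ceil((s+1)/2) < s`, so splitting terminates.
Base-case outputs carry tree-path order indices and are concatenated in
index order — arrival order is irrelevant and no reshuffling happens.

## Two-tier memory model

The model counts *logical* accesses; it simulates no latency, cycles or
real concurrency — counts are the verifiable surface of the memory-
hierarchy claims. Defaults mirror a PIM worker: 64 KB fast scratch, 64 MB
bulk bank, 32-bit wavefront elements, 8-byte-aligned transfers.

* Wavefront traffic is charged per element computed: 3 reads + 2 writes on
  the separate compute/extend path, 2 reads + 1 write on the fused path.
  The fused pass is semantically identical (asserted bitwise in tests);
  only the intermediate write-back disappears. The 5-vs-3 figures are
  per-element touches; block-granularity counters are tracked separately.
* Base cases run with wavefronts resident in the fast tier and charge no
  bulk wavefront traffic at all; the driver measures this as a ledger
  delta around every base-case call rather than assuming it.
* Adaptive transfer sizing returns the smallest power of two at or above
  the current wavefront footprint, starting at 8 bytes, capped by
  `min(2048, fast buffer)`; callers keep the running maximum so logged
  sizes are non-decreasing within one alignment.
* The sequence store pads both ends to the 8-byte alignment so aligned
  forward *and reverse* chunked reads (at most 16 characters per
  transfer) never address outside physical limits, and no reversed copy
  of a sequence is ever materialized. The alignment kernels themselves
  read sequences through numpy views — the store is the modeled transfer
  path, exercised and accounted separately, not an interposition layer on
  the hot loop.
* A wavefront wider than its fast-tier slot (a quarter of capacity, one
  slot per live bidirectional wavefront) is placed in the bulk tier and
  its overflow elements charged.

## Scheduler

Worker slots are deterministic sequential simulations dealt pair ids from
a shared monotone counter; batches are logical, and the event log
interleaves the recovery of batch `i` with the computation of batch
`i + 1` to model host-side overlap. The recovery path is plain
`wfa_align` with no cap and no memory budget. Exactly-once execution,
cap soundness (no worker-path result above the cap) and bit-for-bit
determinism at fixed plan are asserted in tests. Score caps are user
configuration; no default cap is imposed.

## Synthetic data generator

The generator draws a uniform reference over `{A,C,G,T}` and applies
exactly `round(length * error_rate)` edits (half-up rounding) at distinct
uniform positions; each edit is a mismatch with probability
`1 - indel_fraction`, else an insertion or deletion with equal
probability. The default `indel_fraction = 0.2` reflects short-read-like
data where substitutions dominate; it is a spec field, not a constant,
because realistic mixes vary by platform. Everything derives from
`(seed, index)` through independent named RNG streams, so datasets are
byte-reproducible and individual pairs can be regenerated in isolation.

What the generator does *not* emulate: sequencing-quality profiles,
homopolymer-biased indels, clustered errors, chimeric reads, or real
genome repeat structure. Passing the test suite therefore demonstrates
algorithmic correctness and the modeled memory behavior on uniform-error
data, not robustness to every artifact of real sequencing datasets. Real
data enters only through the `.seq`/FASTA readers.

Applied edits can cancel or merge (two adjacent indels, a substitution
absorbed by a repeat) but never inflate the distance, so per-pair optimal
score is bounded by the applied edit count and the mean over many pairs
sits a few percent below it; the distribution tests assert exactly that
band.

## Problem sizes used in the checks

The standing verification suite uses exhaustive enumeration up to length
5, 500 random pairs of lengths 1–256 at 0–30% error for cross-aligner
equivalence, 4000 bp pairs with constructed scores (60 vs 120) for the
memory-scaling ratios, and a single 100,000 bp pair at 5% error for the
scale demonstration — sizes chosen so the whole suite runs in well under
a minute per criterion on one CPU while still separating O(s) from O(s²)
behavior cleanly. The 100 kb pair's score is cross-checked against an
independent edit-distance library (edlib) because the O(nm) oracle guard
(10^8 cells) excludes dense DP at that size.

## Known limitations

* Penalties are per-operation linear; no affine gaps.
* The bidirectional overlap rule is validated empirically (exhaustively at
  small sizes), not by a formal proof covering all penalty combinations.
* The memory model counts accesses; it cannot predict wall-clock behavior
  of any particular hardware.
* Workers are simulated sequentially; the scheduler's contract is
  scheduling semantics, not parallel speedup.
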