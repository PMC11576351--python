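"""Shared domain types and CIGAR algebra.

Coordinate convention used throughout the package: 0-based, half-open
intervals. A diagonal is ``k = r - q`` where ``q`` indexes the query and
``r`` the reference; the offset stored for a diagonal is the *reference*
offset ``r`` of the furthest-reaching cell. CIGAR semantics follow SAM
extended CIGAR: ``M`` (match) and ``X`` (mismatch) consume one base of both
sequences, ``I`` consumes query only, ``D`` consumes reference only. With
match cost zero, the alignment score is
``mismatch * #X + insertion * #I + deletion * #D``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

__all__ = [
    "SENTINEL",
    "SequencePair",
    "Penalties",
    "Wavefront",
    "Alignment",
    "Cigar",
    "FormatError",
    "SizeError",
    "AssemblyError",
    "CapacityError",
    "AddressError",
    "VerificationError",
    "parse_cigar",
    "render_cigar",
    "cigar_score",
    "cigar_concat",
    "cigar_query_length",
    "cigar_reference_length",
    "check_alignment",
]

# Sentinel offset for unreachable diagonals: ordered below every valid
# reference offset (valid offsets are >= 0) and far from int32 overflow
# when incremented during the wavefront recurrence.
SENTINEL: int = int(np.iinfo(np.int32).min) // 4

#: A CIGAR is a tuple of (op, run length) pairs with op in {M, X, I, D}.
Cigar = Tuple[Tuple[str, int], ...]

_CIGAR_OPS = frozenset("MXID")
_CIGAR_RE = re.compile(r"(\d+)([A-Za-z=])")


class FormatError(ValueError):
    """Malformed input: bad CIGAR op, bad pair file, bad record."""


class SizeError(ValueError):
    """A guard on problem size was exceeded."""


class AssemblyError(ValueError):
    """Partial alignment outputs do not tile the pair."""


class CapacityError(RuntimeError):
    """Modeled bulk-tier capacity exceeded."""


class AddressError(IndexError):
    """Modeled bulk-tier address outside the padded store."""


class VerificationError(RuntimeError):
    """An alignment failed re-verification against the oracle."""


@dataclass(frozen=True)
class SequencePair:
    """A query/reference pair. ``n = len(query)``, ``m = len(reference)``."""

    query: bytes
    reference: bytes
    pair_id: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.query, str):
            object.__setattr__(self, "query", self.query.encode("ascii"))
        if isinstance(self.reference, str):
            object.__setattr__(self, "reference", self.reference.encode("ascii"))
        if b"\n" in self.query or b"\n" in self.reference:
            raise FormatError("sequences must not contain newline bytes")
        if self.pair_id < 0:
            raise ValueError("pair_id must be non-negative")

    @property
    def n(self) -> int:
        return len(self.query)

    @property
    def m(self) -> int:
        return len(self.reference)

    def query_array(self) -> np.ndarray:
        return np.frombuffer(self.query, dtype=np.uint8)

    def reference_array(self) -> np.ndarray:
        return np.frombuffer(self.reference, dtype=np.uint8)


@dataclass(frozen=True)
class Penalties:
    """Match-cost-zero edit penalties. Unit penalties give edit distance."""

    mismatch: int = 1
    insertion: int = 1
    deletion: int = 1

    def __post_init__(self) -> None:
        if min(self.mismatch, self.insertion, self.deletion) < 1:
            raise ValueError("penalties must be positive integers")

    @property
    def max_penalty(self) -> int:
        return max(self.mismatch, self.insertion, self.deletion)

    @property
    def is_unit(self) -> bool:
        return self.mismatch == self.insertion == self.deletion == 1


UNIT = Penalties()


@dataclass
class Wavefront:
    """Furthest-reaching reference offsets per diagonal at one score.

    ``offsets[k - lo]`` is the furthest-reaching reference offset on
    diagonal ``k`` (``SENTINEL`` where the diagonal is unreachable).
    ``base_offsets`` retains the pre-extension offsets produced by the
    compute step; the traceback needs them to tell free matches apart
    from the edit that entered the diagonal.
    """

    score: int
    lo: int
    hi: int
    offsets: np.ndarray
    base_offsets: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError("empty diagonal range")
        if len(self.offsets) != self.hi - self.lo + 1:
            raise ValueError("offsets length does not match diagonal range")

    @property
    def width(self) -> int:
        return self.hi - self.lo + 1

    def diagonals(self) -> np.ndarray:
        return np.arange(self.lo, self.hi + 1, dtype=np.int64)

    def offset(self, k: int) -> int | None:
        """Offset on diagonal ``k``, or None if unreachable/out of range."""
        if not self.lo <= k <= self.hi:
            return None
        v = int(self.offsets[k - self.lo])
        return None if v < 0 else v

    def base_offset(self, k: int) -> int | None:
        if self.base_offsets is None or not self.lo <= k <= self.hi:
            return None
        v = int(self.base_offsets[k - self.lo])
        return None if v < 0 else v

    def valid_mask(self) -> np.ndarray:
        return self.offsets >= 0

    def copy(self) -> "Wavefront":
        return Wavefront(
            self.score,
            self.lo,
            self.hi,
            self.offsets.copy(),
            None if self.base_offsets is None else self.base_offsets.copy(),
        )


@dataclass(frozen=True)
class Alignment:
    """Score plus CIGAR transcript; ``interrupted`` means a score cap hit."""

    score: int
    cigar: Cigar
    status: str = "complete"

    def __post_init__(self) -> None:
        if self.status not in ("complete", "interrupted"):
            raise ValueError(f"bad status {self.status!r}")

    @property
    def cigar_string(self) -> str:
        return render_cigar(self.cigar)


def parse_cigar(text: str) -> Cigar:
    """Parse a SAM-style extended CIGAR string (``=`` accepted as ``M``)."""
    if text == "" or text == "*":
        return ()
    out = []
    pos = 0
    for match in _CIGAR_RE.finditer(text):
        if match.start() != pos:
            raise FormatError(f"malformed CIGAR near {text[pos:pos + 8]!r}")
        length = int(match.group(1))
        op = match.group(2)
        if op == "=":
            op = "M"
        if op not in _CIGAR_OPS:
            raise FormatError(f"unknown CIGAR op {op!r}")
        if length <= 0:
            raise FormatError("CIGAR run lengths must be positive")
        out.append((op, length))
        pos = match.end()
    if pos != len(text):
        raise FormatError(f"malformed CIGAR near {text[pos:pos + 8]!r}")
    return tuple(out)


def render_cigar(cigar: Cigar, match_symbol: str = "M") -> str:
    """Render as a string; pass ``match_symbol('=')`` for strict SAM-extended."""
    if match_symbol not in ("M", "="):
        raise ValueError("match_symbol must be 'M' or '='")
    return "".join(
        f"{length}{match_symbol if op == 'M' else op}" for op, length in cigar
    )


def _as_cigar(value) -> Cigar:
    if isinstance(value, str):
        return parse_cigar(value)
    return tuple((op, int(length)) for op, length in value)


def cigar_score(cigar, penalties: Penalties = UNIT) -> int:
    """Penalty-weighted cost of a transcript (matches are free)."""
    cost = {"M": 0, "X": penalties.mismatch,
            "I": penalties.insertion, "D": penalties.deletion}
    total = 0
    for op, length in _as_cigar(cigar):
        if op not in _CIGAR_OPS:
            raise FormatError(f"unknown CIGAR op {op!r}")
        total += cost[op] * length
    return total


def cigar_concat(parts: Sequence) -> Cigar:
    """Concatenate transcripts, merging adjacent runs of the same op."""
    if not parts:
        raise ValueError("parts must be nonempty")
    out: list[list] = []
    for part in parts:
        for op, length in _as_cigar(part):
            if out and out[-1][0] == op:
                out[-1][1] += length
            else:
                out.append([op, length])
    return tuple((op, length) for op, length in out)


def cigar_query_length(cigar) -> int:
    return sum(length for op, length in _as_cigar(cigar) if op in "MXI")


def cigar_reference_length(cigar) -> int:
    return sum(length for op, length in _as_cigar(cigar) if op in "MXD")


def check_alignment(pair: SequencePair, alignment: Alignment,
                    penalties: Penalties = UNIT) -> None:
    """Replay the CIGAR against the pair; raise VerificationError on any defect.

    Checks consumption totals, per-base match/mismatch agreement, and that
    the recorded score equals the penalty-weighted transcript cost.
    """
    if alignment.status != "complete":
        raise VerificationError("cannot replay an interrupted alignment")
    q, r = pair.query, pair.reference
    i = j = 0
    for op, length in alignment.cigar:
        if op in ("M", "X"):
            qs, rs = q[i:i + length], r[j:j + length]
            if len(qs) != length or len(rs) != length:
                raise VerificationError("CIGAR overruns the sequences")
            if op == "M" and qs != rs:
                raise VerificationError("M run covers mismatching bases")
            if op == "X" and any(a == b for a, b in zip(qs, rs)):
                raise VerificationError("X run covers matching bases")
            i += length
            j += length
        elif op == "I":
            i += length
        elif op == "D":
            j += length
        else:
            raise FormatError(f"unknown CIGAR op {op!r}")
    if i != pair.n or j != pair.m:
        raise VerificationError(
            f"CIGAR consumes ({i},{j}) of ({pair.n},{pair.m})")
    expected = cigar_score(alignment.cigar, penalties)
    if alignment.score != expected:
        raise VerificationError(
            f"score {alignment.score} != transcript cost {expected}")
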