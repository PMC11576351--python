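"""Synthetic pair generation and pair-file I/O.

The generator emulates simulated read datasets: a uniform-random
reference of fixed length and a query derived from it by a fixed number
of edits, ``round(length * error_rate)``, placed at distinct uniform
positions. Each edit is a mismatch with probability ``1 -
indel_fraction``, otherwise an insertion or deletion with equal
probability. Everything is reproducible from ``(seed, index)`` so a
dataset is a pure function of its spec.

File formats: the ``.seq`` pair dialect used by wavefront-alignment tools
(alternating ``>query`` / ``<reference`` lines, one pair per two lines)
and interleaved FASTA (query record followed by reference record).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, List, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import Alignment, FormatError, SequencePair, parse_cigar, render_cigar

__all__ = [
    "DatasetSpec",
    "edit_plan",
    "generate_pair",
    "generate_dataset",
    "read_pairs",
    "write_pairs",
    "write_alignments",
    "read_alignments",
]


@dataclass(frozen=True)
class DatasetSpec:
    """Parameters of a synthetic pair dataset.

    ``length_min``/``length_max`` switch on the heterogeneous mode:
    per-pair lengths drawn log-uniformly from [length_min, length_max],
    emulating long-read datasets whose lengths span orders of magnitude.
    """

    num_pairs: int
    length: int = 150
    error_rate: float = 0.05
    indel_fraction: float = 0.2
    alphabet: bytes = b"ACGT"
    seed: int = 0
    length_min: int | None = None
    length_max: int | None = None

    def __post_init__(self) -> None:
        if self.num_pairs < 0:
            raise ValueError("num_pairs must be non-negative")
        if self.length < 1:
            raise ValueError("length must be positive")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if not 0.0 <= self.indel_fraction <= 1.0:
            raise ValueError("indel_fraction must be in [0, 1]")
        if (self.length_min is None) != (self.length_max is None):
            raise ValueError("set both or neither of length_min/length_max")
        if self.length_min is not None and not (
                1 <= self.length_min <= self.length_max):
            raise ValueError("need 1 <= length_min <= length_max")


def _rng_for(spec: DatasetSpec, index: int) -> np.random.Generator:
    return np.random.default_rng([abs(int(spec.seed)) % (2**31), int(index)])


def _pair_length(spec: DatasetSpec, rng: np.random.Generator) -> int:
    if spec.length_min is None:
        return spec.length
    u = rng.uniform(math.log(spec.length_min), math.log(spec.length_max))
    return max(spec.length_min, min(spec.length_max, round(math.exp(u))))


def edit_plan(spec: DatasetSpec, index: int) -> List[Tuple[int, str]]:
    """The (position, kind) edits applied to pair ``index``.

    Exactly ``round(length * error_rate)`` edits (half-up rounding) at
    distinct reference positions; kind is one of ``X``, ``I``
    (insert after the position) or ``D``.
    """
    rng = _rng_for(spec, index)
    length = _pair_length(spec, rng)
    rng_edits = np.random.default_rng(
        [abs(int(spec.seed)) % (2**31), int(index), 1])
    n_edits = int(math.floor(length * spec.error_rate + 0.5))
    n_edits = min(n_edits, length)
    positions = rng_edits.choice(length, size=n_edits, replace=False)
    plan = []
    for pos in sorted(int(p) for p in positions):
        u = rng_edits.random()
        if u >= spec.indel_fraction:
            kind = "X"
        else:
            kind = "I" if rng_edits.random() < 0.5 else "D"
        plan.append((pos, kind))
    return plan


def generate_pair(spec: DatasetSpec, index: int) -> SequencePair:
    """Deterministically generate pair ``index`` of the dataset."""
    rng = _rng_for(spec, index)
    length = _pair_length(spec, rng)
    alphabet = np.frombuffer(spec.alphabet, dtype=np.uint8)
    reference = alphabet[rng.integers(0, len(alphabet), size=length)]
    rng_chars = np.random.default_rng(
        [abs(int(spec.seed)) % (2**31), int(index), 2])
    query = list(reference.tolist())
    # Descending positions keep earlier indices stable under indels.
    for pos, kind in reversed(edit_plan(spec, index)):
        if kind == "X":
            old = query[pos]
            others = [c for c in alphabet.tolist() if c != old]
            query[pos] = others[int(rng_chars.integers(0, len(others)))]
        elif kind == "I":
            query.insert(pos + 1,
                         int(alphabet[int(rng_chars.integers(0, len(alphabet)))]))
        else:
            del query[pos]
    return SequencePair(bytes(query), reference.tobytes(), pair_id=index)


def generate_dataset(spec: DatasetSpec) -> List[SequencePair]:
    return [generate_pair(spec, i) for i in range(spec.num_pairs)]


# -- pair files ----------------------------------------------------------


def read_pairs(path, fmt: str = "seqpair") -> List[SequencePair]:
    """Read pairs from a ``.seq`` pair file or interleaved FASTA."""
    path = Path(path)
    if fmt == "seqpair":
        return list(_read_seqpair(path))
    if fmt == "fasta_interleaved":
        return list(_read_fasta(path))
    raise ValueError(f"unknown pair format {fmt!r}")


def _read_seqpair(path: Path) -> Iterator[SequencePair]:
    with open(path, "rb") as handle:
        lines = handle.read().splitlines()
    if len(lines) % 2:
        raise FormatError(f"{path}: odd line count {len(lines)}")
    for i in range(0, len(lines), 2):
        qline, rline = lines[i], lines[i + 1]
        if not qline.startswith(b">"):
            raise FormatError(
                f"{path}: line {i + 1}: expected '>' query prefix")
        if not rline.startswith(b"<"):
            raise FormatError(
                f"{path}: line {i + 2}: expected '<' reference prefix")
        query, reference = qline[1:], rline[1:]
        if not query or not reference:
            raise FormatError(f"{path}: line {i + 1}: empty sequence")
        yield SequencePair(query, reference, pair_id=i // 2)


def _read_fasta(path: Path) -> Iterator[SequencePair]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 2:
        raise FormatError(f"{path}: odd FASTA record count {len(records)}")
    for i in range(0, len(records), 2):
        yield SequencePair(str(records[i].seq).encode("ascii"),
                           str(records[i + 1].seq).encode("ascii"),
                           pair_id=i // 2)


def write_pairs(path, pairs: Iterable[SequencePair],
                fmt: str = "seqpair") -> None:
    path = Path(path)
    if fmt == "seqpair":
        with open(path, "wb") as handle:
            for pair in pairs:
                handle.write(b">" + pair.query + b"\n")
                handle.write(b"<" + pair.reference + b"\n")
    elif fmt == "fasta_interleaved":
        records = []
        for pair in pairs:
            records.append(SeqRecord(Seq(pair.query.decode("ascii")),
                                     id=f"pair{pair.pair_id}/query",
                                     description=""))
            records.append(SeqRecord(Seq(pair.reference.decode("ascii")),
                                     id=f"pair{pair.pair_id}/reference",
                                     description=""))
        SeqIO.write(records, str(path), "fasta")
    else:
        raise ValueError(f"unknown pair format {fmt!r}")


# -- alignment output ----------------------------------------------------

_TSV_HEADER = "pair_id\tscore\tcigar\tstatus\tpath"


def write_alignments(path, rows: Iterable[Tuple[int, Alignment, str]],
                     fmt: str = "tsv") -> None:
    """Write alignment rows (pair_id, alignment, path) sorted by pair_id."""
    if fmt != "tsv":
        raise ValueError(f"unknown alignment format {fmt!r}")
    rows = sorted(rows, key=lambda row: row[0])
    with open(path, "w", encoding="ascii") as handle:
        handle.write(_TSV_HEADER + "\n")
        for pair_id, alignment, via in rows:
            cigar = render_cigar(alignment.cigar) or "*"
            handle.write(f"{pair_id}\t{alignment.score}\t{cigar}\t"
                         f"{alignment.status}\t{via}\n")


def read_alignments(path) -> List[Tuple[int, Alignment, str]]:
    with open(path, encoding="ascii") as handle:
        lines = handle.read().splitlines()
    if not lines or lines[0] != _TSV_HEADER:
        raise FormatError(f"{path}: line 1: missing alignment header")
    out = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != 5:
            raise FormatError(f"{path}: line {lineno}: expected 5 columns")
        pair_id, score, cigar, status, via = fields
        out.append((int(pair_id),
                    Alignment(score=int(score),
                              cigar=parse_cigar("" if cigar == "*" else cigar),
                              status=status),
                    via))
    return out
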