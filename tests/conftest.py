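"""Shared fixtures: reproducible random sequence pairs."""

import random

import pytest

from pimwave import Penalties, SequencePair


def mutate(reference: str, error: float, rng: random.Random) -> str:
    """Derive a query by random mismatches/indels at the given rate."""
    q = list(reference)
    n_edits = int(len(reference) * error)
    for _ in range(n_edits):
        if not q:
            break
        i = rng.randrange(len(q))
        op = rng.choice("XXID")
        if op == "X":
            q[i] = rng.choice("ACGT")
        elif op == "I":
            q.insert(i, rng.choice("ACGT"))
        else:
            del q[i]
    return "".join(q)


def random_pair(rng: random.Random, max_len: int = 256,
                max_error: float = 0.3, pair_id: int = 0) -> SequencePair:
    n = rng.randint(1, max_len)
    reference = "".join(rng.choice("ACGT") for _ in range(n))
    query = mutate(reference, rng.uniform(0.0, max_error), rng)
    return SequencePair(query.encode(), reference.encode(), pair_id=pair_id)


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240901)


@pytest.fixture
def unit() -> Penalties:
    return Penalties()


@pytest.fixture
def pair_factory(rng):
    counter = iter(range(10**6))

    def make(max_len: int = 256, max_error: float = 0.3) -> SequencePair:
        return random_pair(rng, max_len, max_error, pair_id=next(counter))

    return make
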