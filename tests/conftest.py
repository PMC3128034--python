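"""Shared fixtures: seeded RNG and randomized instance construction.

Purely random read/reference pairs almost never admit feasible edit-distance
matches at small k, so the instance generator plants structure: exact or
mutated read occurrences, multiple copies, and short-period tandem repeats
(the regime where match classes actually merge).
"""

from __future__ import annotations

import numpy as np
import pytest

from mapbench.seqs import Sequence

BASES = "ACGT"


def rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def rand_seq(rng: np.random.Generator, n: int, sid: str = "seq") -> Sequence:
    return Sequence(sid, rand_dna(rng, n))


def mutate(rng: np.random.Generator, s: str, n_edits: int) -> str:
    """Apply up to n_edits random substitutions/insertions/deletions."""
    out = list(s)
    for _ in range(n_edits):
        if not out:
            break
        op = rng.integers(0, 3)
        p = int(rng.integers(0, len(out)))
        if op == 0:
            out[p] = BASES[(BASES.index(out[p]) + int(rng.integers(1, 4))) % 4]
        elif op == 1 and len(out) > 1:
            out.pop(p)
        else:
            out.insert(p, BASES[int(rng.integers(0, 4))])
    return "".join(out) or s


def make_instance(rng: np.random.Generator, ref_len: int, read_len: int, k: int):
    """One randomized (read, ref) pair with planted matching structure."""
    kind = ["random", "planted", "multi", "tandem"][int(rng.integers(0, 4))]
    ref = list(rand_dna(rng, ref_len))
    if kind == "random":
        read = rand_dna(rng, read_len)
    elif kind == "tandem":
        u = int(rng.integers(1, max(2, read_len // 2) + 1))
        unit = rand_dna(rng, u)
        read = (unit * (read_len // u + 1))[:read_len]
        copies = int(rng.integers(2, 6))
        span = min(len(unit) * copies * 2, ref_len)
        start = int(rng.integers(0, ref_len - span + 1))
        block = (unit * (span // u + 1))[:span]
        ref[start : start + span] = list(block)
    else:
        pos = int(rng.integers(0, ref_len - read_len + 1))
        read = "".join(ref[pos : pos + read_len])
        if kind == "multi":
            for _ in range(int(rng.integers(1, 4))):
                copy = mutate(rng, read, int(rng.integers(0, k + 1)))
                p = int(rng.integers(0, max(1, ref_len - len(copy))))
                ref[p : p + len(copy)] = list(copy)
            ref = ref[:ref_len]
        read = mutate(rng, read, int(rng.integers(0, k + 1)))
        if not (1 <= len(read)):
            read = rand_dna(rng, read_len)
    return Sequence("read", read), Sequence("ref", "".join(ref))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
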