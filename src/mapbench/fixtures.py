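"""Deterministic repeat-structure fixtures.

Read mapping ambiguity is dominated by a handful of reference phenomena:
unique loci, short-period tandem repeats (where near-identical alignments
shingle and must merge into one match class), long-period tandem repeats
(distinct copies that must stay separate classes), near-duplicate segment
pairs, and matches hugging contig borders. Each fixture kind constructs a
small reference/read pair that provably exhibits one phenomenon, together
with a manifest of the interval counts the gold standard must produce.

Construction is seeded and self-checking: random flanks are redrawn until
the manifest expectation holds, so a fixture either comes out correct or
generation fails loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .alignment import DistanceModel
from .equivalence import GoldInterval, intervals_for_read
from .seqs import Sequence

__all__ = ["FixtureSpec", "make_fixture"]

KINDS = (
    "unique_match",
    "short_period_tandem",
    "long_period_tandem",
    "near_duplicate_pair",
    "border_case",
)

_BASES = "ACGT"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one generated test case."""

    kind: str
    rng_seed: int = 0
    model: DistanceModel = DistanceModel.EDIT
    k: int = 0
    ref_length: int = 200
    read_length: int = 20
    period: int = 2
    copies: int = 10
    read_periods: int = 3
    n_mutations: int = 1
    spacer_length: int = 40

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _count_intervals(
    read: Sequence, ref: Sequence, model: DistanceModel, k: int
) -> List[GoldInterval]:
    return [iv for iv in intervals_for_read(read, [ref], model, k) if iv.k == k]


def make_fixture(spec: FixtureSpec) -> Tuple[List[Sequence], List[Sequence], Dict]:
    """Build (reference contigs, reads, manifest) for one fixture spec.

    The manifest records the expected number of gold intervals at the spec's
    ``k`` (total over both strands) plus kind-specific placement facts; the
    expectation is verified during construction and generation retries with
    fresh randomness (still derived from the one seed) until it holds.
    """
    rng = np.random.default_rng(spec.rng_seed)
    for _ in range(50):
        built = _attempt(spec, rng)
        if built is not None:
            return built
    raise ValueError(f"could not realise fixture {spec.kind!r} (contradictory spec?)")


def _attempt(
    spec: FixtureSpec, rng: np.random.Generator
) -> Optional[Tuple[List[Sequence], List[Sequence], Dict]]:
    if spec.kind == "unique_match":
        ref_s = _random_seq(rng, spec.ref_length)
        pos = int(rng.integers(0, spec.ref_length - spec.read_length + 1))
        read_s = ref_s[pos : pos + spec.read_length]
        ref = Sequence("fixture", ref_s)
        read = Sequence("read0", read_s)
        ivals = _count_intervals(read, ref, spec.model, spec.k)
        expected = 1
        if len(ivals) != expected or ivals[0].first != ivals[0].last:
            return None
        manifest = {
            "kind": spec.kind,
            "k": spec.k,
            "expected_intervals": expected,
            "end": pos + spec.read_length - 1,
        }
        return [ref], [read], manifest

    if spec.kind == "short_period_tandem":
        # unit over {A,C} with G-homopolymer flanks: the read and its reverse
        # complement stay far from the flanks at small k, so the only match
        # classes live in the repeat (where they merge)
        if spec.period == 2:
            unit = "AC"
        else:
            unit = "".join("AC"[i] for i in rng.integers(0, 2, spec.period))
            if len(set(unit)) < 2:
                return None
        repeat = unit * spec.copies
        flank = "G" * (4 * spec.read_periods * spec.period + 20)
        ref = Sequence("fixture", flank + repeat + flank)
        flank_l = flank
        read = Sequence("read0", unit * spec.read_periods)
        # merging needs the off-phase ends flooded: a shift that is not a
        # multiple of the period costs an indel plus the forced end mismatch
        k = max(spec.k, 2)
        ivals = _count_intervals(read, ref, spec.model, k)
        if len(ivals) != 1:
            return None
        manifest = {
            "kind": spec.kind,
            "k": k,
            "expected_intervals": 1,
            "repeat_span": [len(flank_l), len(flank_l) + len(repeat) - 1],
        }
        return [ref], [read], manifest

    if spec.kind == "long_period_tandem":
        period = max(spec.period, spec.read_length)
        unit = _random_seq(rng, period)
        ref_s = _random_seq(rng, 30) + unit * spec.copies + _random_seq(rng, 30)
        ref = Sequence("fixture", ref_s)
        read = Sequence("read0", unit[: spec.read_length])
        ivals = _count_intervals(read, ref, spec.model, spec.k)
        if len(ivals) != spec.copies:
            return None
        manifest = {
            "kind": spec.kind,
            "k": spec.k,
            "expected_intervals": spec.copies,
            "period": period,
        }
        return [ref], [read], manifest

    if spec.kind == "near_duplicate_pair":
        seg = _random_seq(rng, spec.read_length)
        copy = list(seg)
        mut_pos = rng.choice(spec.read_length, size=spec.n_mutations, replace=False)
        for p in mut_pos:
            copy[p] = _BASES[(_BASES.index(copy[p]) + int(rng.integers(1, 4))) % 4]
        spacer = _random_seq(rng, spec.spacer_length)
        ref = Sequence(
            "fixture",
            _random_seq(rng, 20) + seg + spacer + "".join(copy) + _random_seq(rng, 20),
        )
        read = Sequence("read0", seg)
        k = max(spec.k, spec.n_mutations)
        ivals = _count_intervals(read, ref, spec.model, k)
        if len(ivals) != 2:
            return None
        manifest = {
            "kind": spec.kind,
            "k": k,
            "expected_intervals": 2,
            "mutations": sorted(int(p) for p in mut_pos),
        }
        return [ref], [read], manifest

    # border_case: exact occurrences flush against both contig ends
    read_s = _random_seq(rng, spec.read_length)
    middle = _random_seq(rng, max(spec.ref_length - 2 * spec.read_length, 10))
    ref = Sequence("fixture", read_s + middle + read_s)
    read = Sequence("read0", read_s)
    ivals = _count_intervals(read, ref, spec.model, spec.k)
    if len(ivals) != 2:
        return None
    ends = sorted(iv.last for iv in ivals)
    if ends != [spec.read_length - 1, len(ref) - 1]:
        return None
    manifest = {
        "kind": spec.kind,
        "k": spec.k,
        "expected_intervals": 2,
        "ends": ends,
    }
    return [ref], [read], manifest
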