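"""Equivalence classes of matches: lakes and their trace-driven merging.

With the water-level metaphor, fixing an error budget ``k`` floods the error
landscape to level ``k + 0.5``; the *lakes* — maximal runs of end positions
with ``delta <= k`` — are the neighbour-equivalence classes. Two matches in
different lakes are still the same match class when their alignments share a
trace, i.e. have the same canonical start: the infeasible positions between
such a pair are *separating* positions that the relation absorbs, together
with every feasible position in between. The transitive closure of these two
relations partitions the feasible end positions; each class is an interval
``[first, last]`` of (extreme feasible) end positions and becomes one gold
interval ``(k, first, last)``.

Under Hamming distance an end position fixes the diagonal, so canonical
starts are distinct across lakes and merging never fires: every lake is its
own class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence as PySequence, Tuple

import numpy as np

from .alignment import DistanceModel, ErrorLandscape, landscape
from .seqs import Sequence, reverse_complement

__all__ = ["Lake", "GoldInterval", "find_lakes", "merge_lakes", "intervals_for_read"]

STRANDS = ("+", "-")


@dataclass(frozen=True)
class Lake:
    """Maximal run of end positions with ``delta <= k`` (closed interval)."""

    first: int
    last: int


@dataclass(frozen=True, order=True)
class GoldInterval:
    """One equivalence class of matches at error level ``k``.

    ``[first, last]`` are the extreme *feasible* end positions of the class;
    interior positions with ``delta > k`` (absorbed separating positions) may
    exist inside the span. ``min_k`` is the smallest distance attained inside
    the span — the depth of the lake — and drives best-match categories.
    """

    read_id: str
    contig_id: str
    strand: str
    k: int
    first: int
    last: int
    min_k: int = field(default=-1)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _runs(delta: np.ndarray, k: int) -> List[Tuple[int, int]]:
    """Maximal runs of indices with ``delta <= k`` as closed (first, last)."""
    wet = delta <= k
    if not wet.any():
        return []
    d = np.diff(wet.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1))
    if wet[0]:
        starts.insert(0, 0)
    if wet[-1]:
        ends.append(len(wet) - 1)
    return list(zip(starts, ends))


def find_lakes(land: ErrorLandscape, k: int) -> List[Lake]:
    """All lakes at water level ``k + 0.5``: sorted, disjoint, non-adjacent."""
    if k < 0:
        raise ValueError("k must be non-negative")
    return [Lake(a, b) for a, b in _runs(land.delta, k)]


def _merge_spans(
    delta: np.ndarray, cstart: np.ndarray, runs: List[Tuple[int, int]], k: int
) -> List[Tuple[int, int, int]]:
    """Merge lakes into class spans; returns (first, last, min_k) triples.

    Two-phase closure: (1) union lakes that contain trace-equivalent matches,
    i.e. share a canonical start value; (2) a left-to-right sweep absorbing
    every lake that falls inside the span of an already-formed class, since
    any feasible position bracketed by a trace-equivalent pair belongs to
    that pair's class. ``delta``/``cstart`` are indexed like the runs.
    """
    if not runs:
        return []
    uf = _UnionFind(len(runs))
    owner: Dict[int, int] = {}  # canonical start -> first lake seen with it
    for li, (a, b) in enumerate(runs):
        for s in set(cstart[a : b + 1].tolist()):
            if s in owner:
                uf.union(owner[s], li)
            else:
                owner[s] = li
    # span of each union component
    comp_first: Dict[int, int] = {}
    comp_last: Dict[int, int] = {}
    for li, (a, b) in enumerate(runs):
        r = uf.find(li)
        comp_first[r] = min(comp_first.get(r, a), a)
        comp_last[r] = max(comp_last.get(r, b), b)
    # containment sweep: lakes are sorted, so a growing cursor suffices
    merged: List[Tuple[int, int, int]] = []
    cur_first, cur_last = runs[0][0], comp_last[uf.find(0)]
    for li in range(1, len(runs)):
        a, _ = runs[li]
        r = uf.find(li)
        if a <= cur_last:
            cur_last = max(cur_last, comp_last[r])
        else:
            if comp_first[r] <= cur_last:
                # class already started inside the current span: absorb it
                cur_last = max(cur_last, comp_last[r])
            else:
                merged.append((cur_first, cur_last, 0))
                cur_first, cur_last = comp_first[r], comp_last[r]
    merged.append((cur_first, cur_last, 0))
    return [
        (f, l, int(delta[f : l + 1].min())) for f, l, _ in merged
    ]


def merge_lakes(land: ErrorLandscape, lakes: PySequence[Lake], k: int) -> List[GoldInterval]:
    """Collapse lakes into equivalence-class gold intervals at level ``k``."""
    runs = [(lk.first, lk.last) for lk in lakes]
    spans = _merge_spans(land.delta, land.canonical_start, runs, k)
    return [
        GoldInterval(land.read_id, land.contig_id, land.strand, k, f, l, mk)
        for f, l, mk in spans
    ]


def intervals_for_read(
    read: Sequence,
    ref_contigs: PySequence[Sequence],
    model: DistanceModel,
    k_max: int,
) -> List[GoldInterval]:
    """Gold intervals of one read: every contig, both strands, all k <= k_max.

    The reverse strand aligns the reverse-complemented read left-to-right
    against the forward contig, so all coordinates are forward-reference
    positions and ``end`` is the largest position covered.
    """
    if k_max < 0:
        raise ValueError("k_max must be non-negative")
    out: List[GoldInterval] = []
    for contig in ref_contigs:
        for strand in STRANDS:
            query = read if strand == "+" else reverse_complement(read)
            land = landscape(query, contig, model, strand=strand)
            land = replace(land, read_id=read.id)
            for k in range(k_max + 1):
                out.extend(merge_lakes(land, find_lakes(land, k), k))
    return sorted(out)
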