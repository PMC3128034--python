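"""Build, annotate and serialize gold standards of match-equivalence intervals.

A gold standard holds, for every read and every error level ``0 <= k <=
k_max(read)``, the intervals of its match-equivalence classes on every contig
and strand. Two build modes exist:

* ``oracle`` — full error landscapes over the whole reference; exact by
  construction but only affordable for small references;
* ``seeded`` — starting from known matches (e.g. the output of a fully
  sensitive mapper, or simulated read origins), each seed's class interval is
  reconstructed from landscapes over a window around the seed that grows
  until no merge partner can lie outside it. With at least one seed per
  class this reproduces the oracle build bit for bit while touching only a
  fraction of the reference.

Error budgets are expressed as rates relative to read length, so read sets of
mixed lengths get per-read ``k`` values: ``k = floor(rate * m / 100)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence as PySequence, Tuple, Union

import numpy as np

from .alignment import DistanceModel, distance_at, infinity, landscape_window
from .equivalence import GoldInterval, intervals_for_read, _merge_spans, _runs
from .seqs import Sequence, as_dict, reverse_complement

__all__ = [
    "GoldStandard",
    "SeedMatch",
    "rate_to_k",
    "build_oracle",
    "extend_interval",
    "build_seeded",
    "annotate_min_k",
    "write_gsi",
    "read_gsi",
]

GSI_MAGIC = "@MAPBENCH-GSI"
GSI_VERSION = 1

Key = Tuple[str, str, str]  # (read_id, contig_id, strand)


def rate_to_k(rate: float, read_length: int) -> int:
    """Error budget for one read: ``floor(rate% of the read length)``.

    The floor is conservative — a rate of 8% on a 36 bp read admits 2 errors,
    never 3.
    """
    if rate < 0:
        raise ValueError("error rate must be non-negative")
    return int(math.floor(rate * read_length / 100.0 + 1e-9))


@dataclass(frozen=True)
class SeedMatch:
    """A known match used to seed interval reconstruction."""

    read_id: str
    contig_id: str
    strand: str
    end: int
    distance: int = -1  # recomputed, never trusted from input


@dataclass
class GoldStandard:
    """All gold intervals of a read set plus build metadata."""

    model: DistanceModel
    max_error_rate: float
    rate_mode: bool = True
    build_mode: str = "oracle"
    intervals: Dict[Key, List[GoldInterval]] = field(default_factory=dict)
    read_lengths: Dict[str, int] = field(default_factory=dict, compare=False)
    invalid_seeds: List[SeedMatch] = field(default_factory=list, compare=False)

    def k_max(self, read_length: int) -> int:
        if self.rate_mode:
            return rate_to_k(self.max_error_rate, read_length)
        return int(self.max_error_rate)

    def add(self, ivals: Iterable[GoldInterval]) -> None:
        for iv in ivals:
            self.intervals.setdefault((iv.read_id, iv.contig_id, iv.strand), []).append(iv)

    def sort(self) -> None:
        for key in self.intervals:
            self.intervals[key] = sorted(set(self.intervals[key]))

    def __iter__(self) -> Iterator[GoldInterval]:
        for key in sorted(self.intervals):
            yield from self.intervals[key]

    def for_read(self, read_id: str, k: int) -> List[GoldInterval]:
        """All intervals of one read at level ``k``, across contigs/strands."""
        out = []
        for (rid, _, _), ivals in self.intervals.items():
            if rid == read_id:
                out.extend(iv for iv in ivals if iv.k == k)
        return sorted(out)


def build_oracle(
    ref_contigs: PySequence[Sequence],
    reads: PySequence[Sequence],
    model: DistanceModel,
    max_error_rate: float,
    rate_mode: bool = True,
) -> GoldStandard:
    """Exact gold standard from full landscapes (small references only)."""
    if not reads:
        raise ValueError("empty read set")
    as_dict(ref_contigs)  # rejects contig id collisions
    as_dict(reads)
    gs = GoldStandard(model, max_error_rate, rate_mode, build_mode="oracle")
    for read in reads:
        gs.read_lengths[read.id] = len(read)
        k_max = gs.k_max(len(read))
        gs.add(intervals_for_read(read, ref_contigs, model, k_max))
    gs.sort()
    return gs


def extend_interval(
    seed: SeedMatch,
    read: Sequence,
    contig: Sequence,
    model: DistanceModel,
    k: int,
) -> Optional[GoldInterval]:
    """Reconstruct the gold interval of ``seed``'s class at level ``k``.

    Works on a window of end positions around the seed and grows it until the
    window provably contains every merge partner of the class: two
    trace-equivalent matches lie within ``m + k - 1`` positions of each
    other (their shared alignment start bounds both), so once the window
    extends ``m + k + 1`` beyond both class bounds and the class stops
    changing, it is complete. Returns ``None`` for an infeasible seed
    (recomputed distance above ``k``); such seeds are reported by the caller,
    not raised.
    """
    query = read if seed.strand == "+" else reverse_complement(read)
    m = len(read)
    n = len(contig)
    margin = m + k + 1
    wlo = max(0, seed.end - margin)
    whi = min(n, seed.end + margin + 1)
    prev_span = None
    while True:
        delta, cstart, lo = landscape_window(query, contig, model, wlo, whi, k)
        if delta[seed.end - lo] > k:
            return None
        runs = _runs(delta, k)
        spans = _merge_spans(delta, cstart, runs, k)
        span = next(
            (s for s in spans if s[0] + lo <= seed.end <= s[1] + lo), None
        )
        assert span is not None  # seed is feasible, so its run exists
        first, last, min_k = span[0] + lo, span[1] + lo, span[2]
        need_lo = max(0, first - margin)
        need_hi = min(n, last + margin + 1)
        if wlo <= need_lo and whi >= need_hi and prev_span == (first, last):
            return GoldInterval(read.id, contig.id, seed.strand, k, first, last, min_k)
        prev_span = (first, last)
        wlo = min(wlo, need_lo)
        whi = max(whi, need_hi)


def build_seeded(
    ref_contigs: PySequence[Sequence],
    reads: PySequence[Sequence],
    seeds: Union[str, Path, PySequence[SeedMatch]],
    model: DistanceModel,
    max_error_rate: float,
    rate_mode: bool = True,
) -> GoldStandard:
    """Gold standard from seed matches (SAM path or ``SeedMatch`` list).

    Every seed is de-duplicated by (read, contig, strand, end) and its
    distance recomputed; a seed at distance ``d`` then seeds its class at
    every level ``d <= k <= k_max(read)``. Completeness of the result is
    exactly the completeness of the seed set: one seed per class reproduces
    the oracle build, a missing class stays missing. Seeds beyond
    ``k_max`` are collected in ``invalid_seeds`` rather than raised.
    """
    if not reads:
        raise ValueError("empty read set")
    refs = as_dict(ref_contigs)
    read_map = as_dict(reads)
    if isinstance(seeds, (str, Path)):
        from .evaluator import parse_sam

        parsed = parse_sam(seeds, read_map, strict_contigs=refs)
        seeds = [
            SeedMatch(r.read_id, r.contig_id, r.strand, r.end) for r in parsed.records
        ]
    gs = GoldStandard(model, max_error_rate, rate_mode, build_mode="seeded")
    for read in reads:
        gs.read_lengths[read.id] = len(read)
    seen = set()
    for seed in seeds:
        dk = (seed.read_id, seed.contig_id, seed.strand, seed.end)
        if dk in seen:
            continue
        seen.add(dk)
        read = read_map[seed.read_id]
        contig = refs[seed.contig_id]
        query = read if seed.strand == "+" else reverse_complement(read)
        d = distance_at(query, contig, model, seed.end)
        k_max = gs.k_max(len(read))
        if d > k_max:
            gs.invalid_seeds.append(replace(seed, distance=d))
            continue
        seed = replace(seed, distance=d)
        for k in range(d, k_max + 1):
            iv = extend_interval(seed, read, contig, model, k)
            assert iv is not None
            gs.add([iv])
    gs.sort()
    return gs


def annotate_min_k(gs: GoldStandard) -> GoldStandard:
    """Set each interval's ``min_k`` from the intervals it contains.

    The smallest ``k`` of any contained interval equals the minimum distance
    attained in the span, provided intervals were built for all levels. The
    builders already record exact minima from the landscapes; this pass keeps
    whichever is smaller, so partially seeded standards are never worsened.
    """
    new = replace(gs, intervals={})
    new.read_lengths = dict(gs.read_lengths)
    for key, ivals in gs.intervals.items():
        out = []
        for iv in ivals:
            contained = min(
                (o.k for o in ivals if o.first >= iv.first and o.last <= iv.last),
                default=iv.k,
            )
            mk = contained if iv.min_k < 0 else min(iv.min_k, contained)
            out.append(replace(iv, min_k=mk))
        new.intervals[key] = sorted(out)
    return new


class GsiFormatError(ValueError):
    """Malformed or version-incompatible gold-standard interval file."""


def write_gsi(gs: GoldStandard, path: Union[str, Path]) -> None:
    """Serialize to the tab-separated gold-standard interval (GSI) format.

    Header: magic+version, distance model, error rate (plus ``@KMODE:absolute``
    when the budget is an absolute ``k`` rather than a rate). Body: one line
    per interval — read, contig, strand, k, min_k, first, last (0-based,
    closed).
    """
    with open(path, "w") as fh:
        fh.write(f"{GSI_MAGIC}\tVERSION:{GSI_VERSION}\n")
        fh.write(f"@MODEL:{gs.model.value}\n")
        fh.write(f"@RATE:{gs.max_error_rate:g}\n")
        if not gs.rate_mode:
            fh.write("@KMODE:absolute\n")
        for iv in gs:
            fh.write(
                f"{iv.read_id}\t{iv.contig_id}\t{iv.strand}\t{iv.k}\t{iv.min_k}"
                f"\t{iv.first}\t{iv.last}\n"
            )


def read_gsi(path: Union[str, Path]) -> GoldStandard:
    """Load a GSI file; inverse of :func:`write_gsi` up to build metadata."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith(f"{GSI_MAGIC}\tVERSION:"):
        raise GsiFormatError(f"{path}: not a GSI file (bad magic line)")
    version = lines[0].split("VERSION:", 1)[1]
    if version != str(GSI_VERSION):
        raise GsiFormatError(f"{path}: unsupported GSI version {version!r}")
    model: Optional[DistanceModel] = None
    rate: Optional[float] = None
    rate_mode = True
    body_start = 1
    for i, line in enumerate(lines[1:], start=2):
        if not line.startswith("@"):
            body_start = i - 1
            break
        body_start = i
        if line.startswith("@MODEL:"):
            model = DistanceModel(line[len("@MODEL:") :])
        elif line.startswith("@RATE:"):
            rate = float(line[len("@RATE:") :])
        elif line == "@KMODE:absolute":
            rate_mode = False
        else:
            raise GsiFormatError(f"{path}:{i}: unknown header line {line!r}")
    if model is None or rate is None:
        raise GsiFormatError(f"{path}: missing @MODEL or @RATE header")
    gs = GoldStandard(model, rate, rate_mode, build_mode="loaded")
    for i, line in enumerate(lines[body_start:], start=body_start + 1):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 7:
            raise GsiFormatError(f"{path}:{i}: expected 7 fields, got {len(parts)}")
        rid, cid, strand, k, min_k, first, last = parts
        try:
            iv = GoldInterval(rid, cid, strand, int(k), int(first), int(last), int(min_k))
        except ValueError as exc:
            raise GsiFormatError(f"{path}:{i}: {exc}") from None
        if strand not in "+-" or iv.first > iv.last:
            raise GsiFormatError(f"{path}:{i}: invalid interval {line!r}")
        gs.add([iv])
    gs.sort()
    return gs
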