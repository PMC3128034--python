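"""Score read-mapper SAM output against a gold standard.

Categories:

* ``all`` — every equivalence class at the evaluation budget ``c`` counts;
  a read with ``n`` classes contributes ``1/n`` point per class found.
* ``all-best`` — only classes whose depth (``min_k``) equals the read's best
  achievable distance count, scored the same way.
* ``any-best`` — one point if at least one best class was found.

The headline metric, *normalized found intervals*, is ``100 x (sum of
points) / (number of reads with at least one relevant class)``. A hit
requires matching read, contig and strand, an end position inside the
interval span, and — because class spans may absorb infeasible separating
positions — a recomputed distance at that end position within the budget.
Reported alignments and NM tags are never trusted; the distance is always
recomputed from the sequences.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence as PySequence, Tuple, Union

import numpy as np
import pysam

from .alignment import DistanceModel, distance_at
from .equivalence import GoldInterval
from .goldstandard import GoldStandard, rate_to_k
from .seqs import Sequence, as_dict, reverse_complement

__all__ = [
    "MapperRecord",
    "ParsedSam",
    "EvalResult",
    "parse_sam",
    "cap_matches",
    "evaluate",
    "report_missed",
]

CATEGORIES = ("all", "all-best", "any-best")


@dataclass(frozen=True)
class MapperRecord:
    """One mapped SAM alignment in benchmark conventions.

    ``pos``/``end`` are 0-based leftmost/rightmost reference positions of the
    alignment; ``end`` is derived from the CIGAR (reference-consuming
    operations only). Reverse-flag records already match the reverse-strand
    convention: the reverse-complemented read aligned left-to-right on the
    forward reference, identified by its rightmost position.
    """

    read_id: str
    contig_id: str
    strand: str
    pos: int
    end: int
    cigar: str
    reported_distance: Optional[int] = None
    line_no: int = -1


@dataclass
class ParsedSam:
    records: List[MapperRecord]
    invalid: List[Tuple[MapperRecord, str]] = field(default_factory=list)


def parse_sam(
    path: Union[str, Path],
    reads: Union[Dict[str, Sequence], PySequence[Sequence]],
    strict_contigs: Optional[Dict[str, Sequence]] = None,
) -> ParsedSam:
    """Parse mapped records from a SAM file.

    Unmapped records are dropped. Records with soft/hard clipping or unknown
    read names are routed to ``invalid`` with a reason — the benchmark is
    defined for full-length (semi-global) alignments only. With
    ``strict_contigs`` given, a record naming an unknown contig is a hard
    error (used for seed input, where it indicates mismatched files).
    """
    read_map = reads if isinstance(reads, dict) else as_dict(reads)
    out = ParsedSam([])
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for line_no, aln in enumerate(sam.fetch(until_eof=True), start=1):
            if aln.is_unmapped:
                continue
            if strict_contigs is not None and aln.reference_name not in strict_contigs:
                raise ValueError(
                    f"{path}: record {line_no}: unknown contig {aln.reference_name!r}"
                )
            rec = MapperRecord(
                read_id=aln.query_name,
                contig_id=aln.reference_name,
                strand="-" if aln.is_reverse else "+",
                pos=aln.reference_start,
                end=aln.reference_end - 1,
                cigar=aln.cigarstring or "",
                reported_distance=(
                    int(aln.get_tag("NM")) if aln.has_tag("NM") else None
                ),
                line_no=line_no,
            )
            if aln.query_name not in read_map:
                out.invalid.append((rec, "unknown read"))
            elif any(op in (4, 5) for op, _ in (aln.cigartuples or [])):
                out.invalid.append((rec, "clipped"))
            else:
                out.records.append(rec)
    return out


class _DistanceCache:
    """Memoised recomputation of delta at reported end positions."""

    def __init__(
        self,
        reads: Dict[str, Sequence],
        refs: Dict[str, Sequence],
        model: DistanceModel,
    ) -> None:
        self.reads = reads
        self.refs = refs
        self.model = model
        self._rc: Dict[str, Sequence] = {}
        self._memo: Dict[Tuple[str, str, str, int], int] = {}

    def query(self, read_id: str, strand: str) -> Sequence:
        if strand == "+":
            return self.reads[read_id]
        if read_id not in self._rc:
            self._rc[read_id] = reverse_complement(self.reads[read_id])
        return self._rc[read_id]

    def distance(self, rec: MapperRecord) -> int:
        key = (rec.read_id, rec.contig_id, rec.strand, rec.end)
        if key not in self._memo:
            self._memo[key] = distance_at(
                self.query(rec.read_id, rec.strand),
                self.refs[rec.contig_id],
                self.model,
                rec.end,
            )
        return self._memo[key]


def cap_matches(
    records: PySequence[MapperRecord],
    per_read_limit: int,
    model: DistanceModel,
    refs: Union[Dict[str, Sequence], PySequence[Sequence]],
    reads: Union[Dict[str, Sequence], PySequence[Sequence]],
    rng_seed: int,
) -> List[MapperRecord]:
    """Keep at most ``per_read_limit`` records per read, best distance first.

    Distances are recomputed; ties are broken by a seeded RNG so the
    selection is deterministic for a fixed seed. Mirrors the post-processing
    applied to mappers whose output cannot be limited natively.
    """
    if per_read_limit < 1:
        raise ValueError("per-read limit must be >= 1")
    refs = refs if isinstance(refs, dict) else as_dict(refs)
    reads = reads if isinstance(reads, dict) else as_dict(reads)
    cache = _DistanceCache(reads, refs, model)
    rng = np.random.default_rng(rng_seed)
    by_read: Dict[str, List[Tuple[int, float, int, MapperRecord]]] = {}
    for i, rec in enumerate(records):
        d = cache.distance(rec)
        by_read.setdefault(rec.read_id, []).append((d, float(rng.random()), i, rec))
    kept: List[MapperRecord] = []
    for read_id in sorted(by_read):
        ranked = sorted(by_read[read_id], key=lambda t: (t[0], t[1]))
        kept.extend(rec for _, _, _, rec in ranked[:per_read_limit])
    return sorted(kept, key=lambda r: r.line_no)


@dataclass
class EvalResult:
    category: str
    rate: float
    points: float
    n_reads_scored: int
    normalized_found_intervals: float
    missed: List[GoldInterval]
    unexpected: List[MapperRecord]
    invalid: List[Tuple[MapperRecord, str]]
    absorbed: List[MapperRecord] = field(default_factory=list)
    per_read_points: Dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "category": self.category,
            "rate": self.rate,
            "points": self.points,
            "n_reads_scored": self.n_reads_scored,
            "normalized_found_intervals": self.normalized_found_intervals,
            "n_missed": len(self.missed),
            "n_unexpected": len(self.unexpected),
            "n_invalid": len(self.invalid),
            "n_absorbed": len(self.absorbed),
        }

    def write_json(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def evaluate(
    gs: GoldStandard,
    records: Union[ParsedSam, PySequence[MapperRecord]],
    category: str,
    rate: float,
    reads: Union[Dict[str, Sequence], PySequence[Sequence]],
    refs: Union[Dict[str, Sequence], PySequence[Sequence]],
) -> EvalResult:
    """Score mapper records against the gold standard at error rate ``rate``."""
    category = category.replace("_", "-")
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}; expected one of {CATEGORIES}")
    if gs.rate_mode and rate > gs.max_error_rate:
        raise ValueError(
            f"evaluation rate {rate} exceeds gold-standard rate {gs.max_error_rate}: "
            "the gold standard is too shallow"
        )
    invalid: List[Tuple[MapperRecord, str]] = []
    if isinstance(records, ParsedSam):
        invalid = list(records.invalid)
        records = records.records
    reads = reads if isinstance(reads, dict) else as_dict(reads)
    refs = refs if isinstance(refs, dict) else as_dict(refs)
    cache = _DistanceCache(reads, refs, gs.model)

    # relevant intervals per read at its own budget c = rate_to_k(rate, m)
    budget: Dict[str, int] = {}
    relevant: Dict[str, List[GoldInterval]] = {}
    for (rid, _, _), ivals in gs.intervals.items():
        if rid not in budget:
            if rid not in reads:
                raise ValueError(f"gold standard read {rid!r} missing from read set")
            budget[rid] = (
                rate_to_k(rate, len(reads[rid])) if gs.rate_mode else int(rate)
            )
        c = budget[rid]
        relevant.setdefault(rid, []).extend(iv for iv in ivals if iv.k == c)
    relevant = {r: sorted(v) for r, v in relevant.items() if v}
    if category != "all":
        for rid, ivals in relevant.items():
            best = min(iv.min_k for iv in ivals)
            relevant[rid] = [iv for iv in ivals if iv.min_k == best]

    # index spans per (read, contig, strand) for binary-search lookup
    index: Dict[Tuple[str, str, str], Tuple[List[int], List[GoldInterval]]] = {}
    for rid, ivals in relevant.items():
        for iv in ivals:
            index.setdefault((rid, iv.contig_id, iv.strand), ([], []))
    for key, (firsts, lst) in index.items():
        rid = key[0]
        for iv in relevant[rid]:
            if (iv.contig_id, iv.strand) == key[1:]:
                lst.append(iv)
        lst.sort(key=lambda iv: iv.first)
        firsts.extend(iv.first for iv in lst)

    hit: Dict[str, set] = {rid: set() for rid in relevant}
    unexpected: List[MapperRecord] = []
    absorbed: List[MapperRecord] = []
    for rec in records:
        if rec.read_id not in reads:
            invalid.append((rec, "unknown read"))
            continue
        c = budget.get(rec.read_id)
        if c is None:
            c = rate_to_k(rate, len(reads[rec.read_id])) if gs.rate_mode else int(rate)
        entry = index.get((rec.read_id, rec.contig_id, rec.strand))
        iv = None
        if entry is not None:
            firsts, lst = entry
            i = bisect_right(firsts, rec.end) - 1
            if i >= 0 and lst[i].first <= rec.end <= lst[i].last:
                iv = lst[i]
        if iv is not None:
            if cache.distance(rec) <= c:
                hit[rec.read_id].add((iv.contig_id, iv.strand, iv.first, iv.last))
            else:
                absorbed.append(rec)  # inside a span, but at a separating position
        else:
            if cache.distance(rec) > c:
                unexpected.append(rec)
            elif category == "all" or rec.read_id not in relevant:
                # feasible position outside every recorded class: only possible
                # against an incomplete (seeded) gold standard
                unexpected.append(rec)
            # in best categories a feasible hit outside the best classes is
            # simply a non-best match: neither a point nor a complaint

    per_read: Dict[str, float] = {}
    for rid, ivals in relevant.items():
        n = len(ivals)
        got = len(hit[rid])
        if category == "any-best":
            per_read[rid] = 1.0 if got else 0.0
        else:
            per_read[rid] = got / n
    points = float(sum(per_read.values()))
    n_scored = len(relevant)
    normalized = 100.0 * points / n_scored if n_scored else 0.0
    missed = sorted(
        iv
        for rid, ivals in relevant.items()
        for iv in ivals
        if (iv.contig_id, iv.strand, iv.first, iv.last) not in hit[rid]
    )
    return EvalResult(
        category=category,
        rate=rate,
        points=points,
        n_reads_scored=n_scored,
        normalized_found_intervals=normalized,
        missed=missed,
        unexpected=unexpected,
        invalid=invalid,
        absorbed=absorbed,
        per_read_points=per_read,
    )


def report_missed(result: EvalResult, path: Union[str, Path]) -> None:
    """Write missed intervals in GSI line syntax, one per line, sorted."""
    with open(path, "w") as fh:
        fh.write(f"# category: {result.category}\n# rate: {result.rate:g}\n")
        for iv in sorted(result.missed):
            fh.write(
                f"{iv.read_id}\t{iv.contig_id}\t{iv.strand}\t{iv.k}\t{iv.min_k}"
                f"\t{iv.first}\t{iv.last}\n"
            )
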