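"""Semi-global alignment distances: error landscapes and canonical starts.

The central object is the *error landscape* of a read against one strand of a
reference: for every reference end position ``i`` it holds ``delta[i]``, the
distance of the best alignment of the *whole* read that ends exactly there,
and ``canonical_start[i]``, the leftmost start position among minimal-distance
alignments ending at ``i``.

Alignment conventions (shared by every downstream module):

* the alignment is semi-global — the full read against some substring of the
  reference, lying entirely inside the reference (no overhang);
* the first and the last base of the read must align to reference characters,
  never to gaps (gap columns at the read ends only produce redundant,
  never-better alignments);
* ``end`` is the 0-based reference position aligned to the last read base,
  ``start`` the position aligned to the first read base;
* under Hamming distance an alignment is ungapped, so an end position fixes
  the diagonal and the start is always ``end - m + 1``;
* ``N`` in read or reference mismatches everything, including another ``N``.

Distances never exceed the read length ``m`` wherever any anchored alignment
exists, so ``m + 1`` serves as the integer infinity sentinel.

The edit-distance kernel runs the dynamic program row-by-row over the read
(``m`` rows), vectorising each row over all reference columns with numpy; the
within-row horizontal dependency (reference gaps) is resolved with a
prefix-minimum scan. Cost and leftmost start are packed into one int64 per
cell so that a single numeric minimum implements the lexicographic
(cost, start) order.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .seqs import Sequence

__all__ = [
    "DistanceModel",
    "ErrorLandscape",
    "NoAlignmentError",
    "landscape",
    "landscape_window",
    "distance_at",
    "canonical_start_at",
    "infinity",
    "reset_touched",
    "touched_positions",
]


class DistanceModel(str, enum.Enum):
    """Distance function for semi-global alignments."""

    HAMMING = "hamming"
    EDIT = "edit"


class NoAlignmentError(ValueError):
    """Raised when a query refers to an end position with no valid alignment."""


def infinity(read_length: int) -> int:
    """The integer sentinel standing for 'no alignment ends here'."""
    return read_length + 1


# --- instrumentation -------------------------------------------------------
# Number of reference positions fed to the kernels since the last reset.
# Used to verify the locality claim of seeded gold-standard construction.
_touched = 0


def reset_touched() -> None:
    global _touched
    _touched = 0


def touched_positions() -> int:
    return _touched


def _count(n: int) -> None:
    global _touched
    _touched += n


@dataclass
class ErrorLandscape:
    """Per-end-position best distances of one read on one strand.

    ``delta`` and ``canonical_start`` are indexed by 0-based reference end
    position and have the reference length. ``delta[i]`` is ``m + 1`` (the
    infinity sentinel) where no anchored alignment ends, in which case
    ``canonical_start[i]`` is ``-1``.
    """

    read_id: str
    contig_id: str
    strand: str  # '+' or '-'
    read_length: int
    delta: np.ndarray
    canonical_start: np.ndarray

    @property
    def inf(self) -> int:
        return infinity(self.read_length)

    def __len__(self) -> int:
        return len(self.delta)


def _mismatch(code: int, ref_codes: np.ndarray) -> np.ndarray:
    """1 where the read base mismatches the reference base (N hits nothing)."""
    if code == 4:
        return np.ones(len(ref_codes), dtype=np.int64)
    return ((ref_codes != code) | (ref_codes == 4)).astype(np.int64)


def _hamming_kernel(read: np.ndarray, ref: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    m, n = len(read), len(ref)
    _count(n)
    inf = infinity(m)
    delta = np.full(n, inf, dtype=np.int64)
    cstart = np.full(n, -1, dtype=np.int64)
    if n >= m:
        acc = np.zeros(n - m + 1, dtype=np.int64)
        for t in range(m):
            acc += _mismatch(int(read[t]), ref[t : t + n - m + 1])
        delta[m - 1 :] = acc
        cstart[m - 1 :] = np.arange(n - m + 1)
    return delta, cstart


def _edit_kernel(read: np.ndarray, ref: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Anchored semi-global edit DP, returning (delta, canonical_start).

    Cells carry ``cost * BIG + start`` so the numeric minimum realises the
    'smallest cost, then leftmost start' rule exactly. Row 0 encodes a free
    start at every column; the transition into row 1 is diagonal-only (the
    first read base may not align to a gap), and the final transition into
    the virtual row m is diagonal-only as well (last base anchored), which is
    applied directly when reading the answer off row m-1.
    """
    m, n = len(read), len(ref)
    _count(n)
    big = n + 2
    inf_enc = (m + 2) * big
    cols = np.arange(n + 1, dtype=np.int64)
    row = cols.copy()  # row 0: cost 0, prospective start == column index
    col_big = cols * big
    for j in range(1, m):
        sub = _mismatch(int(read[j - 1]), ref) * big
        diag = np.empty(n + 1, dtype=np.int64)
        diag[0] = inf_enc
        diag[1:] = row[:-1] + sub
        if j >= 2:
            base = np.minimum(diag, row + big)  # vertical: read base vs gap
        else:
            base = diag  # no gap under the first read base
        # horizontal closure: reference bases skipped inside the alignment
        t = np.minimum.accumulate(base - col_big)
        row = np.minimum(t + col_big, inf_enc)
    # last read base anchored: diagonal from (m-1, e) consuming ref[e]
    sub_last = _mismatch(int(read[m - 1]), ref) * big
    enc = row[:n] + sub_last
    cost = enc // big
    start = enc % big
    inf = infinity(m)
    feasible = cost <= m
    delta = np.where(feasible, cost, inf)
    cstart = np.where(feasible, start, -1)
    return delta, cstart


def _kernel(read: np.ndarray, ref: np.ndarray, model: DistanceModel):
    if model == DistanceModel.HAMMING:
        return _hamming_kernel(read, ref)
    return _edit_kernel(read, ref)


def landscape(
    read: Sequence,
    ref: Sequence,
    model: DistanceModel,
    strand: str = "+",
) -> ErrorLandscape:
    """Full error landscape of ``read`` against ``ref``.

    For the reverse strand, call with the reverse-complemented read and the
    forward reference: end positions then live in forward coordinates, with
    ``end`` the largest reference position covered by the alignment.
    """
    if len(read) < 1:
        raise ValueError("empty read")
    delta, cstart = _kernel(read.codes(), ref.codes(), model)
    return ErrorLandscape(read.id, ref.id, strand, len(read), delta, cstart)


def landscape_window(
    read: Sequence,
    ref: Sequence,
    model: DistanceModel,
    lo: int,
    hi: int,
    k: int,
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Landscape restricted to end positions ``[lo, hi)``.

    Only reference context ``m + k`` to the left of ``lo`` is examined, which
    is enough to make the answers *exact for every value <= k*: an anchored
    alignment of cost <= k spans at most ``m + k`` reference characters.
    Returned ``delta`` values larger than ``k`` may overestimate the true
    distance (they are still lower-bounded by it), so callers must only rely
    on the feasible/infeasible classification at level ``k`` plus the exact
    values and canonical starts of feasible positions.

    Returns ``(delta, cstart, lo)`` with arrays of length ``hi - lo`` indexed
    by ``end - lo``.
    """
    m = len(read)
    lo = max(0, lo)
    hi = min(len(ref), hi)
    if hi <= lo:
        return (
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64),
            lo,
        )
    a = max(0, lo - (m + k))
    sub = ref.codes()[a:hi]
    delta, cstart = _kernel(read.codes(), sub, model)
    off = lo - a
    delta = delta[off:]
    cstart = cstart[off:]
    if a:
        cstart = np.where(cstart >= 0, cstart + a, -1)
    return delta, cstart, lo


def distance_at(read: Sequence, ref: Sequence, model: DistanceModel, end: int) -> int:
    """Best anchored alignment distance ending exactly at ``end``.

    Equals ``landscape(read, ref, model).delta[end]`` but only inspects a
    window of ``2 m`` reference characters (any realisable distance is at most
    ``m``, so that much context is always sufficient).
    """
    if not 0 <= end < len(ref):
        raise ValueError(f"end position {end} outside reference of length {len(ref)}")
    delta, _, lo = landscape_window(read, ref, model, end, end + 1, len(read))
    return int(delta[end - lo])


def canonical_start_at(read: Sequence, ref: Sequence, model: DistanceModel, end: int) -> int:
    """Leftmost start among minimal-distance alignments ending at ``end``."""
    if not 0 <= end < len(ref):
        raise ValueError(f"end position {end} outside reference of length {len(ref)}")
    delta, cstart, lo = landscape_window(read, ref, model, end, end + 1, len(read))
    if delta[end - lo] >= infinity(len(read)):
        raise NoAlignmentError(f"no alignment of read {read.id!r} ends at {end}")
    return int(cstart[end - lo])
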