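"""Independent brute-force oracles used only by the test suite.

Three layers, each validating the next:

1. ``enumerate_best`` — exhaustive enumeration of every anchored semi-global
   alignment (tiny inputs only); the ground truth for distances and leftmost
   minimal starts.
2. ``brute_landscape`` — a plain-Python full DP over (cost, start) pairs;
   validated against the enumeration on tiny inputs, then used as the
   landscape oracle at moderate sizes.
3. ``naive_intervals`` / ``brute_intervals`` — equivalence classes of matches
   by explicit closure of the neighbour / trace / k-trace relations;
   ``naive_intervals`` checks every pair of feasible end positions literally
   (small landscapes), ``brute_intervals`` applies the same relations through
   shared-start spans (larger landscapes) and is validated against the naive
   version.

Nothing here imports the package's alignment or equivalence machinery.
"""

from __future__ import annotations

from collections import defaultdict
from typing import List, Optional, Tuple

BIG = 10**9


def _mm(a: str, b: str) -> int:
    return 1 if (a != b or a == "N" or b == "N") else 0


def enumerate_best(
    read: str, ref: str, end: int, model: str
) -> Tuple[int, int]:
    """(min distance, leftmost minimal start) over ALL anchored alignments
    of ``read`` ending at ``end``; (BIG, -1) if none exists."""
    m = len(read)
    if model == "hamming":
        s = end - m + 1
        if s < 0:
            return BIG, -1
        return sum(_mm(read[t], ref[s + t]) for t in range(m)), s
    if m == 1:  # first and last base coincide: single diagonal at `end`
        return _mm(read[0], ref[end]), end
    best = (BIG, -1)

    def rec(ri: int, gi: int, cost: int, start: int) -> None:
        """read[:ri] aligned, next reference index ``gi``; explore all ops."""
        nonlocal best
        if cost > m or gi > end or (cost, start) >= best:
            return
        if ri == m - 1:  # last base: forced diagonal onto ref[end]
            if gi == end:
                cand = (cost + _mm(read[ri], ref[end]), start)
                if cand < best:
                    best = cand
            # or reach `end` with reference-gap columns first
            rec(ri, gi + 1, cost + 1, start)
            return
        rec(ri + 1, gi + 1, cost + _mm(read[ri], ref[gi]), start)  # diagonal
        rec(ri + 1, gi, cost + 1, start)  # read base on a gap (interior base)
        rec(ri, gi + 1, cost + 1, start)  # reference base on a gap

    for s in range(0, end + 1):
        # first base: forced diagonal onto ref[s]
        rec(1, s + 1, _mm(read[0], ref[s]), s)
    return best


def brute_landscape(read: str, ref: str, model: str) -> Tuple[List[int], List[int]]:
    """Full-DP landscape: per end position the best distance and the leftmost
    start among minimal alignments. Infinity is encoded as ``len(read)+1``."""
    m, n = len(read), len(ref)
    inf = m + 1
    if model == "hamming":
        delta = [inf] * n
        cs = [-1] * n
        for e in range(m - 1, n):
            s = e - m + 1
            delta[e] = sum(_mm(read[t], ref[s + t]) for t in range(m))
            cs[e] = s
        return delta, cs
    # cell (j, i): read prefix j aligned, i reference characters consumed;
    # value = (cost, leftmost start), lexicographic minimum
    prev = [(0, i) for i in range(n + 1)]  # row 0: free start at any column
    for j in range(1, m):
        row: List[Tuple[int, int]] = [(BIG, -1)] * (n + 1)
        for i in range(1, n + 1):
            c, s = prev[i - 1]
            best = (c + _mm(read[j - 1], ref[i - 1]), s)
            if j >= 2:  # read base against a gap, forbidden under the first base
                c, s = prev[i]
                cand = (c + 1, s)
                if cand < best:
                    best = cand
            c, s = row[i - 1]  # reference base against a gap
            cand = (c + 1, s)
            if cand < best:
                best = cand
            row[i] = best
        prev = row
    delta = [inf] * n
    cs = [-1] * n
    for e in range(n):
        c, s = prev[e]
        c += _mm(read[m - 1], ref[e])
        if c <= m:
            delta[e] = c
            cs[e] = s
    return delta, cs


class _UF:
    def __init__(self, items):
        self.p = {i: i for i in items}

    def find(self, x):
        while self.p[x] != x:
            self.p[x] = self.p[self.p[x]]
            x = self.p[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.p[rb] = ra


def _classes_to_intervals(delta, k, uf, feas) -> List[Tuple[int, int, int]]:
    groups = defaultdict(list)
    for i in feas:
        groups[uf.find(i)].append(i)
    out = []
    for members in groups.values():
        first, last = min(members), max(members)
        out.append((first, last, min(delta[first : last + 1])))
    return sorted(out)


def naive_intervals(delta, cstart, k) -> List[Tuple[int, int, int]]:
    """Literal pairwise closure of the three match-equivalence relations.

    O(F^2 * n); use on landscapes of length <= ~120 only.
    """
    n = len(delta)
    feas = [i for i in range(n) if delta[i] <= k]
    if not feas:
        return []
    separating = [
        z
        for z in range(n)
        if delta[z] > k
        and any(delta[x] <= k for x in range(z))
        and any(delta[x] <= k for x in range(z + 1, n))
    ]
    # trace-equivalent feasible pairs, indexed by shared canonical start
    span_of_start = {}
    for i in feas:
        lo, hi = span_of_start.get(cstart[i], (i, i))
        span_of_start[cstart[i]] = (min(lo, i), max(hi, i))
    uf = _UF(feas)
    for ai, a in enumerate(feas):
        for b in feas[ai + 1 :]:
            neighbour = all(delta[x] <= k for x in range(a, b + 1))
            ktrace = neighbour and cstart[a] == cstart[b]
            if not ktrace:
                for alpha, beta in span_of_start.values():
                    if alpha <= a and b <= beta and any(
                        a <= z <= b for z in separating
                    ):
                        ktrace = True
                        break
            if neighbour or ktrace:
                uf.union(a, b)
    return _classes_to_intervals(delta, k, uf, feas)


def brute_intervals(delta, cstart, k) -> List[Tuple[int, int, int]]:
    """Same relations, applied via shared-canonical-start spans.

    Every pair of trace-equivalent feasible matches brackets all feasible
    positions between them (separating positions exist between distinct
    lakes), so flooding each shared-start span is exactly the k-trace
    closure. Validated against ``naive_intervals`` in the suite.
    """
    n = len(delta)
    feas = [i for i in range(n) if delta[i] <= k]
    if not feas:
        return []
    uf = _UF(feas)
    for a, b in zip(feas, feas[1:]):
        if all(delta[x] <= k for x in range(a, b + 1)):
            uf.union(a, b)
    spans = defaultdict(list)
    for i in feas:
        spans[cstart[i]].append(i)
    for members in spans.values():
        lo, hi = min(members), max(members)
        inside = [i for i in feas if lo <= i <= hi]
        for a, b in zip(inside, inside[1:]):
            uf.union(a, b)
    return _classes_to_intervals(delta, k, uf, feas)


def brute_gold(read: str, ref: str, model: str, k: int):
    """(delta-oracle) gold intervals of one read on the forward strand."""
    delta, cs = brute_landscape(read, ref, model)
    return brute_intervals(delta, cs, k)
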