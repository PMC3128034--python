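# Methods

## Problem setting

`mapbench` treats read mapping as a formally defined search problem: for a
read *r*, a reference *S*, a distance function δ (Hamming or edit) and a
budget *k*, find the *match equivalence classes* — intervals of alignment end
positions — rather than individual alignments. This sidesteps the two classic
failure modes of mapper comparisons: counting near-identical alignments
(shifted by one gap column) as distinct finds, and counting a read once no
matter how many genuinely distinct loci it matches.

Only full-read (semi-global) alignments count. Two conventions remove
redundant alignments and make classes well defined:

* the first and last read base must align to reference characters, never to
  gaps (a boundary gap column can always be removed without raising the
  distance);
* alignments must lie entirely inside the reference — no overhang at contig
  ends. This is a deliberate simplification: matches that would run off the
  contig are treated as non-existent rather than specially scored.

Every match is identified by its **end position** (0-based, closed; SAM I/O
converts from 1-based). Its **canonical start** is the leftmost start among
minimal-distance alignments with that end. Under Hamming distance the start
is always `end − m + 1` (one diagonal per match); under edit distance the
canonical start is what links alignments that share a trace.

## The error landscape kernel

`alignment.landscape` computes δ(i) and the canonical start for every end
position in one pass. The edit-distance dynamic program runs row-by-row over
the read (m rows), vectorised over all reference columns with numpy:

* each cell carries `cost * BIG + start` in one int64 (`BIG` > reference
  length), so a plain numeric minimum implements the lexicographic
  (smallest cost, then leftmost start) rule with no tie-break ambiguity;
* the within-row dependency (reference bases aligned to gaps) is a
  prefix-minimum scan: subtract `column * BIG`, `np.minimum.accumulate`,
  add it back;
* anchoring is structural: row 0 encodes a free start per column, the
  transition into row 1 and the final transition out of row m−1 are
  diagonal-only.

A feasible anchored alignment never costs more than m (align some window and
substitute everything), so `m + 1` is the integer infinity sentinel and
costs above m are reported as infeasible. `N` bases mismatch everything,
including other `N`s — a conservative choice the input formats force us to
make somehow; it means reads overlapping assembly gaps simply do not match
there.

Correctness is defined by oracles, not by the kernel: the test suite layers
(1) exhaustive enumeration of all anchored alignments (tiny inputs), (2) an
independent plain-Python full DP validated against (1), and (3) the numpy
kernel validated against (2) on randomized instances with planted matches,
repeats and both distance models.

Windowed evaluation (`landscape_window`) recomputes the landscape on a slice
with `m + k` columns of left context. That context bound is exact for every
value ≤ k (an alignment of cost ≤ k spans at most `m + k` reference
characters), so windowed results are guaranteed to agree with the full
landscape on the feasible/infeasible classification and on all feasible
values and canonical starts; values above k may be overestimated and are
never used for anything but the "> k" test.

## Classes: lakes, trace merging, intervals

At budget k, lakes (maximal runs with δ ≤ k) are the neighbour-equivalence
classes. Lakes merge when they contain trace-equivalent matches — feasible
end positions with equal canonical starts — because the infeasible positions
between them are *separating* positions absorbed by the equivalence: any
feasible position bracketed by a trace-equivalent pair joins the pair's
class. `merge_lakes` implements this as a union-find over lakes keyed by
shared canonical starts, followed by a left-to-right sweep that absorbs every
lake falling inside an already-formed class span (shared-start pairs lie at
most `m + k − 1` apart, so spans and their chains close locally). Each final
class is stored as `(k, first, last, min_k)` where `first`/`last` are the
extreme *feasible* positions and `min_k` — the lake depth — is the minimum
δ inside the span. Interior positions with δ > k may exist inside a span;
the evaluator therefore re-checks feasibility of every hit.

Consequences verified as properties: intervals at fixed k partition the
feasible positions; every interval at k nests in exactly one interval at
k + 1; Hamming lakes never merge (distinct diagonals ⇒ distinct starts).

One point where intuition misleads: in a period-2 tandem repeat, end
positions off the repeat phase cost 2 under edit distance (an indel shift
plus the forced mismatch under the anchored last base), not 1. Short-period
tandem classes therefore fuse at k ≥ 2; the fixtures and tests use that
threshold, which the exhaustive oracle confirms.

## Building gold standards

**Oracle mode** computes full landscapes of every read against both strands
of every contig (reverse strand = reverse-complemented read against the
forward contig; all coordinates stay forward, `end` is the rightmost
position covered). It is exact by construction and intended for references
up to a few hundred kb times the read count.

**Seeded mode** starts from known matches — a fully sensitive mapper's
output, or simulated origins — de-duplicated by (read, contig, strand, end),
with distances always recomputed. A seed at distance d seeds its class at
every budget d ≤ k ≤ k_max. `extend_interval` grows a window around the
seed and recomputes classes inside it until the window provably contains
every merge partner: `m + k + 1` beyond both class bounds with the class
unchanged between iterations. Completeness of the output equals completeness
of the seed set; seeds beyond the budget are collected and reported, never
raised. On complete seeds the seeded build is bit-identical to the oracle
build (tested on randomized instances and fixtures), while touching
O(interval + m + k) reference positions per seed (asserted via an
instrumentation counter).

Budgets are error rates relative to read length, `k = ⌊rate·m/100⌋`. The
floor is a deliberate choice: a stated rate never admits more errors than
it promises. Absolute-k budgets are supported in memory (`rate_mode=False`)
for fixture work.

The GSI serialization is three header lines (magic + version, distance
model, rate) plus one 7-column TSV row per interval; loading rejects version
mismatches and reports malformed lines by number.

## Evaluation

Records are read with pysam; unmapped records are dropped, soft/hard-clipped
and unknown-read records are routed to an `invalid` list (the benchmark is
defined for full-read alignment only — projecting clips would silently score
a different problem). Reverse-flag records already match the reverse-strand
convention, and `end` derives from reference-consuming CIGAR operations.

Per read the budget is c = ⌊rate·m/100⌋ and the *relevant* classes are the
gold intervals with k = c; for the best categories, those whose `min_k`
equals the read's minimum. A record hits a class iff it matches read,
contig, strand, falls inside the span (binary search over sorted firsts) and
the recomputed δ at its end is ≤ c. The mapper's own CIGAR/NM are never
trusted — mappers legitimately produce different alignments of the same
match, and the gold standard is defined over δ, not over alignments.
Records inside a span at an infeasible position are logged separately
("absorbed" — a wrong alignment inside a correct region); feasible-nowhere
records are reported as unexpected, the sanity check for gold-standard or
mapper defects.

Normalized found intervals = 100 · Σ points / #reads scored, where a read is
scored if it has at least one relevant class. Reads that cannot match
anywhere at the budget are excluded from the denominator — they carry no
information about the mapper; the alternative (counting them) would reward
mappers only on easy read sets. `cap_matches` mirrors the common
post-processing for mappers without native output limits: keep the best
`limit` records per read by recomputed distance, ties broken by a seeded
RNG, deterministic for a fixed seed.

## Simulator

The simulator provides controllable error structure, not instrument realism.
Haplotypes apply per-base SNPs (default 10⁻³) and small indels (default
10⁻⁴, sizes 1–6) to the reference, keeping a coordinate log. Reads are
sampled uniformly (position and strand, haplotypes weighted by length):

* `illumina` — fixed length (default 36 bp), substitution-only errors with a
  linear 5'→3' ramp (defaults 0.2 % → 1.2 %, mimicking cycle degradation);
* `longread` — normal length distribution (default 400 ± 40), per-base
  insertion/deletion errors (default 1 %) plus constant substitutions
  (0.5 %), loosely shaped after pyrosequencing error profiles.

Base qualities are the deterministic Phred transform of the per-base error
probability. Origins are projected through the variant log (indel borders
resolve to the nearest reference base actually consumed; reads sample fully
inside the haplotype) and written as a SAM whose POS/CIGAR encode the origin
alignment against the reference — read-vs-haplotype edits composed with
haplotype-vs-reference variants. Origin alignments are trimmed to start and
end on template bases, honouring the anchoring convention.

What passing simulator-based tests do *not* show: robustness to real-data
artefacts — coverage and GC bias, quality-correlated errors, adapter
contamination, structural variation. The simulator's role is to tie the
biological problem to the mathematical one: with sequencing errors capped at
e and variants disabled, every origin end position is feasible at k = e and
therefore falls in a gold interval.

## Sizes and determinism

All randomness flows through explicit `numpy` generators; fixed seeds give
byte-identical FASTQ/SAM outputs and capped-match selections. The test suite
and `scripts/acceptance.py` size their computations for a single CPU:
200 randomized instances (references 50–500 bp, reads 8–40 bp, k ≤ 4) for
the oracle-identity check, and 10 000 simulated 36 bp reads from a 100 kb
random reference for the biological-consistency check — large enough that a
36-mer near-collision is astronomically unlikely in random sequence, which
is what makes the expected any-best value exactly 100.

## Known limitations

* Mate-pair information, base qualities and alignment scores (affine gaps,
  Smith-Waterman) are outside the distance model; color-space reads are
  unsupported.
* Oracle-mode builds scale as O(reads × reference) and are meant for desk-
  scale references; genome-scale gold standards require seeded mode with a
  fully sensitive seed mapper, whose sensitivity is an assumption, not
  checked.
* Multi-read assignment and spliced alignment are out of scope; the
  benchmark evaluates the core (contiguous, per-read) mapping problem.
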