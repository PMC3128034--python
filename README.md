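# mapbench

A formally defined benchmark for DNA read mappers. Given a reference genome,
a read set and an error budget, `mapbench` builds a **gold standard**: the
complete set of *match equivalence classes* — intervals of alignment end
positions — that a fully sensitive mapper should report. Any mapper that
emits SAM can then be scored against it exactly, instead of by ad-hoc
"mapped within 10 bp of the truth" heuristics.

It is aimed at people who develop, tune or choose read mappers and want a
mathematically unambiguous sensitivity number.

## The model

For a read *r* of length *m* and a reference *S*, consider semi-global
alignments of the whole read (no clipping; the first and last read base must
align to reference characters) under Hamming or edit (Levenshtein) distance
δ. The **error landscape** of the read is

> δ(i) = the distance of the best alignment of *r* ending at reference
> position *i*.

Flooding the landscape to level *k* + ½ yields **lakes** — maximal runs of
end positions with δ(i) ≤ *k* — and each lake is a class of
neighbour-equivalent matches. Two matches are additionally
**trace-equivalent** when they share a canonical start position (the
leftmost start among minimal-distance alignments), which merges lakes
separated by infeasible positions when their alignments share a trace. The
transitive closure of the two relations partitions the feasible matches; each
class is one interval (*k*, *first*, *last*) of the gold standard. Intervals
are built for every 0 ≤ *k* ≤ *k*<sub>max</sub>(*r*), with budgets expressed
as error *rates* relative to read length: *k* = ⌊rate · *m* / 100⌋.

A mapper record *hits* a class if its end position lies in the interval on
the same contig and strand **and** the recomputed distance there is within
budget. Scoring categories:

* **all** — a read with *n* classes earns 1/*n* point per class found;
* **all-best** — same, restricted to classes whose depth (min δ inside the
  interval) equals the read's best achievable distance;
* **any-best** — one point if any best class is found.

The headline metric, **normalized found intervals**, is
100 · Σ points / #reads (each read gives at most one point).

Gold standards are built either exhaustively (`oracle` mode, full landscapes,
small references) or by **seeded interval extension** (`seeded` mode):
starting from one known match per class — e.g. the output of a fully
sensitive mapper, or simulated read origins — the class interval is
reconstructed from landscape windows around the seed, touching only a
fraction of the reference. Both modes are bit-identical on complete seeds.

A built-in simulator generates haplotypes (SNPs + indels), technology-
flavoured reads (Illumina-like ramp errors, indel-prone long reads) and a
SAM file of true origins, which doubles as the gold standard for the
*biological* problem: recovering each read's sampling locus.

## Worked example

A 50 kb random reference, 2 000 simulated 36 bp Illumina-like reads, a gold
standard seeded from the simulated origins at an 8 % edit-error rate, and the
origin SAM evaluated as if it were a mapper's output:

```sh
mapbench simulate --ref ref.fa --n-reads 2000 --read-length 36 --seed 7 \
    --snp-rate 0 --indel-rate 0 --out-reads reads.fq --out-origins origins.sam
mapbench build-gold --ref ref.fa --reads reads.fq --distance edit \
    --max-error-rate 8 --mode seeded --seed-sam origins.sam --out gold.gsi
mapbench evaluate --gold gold.gsi --ref ref.fa --reads reads.fq \
    --sam origins.sam --category any-best --error-rate 8 --cap 100 \
    --out result.json --missed missed.gsi
```

prints

```
simulated 2000 reads -> reads.fq, origins -> origins.sam
warning: 4 seeds above the error budget ignored
gold standard: 5498 intervals -> gold.gsi
any-best @ rate 8: normalized found intervals = 100.00 (1996.00 points / 1996 reads)
```

Reading the numbers: at an 8 % rate a 36 bp read may carry
⌊0.08 · 36⌋ = 2 errors. Four simulated reads drew three or more sequencing
errors, so their origins fall outside the gold standard's budget — they are
reported (as ignored seeds while building, and as `"n_unexpected": 4` in
`result.json`) and excluded from scoring. Every one of the remaining 1 996
reads finds a best-scoring class at its true origin, hence 100.0. A real
mapper slots into the same `evaluate` call via its own SAM file; every missed
class is listed in `missed.gsi` with its (k, first, last) triple.

The gold standard itself is a plain TSV (`gold.gsi`):

```
@MAPBENCH-GSI	VERSION:1
@MODEL:edit
@RATE:8
sim.000000	chr1	-	0	0	28117	28117
sim.000000	chr1	-	1	0	28117	28117
sim.000000	chr1	-	2	0	28116	28118
```

— read `sim.000000` maps reverse-strand with 0 errors at end position 28117;
at a budget of 2 the class widens to [28116, 28118] (one-base end wobble
costs an indel), and its depth (`min_k` = 0) marks it as a best class.

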