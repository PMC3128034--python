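"""Simplified read simulator with a gold SAM of origin positions.

The simulator models the benchmark's *biological problem*: reads are sampled
from haplotypes (the reference plus SNPs and small indels), sequencing errors
are added according to a technology profile, and every read's true origin is
projected back to reference coordinates and written as a SAM record. Each
origin position is a representative of the one equivalence class a mapper
solving the biological problem should report, so the origin SAM can seed
gold-standard construction and doubles as the output of a perfect mapper.

Two deliberately minimal error profiles are built in (they provide
controllable error structure, not instrument realism):

* ``illumina`` — fixed read length, substitution-only errors whose per-base
  probability ramps linearly from the 5' to the 3' end of the read (machine
  cycles degrade), default 0.2% -> 1.2%;
* ``longread`` — normally distributed read lengths and indel-dominated
  errors (per-base insertion/deletion plus a constant substitution rate),
  loosely shaped after pyrosequencing data.

All randomness flows through one ``numpy`` generator, so a fixed seed gives
byte-identical FASTQ and SAM output across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence as PySequence, Tuple, Union

import numpy as np

from .seqs import Sequence, reverse_complement, write_fastq

__all__ = [
    "SimulationConfig",
    "Haplotype",
    "ReadOrigin",
    "SimulationResult",
    "simulate_haplotype",
    "sample_reads",
    "simulate",
    "write_origin_sam",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class SimulationConfig:
    """Parameters of haplotype generation and read sampling.

    Haplotype rates are per reference base; profile error rates are per read
    base. Defaults mirror a typical resequencing setting: ~1 SNP per kb,
    ~1 small indel per 10 kb, 36 bp short reads.
    """

    n_haplotypes: int = 1
    snp_rate: float = 0.001
    indel_rate: float = 0.0001
    indel_size_range: Tuple[int, int] = (1, 6)
    n_reads: int = 10000
    read_length: int = 36
    profile: str = "illumina"
    mismatch_rate_begin: float = 0.002
    mismatch_rate_end: float = 0.012
    length_mean: float = 400.0
    length_sd: float = 40.0
    longread_mismatch_rate: float = 0.005
    indel_error_rate: float = 0.01
    rng_seed: int = 42

    def __post_init__(self) -> None:
        for name in (
            "snp_rate",
            "indel_rate",
            "mismatch_rate_begin",
            "mismatch_rate_end",
            "longread_mismatch_rate",
            "indel_error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if self.profile not in ("illumina", "longread"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.indel_size_range[0] < 1 or self.indel_size_range[0] > self.indel_size_range[1]:
            raise ValueError("invalid indel size range")


@dataclass
class Haplotype:
    """A simulated haplotype with its variant log.

    ``hap_to_ref[i]`` is the reference position haplotype base ``i`` derives
    from, or ``-1`` for inserted bases; deleted reference bases appear as
    gaps between consecutive values. The log supports projecting haplotype
    spans back to reference coordinates (indel borders resolve to the
    nearest reference base actually consumed).
    """

    id: str
    contig_id: str
    seq: Sequence
    hap_to_ref: np.ndarray
    is_identity: bool

    def project(self, hb: int, he: int) -> Tuple[int, int]:
        """Reference (begin, end) of the haplotype span [hb, he]."""
        if self.is_identity:
            return hb, he
        h2r = self.hap_to_ref
        j = hb
        while j <= he and h2r[j] < 0:
            j += 1
        if j > he:  # span lies entirely in an insertion; anchor to neighbours
            left = int(h2r[:hb][h2r[:hb] >= 0][-1]) if (h2r[:hb] >= 0).any() else 0
            return left, left
        begin = int(h2r[j])
        j = he
        while j >= hb and h2r[j] < 0:
            j -= 1
        return begin, int(h2r[j])


@dataclass(frozen=True)
class ReadOrigin:
    """The true sampling locus of one simulated read."""

    read_id: str
    haplotype_id: str
    contig_id: str
    strand: str
    ref_begin: int
    ref_end: int
    n_errors_sequencing: int
    edit_string: str  # CIGAR of the origin alignment against the reference


@dataclass
class SimulationResult:
    reads: List[Sequence]
    quals: Dict[str, str]
    origins: List[ReadOrigin]
    haplotypes: List[Haplotype]


def simulate_haplotype(
    ref: Sequence, config: SimulationConfig, rng: np.random.Generator, hap_id: str = "hap0"
) -> Haplotype:
    """Mutate a reference contig into one haplotype (SNPs + small indels)."""
    n = len(ref)
    arr = np.frombuffer(ref.bases.encode("ascii"), dtype=np.uint8).copy()
    snp_mask = (
        rng.random(n) < config.snp_rate if config.snp_rate > 0 else np.zeros(n, bool)
    )
    codes = _CODE[arr]
    snp_mask &= codes < 4  # N positions are left untouched
    idx = np.flatnonzero(snp_mask)
    if len(idx):
        shift = rng.integers(1, 4, size=len(idx))
        arr[idx] = _BASES[(codes[idx] + shift) % 4]
    indel_pos = (
        np.flatnonzero(rng.random(n) < config.indel_rate)
        if config.indel_rate > 0
        else np.empty(0, dtype=np.int64)
    )
    if len(indel_pos) == 0:
        # SNPs do not disturb the coordinate map, only indels do
        hap = Sequence(hap_id, arr.tobytes().decode("ascii"))
        return Haplotype(hap_id, ref.id, hap, np.arange(n), True)
    lo, hi = config.indel_size_range
    pieces: List[np.ndarray] = []
    maps: List[np.ndarray] = []
    cur = 0
    for p in indel_pos:
        p = int(p)
        if p < cur:
            continue  # inside an earlier deletion
        size = int(rng.integers(lo, hi + 1))
        if rng.random() < 0.5:  # deletion of ref bases p .. p+size-1
            pieces.append(arr[cur:p])
            maps.append(np.arange(cur, p))
            cur = min(n, p + size)
        else:  # insertion of random bases before p
            pieces.append(arr[cur:p])
            maps.append(np.arange(cur, p))
            ins = _BASES[rng.integers(0, 4, size=size)]
            pieces.append(ins)
            maps.append(np.full(size, -1, dtype=np.int64))
            cur = p
    pieces.append(arr[cur:])
    maps.append(np.arange(cur, n))
    hap_arr = np.concatenate(pieces)
    h2r = np.concatenate(maps)
    hap = Sequence(hap_id, hap_arr.tobytes().decode("ascii"))
    return Haplotype(hap_id, ref.id, hap, h2r, False)


def _phred_string(p: np.ndarray) -> str:
    q = np.clip(np.round(-10.0 * np.log10(np.maximum(p, 1e-4))), 2, 40).astype(int)
    return "".join(chr(33 + int(v)) for v in q)


def _apply_substitutions(
    rows: np.ndarray, p: np.ndarray, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-base substitutions with position-wise probability ``p`` (per row)."""
    mask = rng.random(rows.shape) < p
    mask &= _CODE[rows] < 4
    idx = np.nonzero(mask)
    if len(idx[0]):
        shift = rng.integers(1, 4, size=len(idx[0]))
        rows[idx] = _BASES[(_CODE[rows[idx]] + shift) % 4]
    return rows, mask.sum(axis=1)


_RC = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _RC[_a] = _b


def _compose_cigar(hap: Haplotype, hb: int, read_ops: List[Tuple[str, int]]) -> str:
    """CIGAR of (read vs haplotype ops) composed with the haplotype's variants."""
    h2r = hap.hap_to_ref
    out: List[Tuple[str, int]] = []

    def emit(op: str, ln: int = 1) -> None:
        if ln and out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + ln)
        elif ln:
            out.append((op, ln))

    hpos = hb
    prev_ref = None
    for op, ln in read_ops:
        if op == "I":
            emit("I", ln)
            continue
        for _ in range(ln):
            r = int(h2r[hpos])
            hpos += 1
            if r < 0:
                emit("I" if op == "M" else "", 1 if op == "M" else 0)
                continue
            if prev_ref is not None and r > prev_ref + 1:
                emit("D", r - prev_ref - 1)
            emit("M" if op == "M" else "D")
            prev_ref = r
    return "".join(f"{ln}{op}" for op, ln in out)


def _sample_illumina(
    haps: List[Haplotype],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SimulationResult:
    L = config.read_length
    usable = [h for h in haps if len(h.seq) >= L]
    if not usable:
        raise ValueError(f"no haplotype is at least {L} bp long")
    weights = np.array([len(h.seq) - L + 1 for h in usable], dtype=float)
    weights /= weights.sum()
    hap_idx = rng.choice(len(usable), size=config.n_reads, p=weights)
    p_ramp = np.linspace(config.mismatch_rate_begin, config.mismatch_rate_end, L)
    qual = _phred_string(p_ramp)
    reads: List[Sequence] = [None] * config.n_reads  # type: ignore[list-item]
    origins: List[ReadOrigin] = [None] * config.n_reads  # type: ignore[list-item]
    quals: Dict[str, str] = {}
    for hi, hap in enumerate(usable):
        sel = np.flatnonzero(hap_idx == hi)
        if len(sel) == 0:
            continue
        arr = np.frombuffer(hap.seq.bases.encode("ascii"), dtype=np.uint8)
        starts = rng.integers(0, len(arr) - L + 1, size=len(sel))
        strands = rng.integers(0, 2, size=len(sel))
        rows = arr[starts[:, None] + np.arange(L)].copy()
        rev = strands == 1
        if rev.any():  # orient templates along the read before the error ramp
            rows[rev] = _RC[rows[rev][:, ::-1]]
        rows, nerr = _apply_substitutions(rows, p_ramp, rng)
        for j, ridx in enumerate(sel):
            rid = f"sim.{ridx:06d}"
            seq = rows[j].tobytes().decode("ascii")
            reads[ridx] = Sequence(rid, seq)
            quals[rid] = qual
            hb = int(starts[j])
            rb, re = hap.project(hb, hb + L - 1)
            cigar = (
                f"{L}M"
                if hap.is_identity
                else _compose_cigar(hap, hb, [("M", L)])
            )
            origins[ridx] = ReadOrigin(
                rid,
                hap.id,
                hap.contig_id,
                "-" if strands[j] else "+",
                rb,
                re,
                int(nerr[j]),
                cigar,
            )
    return SimulationResult(reads, quals, origins, haps)


def _sample_longread(
    haps: List[Haplotype],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SimulationResult:
    weights = np.array([len(h.seq) for h in haps], dtype=float)
    weights /= weights.sum()
    reads: List[Sequence] = []
    origins: List[ReadOrigin] = []
    quals: Dict[str, str] = {}
    const_p = max(config.longread_mismatch_rate + config.indel_error_rate, 1e-4)
    for ridx in range(config.n_reads):
        hap = haps[int(rng.choice(len(haps), p=weights))]
        hlen = len(hap.seq)
        L = int(np.clip(round(rng.normal(config.length_mean, config.length_sd)), 30, hlen))
        hb = int(rng.integers(0, hlen - L + 1))
        strand = "-" if rng.integers(0, 2) else "+"
        tmpl = np.frombuffer(hap.seq.bases.encode("ascii"), dtype=np.uint8)[hb : hb + L]
        out: List[int] = []
        ops: List[Tuple[str, int]] = []
        nerr = 0

        def push(op: str) -> None:
            if ops and ops[-1][0] == op:
                ops[-1] = (op, ops[-1][1] + 1)
            else:
                ops.append((op, 1))

        half = config.indel_error_rate / 2.0
        for t in range(L):
            r = rng.random()
            if r < half:  # inserted base in the read
                out.append(int(_BASES[rng.integers(0, 4)]))
                push("I")
                nerr += 1
                # the template base itself is still sequenced
            elif r < config.indel_error_rate:  # template base dropped
                push("D")
                nerr += 1
                continue
            b = int(tmpl[t])
            if rng.random() < config.longread_mismatch_rate and _CODE[b] < 4:
                b = int(_BASES[(_CODE[b] + rng.integers(1, 4)) % 4])
                nerr += 1
            out.append(b)
            push("M")
        # enforce the anchoring convention: the origin alignment must start
        # and end with a read base on the template, so trim boundary indels
        while ops and ops[0][0] == "D":
            hb += ops[0][1]
            nerr -= ops[0][1]
            ops.pop(0)
        while ops and ops[-1][0] == "D":
            nerr -= ops[-1][1]
            ops.pop()
        while ops and ops[0][0] == "I":
            out = out[ops[0][1] :]
            nerr -= ops[0][1]
            ops.pop(0)
        while ops and ops[-1][0] == "I":
            out = out[: -ops[-1][1]]
            nerr -= ops[-1][1]
            ops.pop()
        seq_fwd = bytes(out).decode("ascii")
        if not ops:  # degenerate: everything trimmed away; emit error-free read
            hb = int(rng.integers(0, hlen - L + 1))
            tmpl = np.frombuffer(hap.seq.bases.encode("ascii"), dtype=np.uint8)[hb : hb + L]
            seq_fwd = tmpl.tobytes().decode("ascii")
            ops = [("M", L)]
            nerr = 0
        rid = f"sim.{ridx:06d}"
        seq = (
            seq_fwd
            if strand == "+"
            else _RC[np.frombuffer(seq_fwd.encode(), dtype=np.uint8)][::-1]
            .tobytes()
            .decode("ascii")
        )
        reads.append(Sequence(rid, seq))
        quals[rid] = _phred_string(np.full(len(seq), const_p))
        consumed = sum(l for o, l in ops if o in ("M", "D"))
        he = hb + consumed - 1  # rightmost template base consumed
        rb, re = hap.project(hb, he)
        cigar = (
            "".join(f"{l}{o}" for o, l in ops)
            if hap.is_identity
            else _compose_cigar(hap, hb, ops)
        )
        origins.append(
            ReadOrigin(rid, hap.id, hap.contig_id, strand, rb, re, nerr, cigar)
        )
    return SimulationResult(reads, quals, origins, haps)


def sample_reads(
    haps: List[Haplotype], config: SimulationConfig, rng: np.random.Generator
) -> SimulationResult:
    """Sample reads with profile-dependent errors from simulated haplotypes."""
    if config.profile == "illumina":
        return _sample_illumina(haps, config, rng)
    return _sample_longread(haps, config, rng)


def simulate(
    ref_contigs: PySequence[Sequence], config: SimulationConfig
) -> SimulationResult:
    """End-to-end simulation: haplotypes, reads, qualities and origins."""
    rng = np.random.default_rng(config.rng_seed)
    haps: List[Haplotype] = []
    for contig in ref_contigs:
        for h in range(config.n_haplotypes):
            haps.append(
                simulate_haplotype(contig, config, rng, hap_id=f"{contig.id}.hap{h}")
            )
    return sample_reads(haps, config, rng)


def write_origin_sam(
    origins: PySequence[ReadOrigin],
    reads: Union[Dict[str, Sequence], PySequence[Sequence]],
    refs: PySequence[Sequence],
    path: Union[str, Path],
) -> None:
    """Write the biological-problem gold standard as a SAM file.

    One record per read; POS/CIGAR encode the origin alignment against the
    reference, reverse-strand reads carry flag 16 and forward-oriented SEQ.
    """
    read_map = reads if isinstance(reads, dict) else {r.id: r for r in reads}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for c in refs:
            fh.write(f"@SQ\tSN:{c.id}\tLN:{len(c)}\n")
        fh.write("@PG\tID:mapbench\tPN:mapbench-simulate\n")
        for o in origins:
            read = read_map[o.read_id]
            seq = read.bases if o.strand == "+" else reverse_complement(read).bases
            flag = 16 if o.strand == "-" else 0
            fh.write(
                f"{o.read_id}\t{flag}\t{o.contig_id}\t{o.ref_begin + 1}\t255"
                f"\t{o.edit_string}\t*\t0\t0\t{seq}\t*\tNM:i:{o.n_errors_sequencing}\n"
            )
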