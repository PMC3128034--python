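"""Sequence container, reverse complementation and FASTA/FASTQ input.

Sequences are plain uppercase DNA strings over the alphabet ``{A, C, G, T, N}``.
Reading goes through Biopython so multi-contig, line-wrapped and mixed-case
files behave as expected; internally everything is normalised to uppercase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Union

import numpy as np
from Bio import SeqIO

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# numeric base codes used by the alignment kernels: A,C,G,T -> 0..3, N -> 4.
# N (code 4) mismatches every base, including another N.
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,N}."""


@dataclass(frozen=True)
class Sequence:
    """A named DNA sequence.

    Attributes
    ----------
    id:
        Record identifier (FASTA/FASTQ header up to the first whitespace).
    bases:
        Uppercase string over ``{A, C, G, T, N}``; never empty.
    """

    id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise InvalidSequenceError(f"sequence {self.id!r} is empty")
        bad = set(self.bases) - ALPHABET
        if bad:
            raise InvalidSequenceError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def codes(self) -> np.ndarray:
        """Numeric base codes (uint8) for the alignment kernels."""
        return _BASE_CODE[np.frombuffer(self.bases.encode("ascii"), dtype=np.uint8)]


def normalize(seq_id: str, raw: str) -> Sequence:
    """Build a :class:`Sequence` from raw text, uppercasing first."""
    return Sequence(seq_id, raw.upper())


def reverse_complement(seq: Sequence) -> Sequence:
    """Reverse complement: C<->G, A<->T, N stays N; the string is reversed.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    return Sequence(seq.id, seq.bases.translate(_COMPLEMENT)[::-1])


def read_fasta(path: Union[str, Path]) -> List[Sequence]:
    """Read a (multi-)FASTA file into a list of normalised sequences.

    Raises on duplicate contig identifiers, which would make interval keys
    ambiguous downstream.
    """
    out: List[Sequence] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append(normalize(rec.id, str(rec.seq)))
    if not out:
        raise ValueError(f"no sequences found in {path}")
    return out


def read_reads(path: Union[str, Path]) -> List[Sequence]:
    """Read reads from FASTA or FASTQ (sniffed from the first character).

    FASTQ base qualities are ignored: the benchmark distances are unweighted.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    out = [normalize(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), fmt)]
    if not out:
        raise ValueError(f"no reads found in {path}")
    return out


def as_dict(seqs: Iterable[Sequence]) -> Dict[str, Sequence]:
    """Index sequences by id, rejecting collisions."""
    out: Dict[str, Sequence] = {}
    for s in seqs:
        if s.id in out:
            raise ValueError(f"duplicate sequence id {s.id!r}")
        out[s.id] = s
    return out


def write_fasta(seqs: Iterable[Sequence], path: Union[str, Path], width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.bases), width):
                fh.write(s.bases[i : i + width] + "\n")


def write_fastq(
    seqs: Iterable[Sequence], path: Union[str, Path], quals: Dict[str, str] | None = None
) -> None:
    """Write FASTQ; qualities default to 'I' (Q40) when not supplied."""
    with open(path, "w") as fh:
        for s in seqs:
            q = (quals or {}).get(s.id, "I" * len(s.bases))
            fh.write(f"@{s.id}\n{s.bases}\n+\n{q}\n")
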