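"""FASTA input/output and allele tallying.

Sequences are treated as alleles identified by their exact nucleotide
string. The method requires a pre-made alignment of equal-length, gap-free
sequences over {A, C, G, T}: the distance between two alleles is the number
of substitutions separating them, so indels and ambiguity codes cannot be
used and are rejected on input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentLengthError,
    AlphabetError,
    EmptyAlignmentError,
    GapError,
)

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_GAP_CHARS = set("-.~")


_CODE_LUT = np.zeros(256, dtype=np.uint8)
for _b, _i in _CODE.items():
    _CODE_LUT[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 code vector (A=0, C=1, G=2, T=3)."""
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_sequences(seqs) -> np.ndarray:
    """Encode an iterable of equal-length ACGT strings as an (n, l) uint8 matrix."""
    seqs = list(seqs)
    if not seqs:
        raise EmptyAlignmentError("no sequences to encode")
    arr = np.empty((len(seqs), len(seqs[0])), dtype=np.uint8)
    for i, s in enumerate(seqs):
        arr[i] = _encode(s)
    return arr


def decode_sequence(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


@dataclass(frozen=True)
class Alignment:
    """An ordered collection of equal-length, gap-free nucleotide sequences.

    One record per sampled individual; identifiers are carried through but
    never used in computation (duplicates are allowed).
    """

    ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in number")
        if not self.sequences:
            raise EmptyAlignmentError("alignment contains no records")
        length = len(self.sequences[0])
        for ident, seq in zip(self.ids, self.sequences):
            if len(seq) != length:
                raise AlignmentLengthError(
                    f"record {ident!r} has length {len(seq)}, expected {length}; "
                    "all alleles must have the same length"
                )
            if length == 0:
                raise EmptyAlignmentError(f"record {ident!r} has zero length")
            bad = set(seq) - set(BASES)
            if bad & _GAP_CHARS:
                raise GapError(
                    f"record {ident!r} contains a gap character; insertions and "
                    "deletions cannot be used with substitution distances"
                )
            if bad:
                raise AlphabetError(
                    f"record {ident!r} contains {sorted(bad)}; only A, C, G, T are "
                    "allowed (mixed/ambiguous bases are not considered)"
                )

    @property
    def length(self) -> int:
        """Alignment (sequence) length l."""
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(zip(self.ids, self.sequences))

    def to_matrix(self) -> np.ndarray:
        """Return the (n, l) uint8 code matrix of the alignment."""
        return encode_sequences(self.sequences)


@dataclass(frozen=True)
class AlleleTable:
    """Distinct alleles of a sample with their observed counts.

    Alleles are listed in order of first appearance in the alignment; counts
    sum to the sample size n.
    """

    alleles: tuple[str, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.alleles:
            raise EmptyAlignmentError("allele table is empty")
        if len(self.alleles) != len(self.counts):
            raise ValueError("alleles and counts differ in number")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError("alleles must be pairwise distinct")
        if any(c < 1 for c in self.counts):
            raise ValueError("allele counts must be positive")

    @property
    def n(self) -> int:
        """Sample size (number of individuals)."""
        return int(sum(self.counts))

    @property
    def k(self) -> int:
        """Number of distinct alleles."""
        return len(self.alleles)

    @property
    def length(self) -> int:
        return len(self.alleles[0])

    @property
    def frequencies(self) -> dict[str, float]:
        n = self.n
        return {a: c / n for a, c in zip(self.alleles, self.counts)}

    def allele_index_of_individual(self, i: int) -> int:
        """Map individual index (0..n-1, grouped by allele) to allele index."""
        if not 0 <= i < self.n:
            raise IndexError(f"individual index {i} out of range for n={self.n}")
        acc = 0
        for k, c in enumerate(self.counts):
            acc += c
            if i < acc:
                return k
        raise AssertionError("unreachable")


def read_alignment(path: str | Path) -> Alignment:
    """Read a FASTA file into a validated :class:`Alignment`.

    Lowercase input is uppercased (DNA only; ``U`` is rejected rather than
    converted). Raises :class:`GapError`, :class:`AlphabetError`,
    :class:`AlignmentLengthError` or :class:`EmptyAlignmentError` on
    constraint violations.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyAlignmentError(f"no FASTA records found in {path}")
    ids = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).upper() for r in records)
    return Alignment(ids=ids, sequences=seqs)


def write_alignment(aln: Alignment, path: str | Path, width: int = 70) -> None:
    """Write an alignment to FASTA (wrapped at `width` columns)."""
    records = [
        SeqRecord(Seq(seq), id=ident, description="") for ident, seq in aln
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def tally_alleles(aln: Alignment) -> AlleleTable:
    """Collapse an alignment into distinct alleles with observed counts.

    These counts are the sample allele frequencies used as the kernel
    centers; order is first appearance.
    """
    order: dict[str, int] = {}
    for seq in aln.sequences:
        order[seq] = order.get(seq, 0) + 1
    return AlleleTable(alleles=tuple(order), counts=tuple(order.values()))


def hamming(a: str, b: str) -> int:
    """Number of substitutions between two equal-length sequences."""
    if len(a) != len(b):
        raise AlignmentLengthError(
            f"cannot compare sequences of lengths {len(a)} and {len(b)}"
        )
    return sum(x != y for x, y in zip(a, b))


def hamming_matrix(seqs_a, seqs_b=None) -> np.ndarray:
    """Pairwise Hamming distances between two sequence collections."""
    A = encode_sequences(seqs_a)
    B = A if seqs_b is None else encode_sequences(seqs_b)
    if A.shape[1] != B.shape[1]:
        raise AlignmentLengthError("sequence collections differ in length")
    return (A[:, None, :] != B[None, :, :]).sum(axis=2).astype(np.int64)
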