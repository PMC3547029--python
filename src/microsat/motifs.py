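"""Motif canonicalization and phase arithmetic for perfect tandem repeats.

A microsatellite motif of period k (1-6 bp) is identified with its
equivalence class under cyclic rotation and reverse complementation:
the class of AAC contains AAC, ACA, CAA and their complements TTG, TGT,
GTT.  The canonical representative is the lexicographically smallest
member.  Only primitive motifs (not a whole-number repetition of a
shorter word) name a class; ACAC is rejected because it is (AC)^2.

For a *perfect* array the terminal k-mer is pure arithmetic: it is the
start k-mer rotated by ``(length - k) mod k``, which is what produces
the characteristic phase structure of array-length spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

__all__ = [
    "MotifClass",
    "canonical_class",
    "end_kmer_of",
    "revcomp",
    "is_primitive",
    "rotations",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string (N maps to N)."""
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def rotations(motif: str) -> list[str]:
    """All cyclic rotations of *motif*, starting with the motif itself."""
    return [motif[i:] + motif[:i] for i in range(len(motif))]


def smallest_period(s: str) -> int:
    """Smallest p such that s[i] == s[i+p] for all valid i."""
    n = len(s)
    for p in range(1, n):
        if all(s[i] == s[i + p] for i in range(n - p)):
            return p
    return n


def is_primitive(motif: str) -> bool:
    """True if *motif* is not a whole-number repetition of a shorter word."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return False
    return True


@dataclass(frozen=True)
class MotifClass:
    """Equivalence class of a primitive motif under rotation and revcomp.

    Attributes
    ----------
    canonical : str
        Lexicographically smallest member; names the class.
    period : int
        Motif length k (1-6).
    members : frozenset[str]
        All rotations of the canonical motif and of its reverse
        complement (at most 2k distinct k-mers; e.g. the AT class
        collapses to {AT, TA}).
    strand_merged : bool
        Whether the two strands' rotations were merged (always True for
        classes built by :func:`canonical_class`).
    """

    canonical: str
    period: int
    members: frozenset = field(repr=False)
    strand_merged: bool = True

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.members

    def __str__(self) -> str:
        return self.canonical


@lru_cache(maxsize=None)
def canonical_class(motif: str) -> MotifClass:
    """Return the strand/rotation class containing *motif*.

    Two motifs map to the same class iff one is a rotation of the other
    or of its reverse complement.

    Raises
    ------
    ValueError
        If the motif is empty, longer than 6 bp, contains non-ACGT
        characters, or is non-primitive (e.g. ``ACAC``).
    """
    if not motif or len(motif) > 6:
        raise ValueError(f"motif length must be 1-6, got {motif!r}")
    if not set(motif) <= _ALPHABET:
        raise ValueError(f"motif contains non-ACGT characters: {motif!r}")
    if not is_primitive(motif):
        raise ValueError(f"non-primitive motif: {motif!r}")
    members = frozenset(rotations(motif) + rotations(revcomp(motif)))
    return MotifClass(
        canonical=min(members), period=len(motif), members=members
    )


def end_kmer_of(start_kmer: str, length_bp: int) -> str:
    """Terminal k-mer of a perfect array given its start k-mer and length.

    The array is the periodic extension of *start_kmer* truncated at
    *length_bp*; its last k bases are the start k-mer rotated by
    ``(length_bp - k) mod k``.  E.g. a 14-bp array starting AAC ends CAA.

    Raises
    ------
    ValueError
        If ``length_bp < len(start_kmer)``.
    """
    k = len(start_kmer)
    if length_bp < k:
        raise ValueError(
            f"length {length_bp} shorter than period {k}: no full end k-mer"
        )
    shift = (length_bp - k) % k
    return start_kmer[shift:] + start_kmer[:shift]
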