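"""Start/end k-mer tables of microsatellite arrays within length windows.

For a perfect array the terminal k-mer is determined by the start k-mer
and the length (see :func:`microsat.motifs.end_kmer_of`), so the joint
distribution of (start k-mer, end k-mer) within a length window captures
the same phase structure as the length spectrum, broken down by the
rotation in which arrays begin and end.  Unlike the rest of the
pipeline, this table keeps the two strands' rotations separate: an
AAC...CAA array and its complement TTG...GTT occupy distinct cells,
which is what exposes the complementary pairing of the most abundant
start/end combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .arrays import RepeatArray
from .motifs import MotifClass, canonical_class, end_kmer_of, rotations

__all__ = ["FlankMotifTable", "start_end_table", "feasible_cells"]


@dataclass
class FlankMotifTable:
    """Counts of arrays by (start k-mer, end k-mer) in a length window.

    ``scope`` is "internal_only" (both array ends strictly inside the
    read/contig, so lengths are uncensored - appropriate for read data)
    or "all" (assembled sequence).
    """

    motif_class: MotifClass
    length_window: tuple[int, int]
    cells: dict[tuple[str, str], int]
    scope: str = "internal_only"
    warning: str | None = None

    @property
    def total(self) -> int:
        return sum(self.cells.values())

    def to_frame(self) -> pd.DataFrame:
        """Table with one row per feasible cell, ordered as in standard
        published layouts: lexicographic starts within each strand."""
        k = self.motif_class.period
        rows = []
        for start, end in _ordered_cells(self.motif_class):
            phase = _phase_for(start, end)
            partial = start[:phase]
            rep = f"({start})n {partial}".rstrip()
            rows.append(
                {
                    "representation": rep,
                    "start": start,
                    "end": end,
                    "count": self.cells.get((start, end), 0),
                }
            )
        return pd.DataFrame(rows)


def _phase_for(start: str, end: str) -> int:
    """Length residue r in [0, k) such that end_kmer_of(start, k + r) == end."""
    k = len(start)
    for r in range(k):
        if end_kmer_of(start, k + r) == end:
            return r
    raise ValueError(f"{end!r} is not a rotation of {start!r}")


def _ordered_cells(motif_class: MotifClass) -> list[tuple[str, str]]:
    """All feasible (start, end) pairs, strands separated, sorted."""
    fwd = sorted(rotations(motif_class.canonical))
    strands = [fwd]
    rev = sorted(r for r in motif_class.members if r not in fwd)
    if rev:
        strands.append(rev)
    cells: list[tuple[str, str]] = []
    for strand in strands:
        for s in strand:
            for e in strand:
                cells.append((s, e))
    return cells


def feasible_cells(
    motif_class: MotifClass | str, length_window: tuple[int, int]
) -> set[tuple[str, str]]:
    """The (start, end) pairs realizable by some length in the window.

    Every rotation pair within one strand is feasible as soon as the
    window covers k consecutive lengths; narrower windows restrict the
    reachable end phases.
    """
    if isinstance(motif_class, str):
        motif_class = canonical_class(motif_class)
    lo, hi = length_window
    k = motif_class.period
    out: set[tuple[str, str]] = set()
    for start, end in _ordered_cells(motif_class):
        r = _phase_for(start, end)
        if any(L % k == (k + r) % k for L in range(max(lo, k), hi + 1)):
            out.add((start, end))
    return out


def start_end_table(
    arrays: Iterable[RepeatArray],
    motif_class: MotifClass | str,
    length_window: tuple[int, int],
    scope: str = "internal_only",
) -> FlankMotifTable:
    """Tabulate arrays of one class by (start k-mer, end k-mer).

    Parameters
    ----------
    arrays :
        Scanned arrays carrying start_kmer, end_kmer and edge status.
    motif_class :
        Class to tabulate (canonical string accepted).
    length_window :
        Inclusive bp range; arrays outside it are ignored.
    scope :
        "internal_only" or "all".

    A window that cannot contain any array of this period (upper bound
    below the period) yields an empty table with a warning set.
    """
    if scope not in ("internal_only", "all"):
        raise ValueError(f"unknown scope {scope!r}")
    if isinstance(motif_class, str):
        motif_class = canonical_class(motif_class)
    lo, hi = length_window
    warning = None
    if hi < motif_class.period:
        warning = (
            f"length window {length_window} below period "
            f"{motif_class.period}: no array can match"
        )
    cells: dict[tuple[str, str], int] = {}
    for a in arrays:
        if a.motif_class != motif_class:
            continue
        if not (lo <= a.length_bp <= hi):
            continue
        if scope == "internal_only" and a.edge != "internal":
            continue
        key = (a.start_kmer, a.end_kmer)
        cells[key] = cells.get(key, 0) + 1
    return FlankMotifTable(
        motif_class=motif_class,
        length_window=(lo, hi),
        cells=cells,
        scope=scope,
        warning=warning,
    )
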