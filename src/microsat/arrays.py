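"""Detection of maximal perfect microsatellite arrays.

The scanner reports every maximal run of exact period-k repetition
(k in a configurable range, 1-6) whose length passes a minimum.  An
array is reported once, at its smallest primitive period: a poly-A run
is a period-1 array and never doubles as an AA "dinucleotide"; arrays of
*different* primitive periods may overlap (AAAAACACACAC yields both a
poly-A run and an AC array).  Repetition must be perfect - a single
mismatch, or any non-ACGT base, terminates the run.  Partial trailing
units count toward length_bp; unit_count is the floor.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .motifs import MotifClass, canonical_class

__all__ = [
    "Thresholds",
    "RepeatArray",
    "find_arrays",
    "find_arrays_in_records",
    "classify_edges",
    "normalize_per_100mb",
]


@dataclass(frozen=True)
class Thresholds:
    """Numeric thresholds used across the pipeline.

    Attributes
    ----------
    min_units_locus : int
        An array counts as a *locus* when it holds at least this many
        whole motif units (default 3: "three and more monomers").
    min_flank_array_bp : int
        Minimum bases of a perfect array that must fall inside a TE
        flank window for the TE to count as microsatellite-associated
        (default 10).
    flank_window_bp : int
        Width of the windows upstream/downstream of a TE (default 50).
    tri_window : tuple[int, int]
        Inclusive length window for trinucleotide start/end tables
        (default 11-31).
    di_min_bp : int
        Minimum length for dinucleotide start/end tables (default 14).
    recomb_min_bp : int
        Arrays must be strictly longer than this for the sliding-window
        recombination track (default 16).
    recomb_window_bp : int
        Window width of the recombination track (default 20 kb).
    rm_max_divergence_pct : float
        Maximum RepeatMasker divergence from consensus for a TE hit to
        be kept (default 24).
    norm_base : int
        Normalization base for rates (default 1e8: per 100 Mb).
    """

    min_units_locus: int = 3
    min_flank_array_bp: int = 10
    flank_window_bp: int = 50
    tri_window: tuple[int, int] = (11, 31)
    di_min_bp: int = 14
    recomb_min_bp: int = 16
    recomb_window_bp: int = 20_000
    rm_max_divergence_pct: float = 24.0
    norm_base: int = 100_000_000

    def __post_init__(self) -> None:
        for name in (
            "min_units_locus",
            "min_flank_array_bp",
            "flank_window_bp",
            "di_min_bp",
            "recomb_min_bp",
            "recomb_window_bp",
            "rm_max_divergence_pct",
            "norm_base",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.tri_window
        if not (0 < lo <= hi):
            raise ValueError(f"invalid tri_window {self.tri_window}")

    def with_(self, **kwargs) -> "Thresholds":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class RepeatArray:
    """One maximal perfect tandem array.

    ``end - start == length_bp``; the subsequence is the periodic
    extension of ``observed_strand_kmer`` truncated at ``length_bp``,
    and extending one base on either side breaks period-k exactness.
    """

    seq_id: str
    start: int
    end: int
    motif_class: MotifClass = field(compare=False)
    observed_strand_kmer: str
    start_kmer: str
    end_kmer: str
    length_bp: int
    unit_count: int
    edge: str = "internal"

    @property
    def period(self) -> int:
        return self.motif_class.period

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

_KNOWN = frozenset("ACGTNacgtn")


def _encode(seq: str) -> np.ndarray:
    """Uppercase-insensitive base codes; -1 for N. Rejects other chars."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _BASE_CODE[raw]
    if (codes < 0).any():
        bad = set(seq) - _KNOWN
        if bad:
            raise ValueError(f"sequence contains invalid characters: {sorted(bad)}")
    return codes


def find_arrays(
    seq: str,
    k_min: int = 1,
    k_max: int = 3,
    min_len_bp: int | None = None,
    seq_id: str = "seq",
) -> list[RepeatArray]:
    """Every maximal perfect array with primitive period in [k_min, k_max].

    Parameters
    ----------
    seq :
        Nucleotide string over {A, C, G, T, N}; lowercase (soft-masked)
        bases are uppercased before scanning; N breaks any array.
    k_min, k_max :
        Primitive period range, 1 <= k_min <= k_max <= 6.
    min_len_bp :
        Minimum array length in bp.  When None the period-specific
        default of three whole units (3k) applies.
    seq_id :
        Identifier recorded on each array.

    Returns
    -------
    list[RepeatArray]
        Sorted by start coordinate.  Edge status is set relative to the
        scanned sequence (see :func:`classify_edges`).
    """
    if not (1 <= k_min <= k_max <= 6):
        raise ValueError(f"period range must satisfy 1 <= k_min <= k_max <= 6")
    n = len(seq)
    out: list[RepeatArray] = []
    if n == 0:
        return out
    codes = _encode(seq)
    valid = codes >= 0
    # prefix sum of valid bases: span [a, b) is N-free iff vcum[b]-vcum[a] == b-a
    vcum = np.concatenate(([0], np.cumsum(valid)))
    # per-period match arrays, kept for smallest-period checks
    match: dict[int, np.ndarray] = {}
    mcum: dict[int, np.ndarray] = {}
    for k in range(1, k_max + 1):
        if n > k:
            m = (codes[:-k] == codes[k:]) & valid[:-k] & valid[k:]
        else:
            m = np.zeros(0, dtype=bool)
        match[k] = m
        mcum[k] = np.concatenate(([0], np.cumsum(m)))

    def span_has_period(a: int, b: int, p: int) -> bool:
        # s[a:b] has period p (all s[i]==s[i+p]); degenerate when b-a <= p
        if b - a <= p:
            return True
        c = mcum[p]
        return c[b - p] - c[a] == (b - a) - p

    seq_up = seq.upper()
    for k in range(k_min, k_max + 1):
        m = match[k]
        if m.size == 0:
            continue
        min_len = 3 * k if min_len_bp is None else min_len_bp
        if min_len < k:
            min_len = k
        # runs of consecutive True in m: run [a, a+r) of matches -> array [a, a+r+k)
        padded = np.concatenate(([False], m, [False]))
        diff = np.diff(padded.astype(np.int8))
        run_starts = np.flatnonzero(diff == 1)
        run_ends = np.flatnonzero(diff == -1)  # exclusive in m-coordinates
        for a, e in zip(run_starts, run_ends):
            b = int(e) + k  # array end, exclusive
            a = int(a)
            if b - a < min_len:
                continue
            # the span itself must be N-free (match only validates paired bases)
            if vcum[b] - vcum[a] != b - a:
                continue
            # report at smallest primitive period only
            if any(span_has_period(a, b, p) for p in range(1, k)):
                continue
            kmer = seq_up[a : a + k]
            out.append(
                RepeatArray(
                    seq_id=seq_id,
                    start=a,
                    end=b,
                    motif_class=canonical_class(kmer),
                    observed_strand_kmer=kmer,
                    start_kmer=kmer,
                    end_kmer=seq_up[b - k : b],
                    length_bp=b - a,
                    unit_count=(b - a) // k,
                    edge=classify_edges(a, b, n),
                )
            )
    out.sort(key=lambda r: (r.start, r.period))
    return out


def find_arrays_in_records(
    records: Iterable[tuple[str, str]],
    k_min: int = 1,
    k_max: int = 3,
    min_len_bp: int | None = None,
) -> tuple[list[RepeatArray], int]:
    """Scan (id, sequence) records; returns (arrays, total bases scanned)."""
    arrays: list[RepeatArray] = []
    total = 0
    for seq_id, seq in records:
        arrays.extend(find_arrays(seq, k_min, k_max, min_len_bp, seq_id=seq_id))
        total += len(seq)
    arrays.sort(key=lambda r: (r.seq_id, r.start, r.period))
    return arrays, total


def classify_edges(start: int, end: int, seq_len: int) -> str:
    """Edge status of an array within its read/contig.

    internal: both ends strictly inside; left_terminal / right_terminal:
    touching one edge; spanning: the whole sequence is array.
    """
    if not (0 <= start < end <= seq_len):
        raise ValueError(
            f"array [{start}, {end}) outside sequence of length {seq_len}"
        )
    left = start == 0
    right = end == seq_len
    if left and right:
        return "spanning"
    if left:
        return "left_terminal"
    if right:
        return "right_terminal"
    return "internal"


def normalize_per_100mb(
    count: float, total_bases: int, norm_base: int = 100_000_000
) -> float:
    """Rate per *norm_base* scanned bases (default: per 100 Mb)."""
    if total_bases <= 0:
        raise ValueError("total_bases must be positive")
    return count * norm_base / total_bases
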