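"""Array-length spectra, locus counts, periodicity, and group comparison.

Length spectra (counts of arrays at each exact length, normalized per
100 Mb of scanned sequence) are the primary readout of microsatellite
dynamics: a class whose spectrum carries a long tail in one group but
not another has undergone array expansion there.  Spectra of AC- and
AAC-type arrays show peaks every k bp; the phase test below quantifies
that periodicity as a chi-square goodness-of-fit of length-mod-k
residues against uniformity.

Distinguishing expansion from new-locus formation uses two per-class
rates: the *locus* rate (arrays of >= 3 whole units, per 100 Mb) and
the *long-array* rate (arrays >= a length threshold, default 50 bp,
chosen because unexpanded genomes rarely exceed it).  Expansion shows
as equal locus rates but an excess of long arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .arrays import RepeatArray, Thresholds, normalize_per_100mb
from .motifs import MotifClass, canonical_class

__all__ = [
    "LengthSpectrum",
    "PeriodicityResult",
    "GroupComparison",
    "build_spectrum",
    "count_loci",
    "count_loci_by_class",
    "phase_periodicity",
    "compare_groups",
    "DEFAULT_LONG_THRESHOLD_BP",
]

DEFAULT_LONG_THRESHOLD_BP = 50


@dataclass
class LengthSpectrum:
    """Per-class histogram of array lengths.

    ``normalized[L] = counts[L] * norm_base / total_bases``.
    """

    motif_class: MotifClass
    counts: dict[int, int]
    total_bases: int
    norm_base: int = 100_000_000
    normalized: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.normalized:
            self.normalized = {
                L: normalize_per_100mb(c, self.total_bases, self.norm_base)
                for L, c in self.counts.items()
            }

    @property
    def n_arrays(self) -> int:
        return sum(self.counts.values())

    def lengths(self) -> list[int]:
        """All array lengths, with multiplicity."""
        out: list[int] = []
        for L in sorted(self.counts):
            out.extend([L] * self.counts[L])
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (str(self.motif_class), L, self.counts[L], self.normalized[L])
            for L in sorted(self.counts)
        ]
        return pd.DataFrame(
            rows, columns=["motif_class", "length_bp", "count", "per_100mb"]
        )


@dataclass
class PeriodicityResult:
    """Chi-square test of array-length phases against uniformity.

    phase_counts[r] is the number of arrays whose length is congruent
    to r modulo the motif period.  A strongly non-uniform phase
    distribution is the signature of length periodicity ("peaks every
    k bp") in the spectrum.  ``degenerate`` flags totals below 5 counts
    per phase, where the chi-square approximation is unreliable.
    """

    period: int
    phase_counts: dict[int, int]
    modal_phase: int
    statistic: float
    p_value: float
    degenerate: bool


@dataclass
class GroupComparison:
    """Per-class locus and long-array rates for two groups and ratios.

    ``*_defined`` is False when the denominator (group B rate) is zero;
    the corresponding ratio is NaN then, never infinite.
    """

    motif_class: MotifClass
    loci_count_a: float
    loci_count_b: float
    loci_ratio: float
    loci_ratio_defined: bool
    long_count_a: float
    long_count_b: float
    long_ratio: float
    long_ratio_defined: bool
    long_threshold_bp: int


def _filter_class(
    arrays: Iterable[RepeatArray], motif_class: MotifClass | str
) -> list[RepeatArray]:
    if isinstance(motif_class, str):
        motif_class = canonical_class(motif_class)
    return [a for a in arrays if a.motif_class == motif_class]


def build_spectrum(
    arrays: Iterable[RepeatArray],
    motif_class: MotifClass | str,
    total_bases: int,
    internal_only: bool = False,
    norm_base: int = 100_000_000,
) -> LengthSpectrum:
    """Histogram of array lengths for one motif class.

    Arrays not of *motif_class* are filtered out, so mixed input is
    accepted.  With ``internal_only`` (appropriate for read data, where
    a terminal array's genomic length is censored) only arrays with
    both ends strictly inside their sequence are counted.
    """
    if isinstance(motif_class, str):
        motif_class = canonical_class(motif_class)
    counts: dict[int, int] = {}
    for a in _filter_class(arrays, motif_class):
        if internal_only and a.edge != "internal":
            continue
        counts[a.length_bp] = counts.get(a.length_bp, 0) + 1
    return LengthSpectrum(motif_class, counts, total_bases, norm_base)


def count_loci(
    arrays: Iterable[RepeatArray],
    total_bases: int,
    thresholds: Thresholds = Thresholds(),
) -> float:
    """Per-100-Mb rate of arrays with >= min_units_locus whole units."""
    n = sum(1 for a in arrays if a.unit_count >= thresholds.min_units_locus)
    return normalize_per_100mb(n, total_bases, thresholds.norm_base)


def count_loci_by_class(
    arrays: Iterable[RepeatArray],
    total_bases: int,
    thresholds: Thresholds = Thresholds(),
) -> dict[MotifClass, float]:
    """Per-class per-100-Mb locus rates."""
    by: dict[MotifClass, int] = {}
    for a in arrays:
        if a.unit_count >= thresholds.min_units_locus:
            by[a.motif_class] = by.get(a.motif_class, 0) + 1
    return {
        mc: normalize_per_100mb(n, total_bases, thresholds.norm_base)
        for mc, n in by.items()
    }


def phase_periodicity(spectrum: LengthSpectrum) -> PeriodicityResult:
    """Test length-mod-period phases of a spectrum against uniformity.

    Raises
    ------
    ValueError
        For period-1 (mononucleotide) spectra, where phases are
        undefined, or an empty spectrum.
    """
    k = spectrum.motif_class.period
    if k < 2:
        raise ValueError("phases are undefined for mononucleotide arrays")
    if not spectrum.counts:
        raise ValueError("empty spectrum")
    phase_counts = {r: 0 for r in range(k)}
    for L, c in spectrum.counts.items():
        phase_counts[L % k] += c
    total = sum(phase_counts.values())
    observed = np.array([phase_counts[r] for r in range(k)], dtype=float)
    stat, p = stats.chisquare(observed)
    modal = int(np.argmax(observed))
    return PeriodicityResult(
        period=k,
        phase_counts=phase_counts,
        modal_phase=modal,
        statistic=float(stat),
        p_value=float(p),
        degenerate=total < 5 * k,
    )


def compare_groups(
    arrays_a: Sequence[RepeatArray],
    arrays_b: Sequence[RepeatArray],
    bases_a: int,
    bases_b: int,
    long_threshold_bp: int = DEFAULT_LONG_THRESHOLD_BP,
    thresholds: Thresholds = Thresholds(),
) -> dict[MotifClass, GroupComparison]:
    """Descriptive per-class rate comparison between two groups.

    For each motif class present in either group, reports per-100-Mb
    locus rates (arrays of >= min_units_locus units), per-100-Mb rates
    of arrays >= *long_threshold_bp*, and the A/B ratios.  Array
    expansion without new-locus formation shows as loci_ratio close to
    1 together with long_ratio above 1.  Ratios with zero denominators
    are flagged undefined (NaN), not returned infinite.
    """
    classes = {a.motif_class for a in arrays_a} | {a.motif_class for a in arrays_b}
    out: dict[MotifClass, GroupComparison] = {}
    for mc in classes:
        ga = [a for a in arrays_a if a.motif_class == mc]
        gb = [a for a in arrays_b if a.motif_class == mc]
        loci_a = count_loci(ga, bases_a, thresholds)
        loci_b = count_loci(gb, bases_b, thresholds)
        long_a = normalize_per_100mb(
            sum(1 for a in ga if a.length_bp >= long_threshold_bp),
            bases_a,
            thresholds.norm_base,
        )
        long_b = normalize_per_100mb(
            sum(1 for a in gb if a.length_bp >= long_threshold_bp),
            bases_b,
            thresholds.norm_base,
        )
        loci_ok = loci_b > 0
        long_ok = long_b > 0
        out[mc] = GroupComparison(
            motif_class=mc,
            loci_count_a=loci_a,
            loci_count_b=loci_b,
            loci_ratio=loci_a / loci_b if loci_ok else float("nan"),
            loci_ratio_defined=loci_ok,
            long_count_a=long_a,
            long_count_b=long_b,
            long_ratio=long_a / long_b if long_ok else float("nan"),
            long_ratio_defined=long_ok,
            long_threshold_bp=long_threshold_bp,
        )
    return out


def comparison_frame(
    comparisons: Mapping[MotifClass, GroupComparison]
) -> pd.DataFrame:
    """Flat table of a :func:`compare_groups` result."""
    rows = []
    for mc in sorted(comparisons, key=lambda m: (m.period, m.canonical)):
        c = comparisons[mc]
        rows.append(
            {
                "motif_class": mc.canonical,
                "period": mc.period,
                "loci_a_per100mb": c.loci_count_a,
                "loci_b_per100mb": c.loci_count_b,
                "loci_ratio": c.loci_ratio,
                "long_a_per100mb": c.long_count_a,
                "long_b_per100mb": c.long_count_b,
                "long_ratio": c.long_ratio,
                "long_threshold_bp": c.long_threshold_bp,
            }
        )
    return pd.DataFrame(rows)
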