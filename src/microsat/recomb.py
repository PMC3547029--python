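"""Windowed abundance of long phase-specific arrays along a chromosome.

Counts arrays longer than a strict threshold (default > 16 bp), of one
motif class and optionally one (start, end) phase, in 20-kb tiles along
a chromosome, and aligns the track with a recombination-rate map
(tab-separated chrom / position / rate in cM/Mb) to ask whether repeat
abundance tracks local recombination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .arrays import RepeatArray, Thresholds
from .motifs import MotifClass, canonical_class

__all__ = ["WindowTrack", "windowed_abundance", "track_correlation"]


@dataclass
class WindowTrack:
    """Per-window array counts along one chromosome.

    Windows tile the chromosome without overlap (a trailing partial
    window is kept and flagged).  ``rate`` is filled in by
    :func:`track_correlation`; NaN where the map has no coverage.
    """

    chrom: str
    windows: list[tuple[int, int]]
    abundance: np.ndarray
    partial_last: bool
    rate: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": self.chrom,
                "win_start": [w[0] for w in self.windows],
                "win_end": [w[1] for w in self.windows],
                "abundance": self.abundance,
            }
        )
        if self.rate is not None:
            df["rate"] = self.rate
        return df


def windowed_abundance(
    arrays: Sequence[RepeatArray],
    chrom_len: int,
    motif_class: MotifClass | str,
    start_end_filter: tuple[str, str] | None = None,
    thresholds: Thresholds = Thresholds(),
    step: int | None = None,
    chrom: str | None = None,
) -> WindowTrack:
    """Count qualifying arrays per window along one chromosome.

    Qualifying arrays match *motif_class*, are strictly longer than
    ``thresholds.recomb_min_bp``, and (when *start_end_filter* is given)
    carry exactly that (start k-mer, end k-mer) phase.  Arrays are
    binned by the window containing their midpoint.  *step* defaults to
    the window width (non-overlapping tiles); a smaller step produces a
    true sliding window, in which case an array may fall in several
    windows and the conservation of totals no longer holds.
    """
    if chrom_len <= 0:
        raise ValueError("chrom_len must be positive")
    if isinstance(motif_class, str):
        motif_class = canonical_class(motif_class)
    width = thresholds.recomb_window_bp
    if step is None:
        step = width
    if step <= 0 or step > width:
        raise ValueError("step must be in (0, window width]")
    windows = []
    pos = 0
    while pos < chrom_len:
        windows.append((pos, min(pos + width, chrom_len)))
        pos += step
    partial_last = windows[-1][1] - windows[-1][0] < width
    counts = np.zeros(len(windows), dtype=np.int64)
    starts = np.array([w[0] for w in windows])
    for a in arrays:
        if a.motif_class != motif_class:
            continue
        if a.length_bp <= thresholds.recomb_min_bp:
            continue
        if start_end_filter is not None and (
            a.start_kmer,
            a.end_kmer,
        ) != tuple(start_end_filter):
            continue
        mid = a.midpoint
        # all windows whose [w0, w0+width) contains mid
        first = int(np.searchsorted(starts, mid - width, side="right"))
        last = int(np.searchsorted(starts, mid, side="right"))
        for w in range(first, last):
            if windows[w][0] <= mid < windows[w][1]:
                counts[w] += 1
    name = chrom or (arrays[0].seq_id if arrays else "chrom")
    return WindowTrack(
        chrom=name, windows=windows, abundance=counts, partial_last=partial_last
    )


def track_correlation(
    track: WindowTrack, recomb_map: pd.DataFrame
) -> dict:
    """Align a window track with a recombination map; Spearman correlation.

    The map is a DataFrame with columns (chrom, pos, rate); rates are
    piecewise-constant between consecutive positions.  Window mean rate
    is the increment of the cumulative genetic map across the window,
    obtained by linear interpolation of the cumulative map at window
    boundaries, divided by window width.  Windows without map coverage
    are flagged absent (NaN) and excluded from the correlation.

    Returns a dict with keys ``rho``, ``p_value``, ``n_windows``,
    ``defined`` (False for zero-variance inputs) and ``table`` (the
    aligned DataFrame).

    Raises
    ------
    ValueError
        If the map and track coordinate ranges are disjoint.
    """
    m = recomb_map
    if "chrom" in m.columns:
        m = m[m["chrom"] == track.chrom]
    m = m.sort_values("pos")
    pos = m["pos"].to_numpy(dtype=float)
    rate = m["rate"].to_numpy(dtype=float)
    if len(pos) < 2:
        raise ValueError("recombination map needs at least two points")
    w0 = np.array([w[0] for w in track.windows], dtype=float)
    w1 = np.array([w[1] for w in track.windows], dtype=float)
    if pos[-1] <= w0[0] or pos[0] >= w1[-1]:
        raise ValueError("recombination map does not overlap the track")
    # cumulative genetic distance; rate[i] applies on [pos[i], pos[i+1])
    cum = np.concatenate(([0.0], np.cumsum(rate[:-1] * np.diff(pos))))
    covered = (w0 >= pos[0]) & (w1 <= pos[-1])
    win_rate = np.full(len(w0), np.nan)
    c0 = np.interp(w0[covered], pos, cum)
    c1 = np.interp(w1[covered], pos, cum)
    win_rate[covered] = (c1 - c0) / (w1[covered] - w0[covered])
    track.rate = win_rate
    table = track.to_frame()
    ok = ~np.isnan(win_rate)
    ab = track.abundance[ok].astype(float)
    rt = win_rate[ok]
    defined = len(ab) >= 3 and np.ptp(ab) > 0 and np.ptp(rt) > 0
    if defined:
        rho, p = stats.spearmanr(ab, rt)
        rho, p = float(rho), float(p)
    else:
        rho, p = float("nan"), float("nan")
    return {
        "rho": rho,
        "p_value": p,
        "n_windows": int(ok.sum()),
        "defined": defined,
        "table": table,
    }
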