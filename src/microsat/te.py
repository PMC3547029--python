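"""Microsatellite occurrence in transposable-element flanks.

A TE is microsatellite-associated when at least ``min_flank_array_bp``
(default 10) bases of a perfect array of period 1-3 fall inside the
50-bp windows immediately upstream of its 5' boundary and downstream of
its 3' boundary.  Windows are orientation-normalized into a 1-100
coordinate frame (1-50 upstream of the 5' end, 51-100 downstream of the
3' end, position 1 most 5'-distal) so that sense and antisense
insertions align.

Significance is assessed against a positional shuffle null: each TE is
repositioned uniformly at random on its own chromosome (length and
strand preserved, overlaps permitted), the associated proportion is
recomputed per replicate, and the enrichment fold is the observed
proportion over the null mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .arrays import RepeatArray, Thresholds, find_arrays
from .motifs import MotifClass

__all__ = [
    "TEAnnotation",
    "FlankPair",
    "FlankProfile",
    "EnrichmentResult",
    "parse_repeatmasker_out",
    "parse_te_bed",
    "extract_flank_windows",
    "ArrayIndex",
    "flank_position_profile",
    "proportion_with_array",
    "shuffle_null",
    "enrichment",
]

logger = logging.getLogger(__name__)

TE_GROUPS = ("DNA", "LTR", "LINE", "SINE", "other")


@dataclass(frozen=True)
class TEAnnotation:
    """One transposable-element hit, 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    te_group: str
    family: str = ""
    divergence_pct: float = 0.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty TE interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FlankPair:
    """Oriented +-50 bp windows around one TE.

    ``upstream_window`` / ``downstream_window`` are genomic intervals
    (0-based half-open) relative to the TE's 5' and 3' ends after strand
    normalization; ``truncated`` flags clipping at chromosome edges.
    """

    te: TEAnnotation
    upstream_window: tuple[int, int]
    downstream_window: tuple[int, int]
    truncated: bool

    def oriented_position(self, genomic: int) -> int | None:
        """Map a genomic coordinate to the 1-100 oriented frame.

        Positions 1-50 run across the upstream window toward the 5' end;
        51-100 run from the 3' end outward.  None if outside both windows.
        """
        te, w = self.te, self.te.strand
        u0, u1 = self.upstream_window
        d0, d1 = self.downstream_window
        fw = 50
        if w == "+":
            if u0 <= genomic < u1:
                return genomic - te.start + fw + 1  # start-50 -> 1
            if d0 <= genomic < d1:
                return fw + 1 + (genomic - te.end)
        else:
            if u0 <= genomic < u1:
                return te.end + fw - genomic  # end+49 -> 1
            if d0 <= genomic < d1:
                return fw + (te.start - genomic)  # start-1 -> 51
        return None


def _te_group_of(class_family: str) -> str:
    head = class_family.split("/")[0].rstrip("?").upper()
    for g in ("DNA", "LTR", "LINE", "SINE"):
        if head == g:
            return g
    return "other"


def parse_repeatmasker_out(
    path, thresholds: Thresholds = Thresholds()
) -> list[TEAnnotation]:
    """Parse a RepeatMasker ``.out`` annotation file.

    The standard layout has two header lines plus a blank line, then
    whitespace-delimited hits: score, %div, %del, %ins, query, begin,
    end, (left), strand (+ or C), repeat name, class/family, ...
    Coordinates (1-based inclusive) are converted to 0-based half-open;
    "C" orientation becomes "-"; class/family is mapped to one of
    DNA/LTR/LINE/SINE/other by its prefix.  Hits above the divergence
    threshold are dropped; malformed lines are skipped with a logged
    warning count.

    Raises
    ------
    ValueError
        If no line in the file can be parsed as a hit.
    """
    tes: list[TEAnnotation] = []
    skipped = 0
    parsed_any = False
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            # header lines start with "SW"/"score" or "bit"
            if fields[0].lower() in ("sw", "score", "bit"):
                continue
            try:
                div = float(fields[1])
                chrom = fields[4]
                start = int(fields[5]) - 1
                end = int(fields[6])
                strand = "-" if fields[8] in ("C", "-") else "+"
                family = fields[9]
                class_family = fields[10]
            except (IndexError, ValueError):
                skipped += 1
                continue
            parsed_any = True
            if div > thresholds.rm_max_divergence_pct:
                continue
            tes.append(
                TEAnnotation(
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    te_group=_te_group_of(class_family),
                    family=family,
                    divergence_pct=div,
                )
            )
    if skipped:
        logger.warning("parse_repeatmasker_out: skipped %d malformed lines", skipped)
    if not parsed_any:
        raise ValueError(f"no RepeatMasker hits parseable in {path}")
    return tes


def parse_te_bed(path) -> list[TEAnnotation]:
    """BED fallback: chrom, start, end, name (group[/family]), score, strand."""
    tes: list[TEAnnotation] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else "other"
            strand = f[5] if len(f) > 5 else "+"
            tes.append(
                TEAnnotation(
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    te_group=_te_group_of(name),
                    family=name,
                )
            )
    return tes


def extract_flank_windows(
    chrom_len: int, te: TEAnnotation, thresholds: Thresholds = Thresholds()
) -> FlankPair:
    """The +-50 bp windows of one TE, orientation-normalized.

    For a + strand TE the upstream (5') window is [start-50, start) and
    the downstream (3') window [end, end+50); for a - strand TE they are
    swapped (upstream = [end, end+50), downstream = [start-50, start))
    and read outward from the element.  Windows are clipped at
    chromosome edges and flagged truncated.
    """
    if te.length > chrom_len:
        raise ValueError(
            f"TE of length {te.length} exceeds chromosome length {chrom_len}"
        )
    fw = thresholds.flank_window_bp
    left = (max(0, te.start - fw), te.start)
    right = (te.end, min(chrom_len, te.end + fw))
    truncated = left[0] > te.start - fw or right[1] < te.end + fw
    if te.strand == "+":
        up, down = left, right
    else:
        up, down = right, left
    return FlankPair(
        te=te, upstream_window=up, downstream_window=down, truncated=truncated
    )


class ArrayIndex:
    """Interval index over arrays of one chromosome for fast flank queries.

    Only arrays of qualifying periods and length >= *min_bp* are kept
    (shorter arrays can never contribute min_bp bases to a window).
    Precomputes, for full windows of width *window_bp*, the merged set
    of window starts at which some single array overlaps by >= min_bp;
    truncated windows fall back to the exact per-window computation.
    """

    def __init__(
        self,
        arrays: Sequence[RepeatArray],
        min_bp: int = 10,
        window_bp: int = 50,
        periods: tuple[int, ...] = (1, 2, 3),
    ):
        kept = sorted(
            (a for a in arrays if a.period in periods and a.length_bp >= min_bp),
            key=lambda a: a.start,
        )
        self.arrays = kept
        self.min_bp = min_bp
        self.window_bp = window_bp
        self.starts = np.array([a.start for a in kept], dtype=np.int64)
        self.ends = np.array([a.end for a in kept], dtype=np.int64)
        self.max_len = int((self.ends - self.starts).max()) if kept else 0
        # window start w qualifies iff w in [a.start - (window_bp - min_bp), a.end - min_bp]
        if kept:
            lo = self.starts - (window_bp - min_bp)
            hi = self.ends - min_bp + 1  # half-open
            order = np.argsort(lo)
            merged_lo, merged_hi = [], []
            for l, h in zip(lo[order], hi[order]):
                if merged_hi and l <= merged_hi[-1]:
                    merged_hi[-1] = max(merged_hi[-1], h)
                else:
                    merged_lo.append(l)
                    merged_hi.append(h)
            self._q_lo = np.array(merged_lo, dtype=np.int64)
            self._q_hi = np.array(merged_hi, dtype=np.int64)
        else:
            self._q_lo = np.zeros(0, dtype=np.int64)
            self._q_hi = np.zeros(0, dtype=np.int64)

    def full_window_qualifies(self, w0: np.ndarray) -> np.ndarray:
        """Vectorized: does the full window starting at each w0 contain
        >= min_bp bases of a single array?"""
        if self._q_lo.size == 0:
            return np.zeros(len(w0), dtype=bool)
        idx = np.searchsorted(self._q_lo, w0, side="right") - 1
        ok = idx >= 0
        ok[ok] = w0[ok] < self._q_hi[idx[ok]]
        return ok

    def overlaps_in(self, w0: int, w1: int) -> list[tuple[int, int, int]]:
        """(array index, overlap bp, clipped start) for arrays hitting [w0, w1)."""
        if self.starts.size == 0 or w1 <= w0:
            return []
        lo = np.searchsorted(self.starts, w0 - self.max_len)
        hi = np.searchsorted(self.starts, w1)
        out = []
        for i in range(lo, hi):
            o0 = max(int(self.starts[i]), w0)
            o1 = min(int(self.ends[i]), w1)
            if o1 > o0:
                out.append((i, o1 - o0, o0))
        return out

    def window_overlap_ge(self, w0: int, w1: int) -> bool:
        """Exact single-window test: any array with >= min_bp overlap."""
        return any(ov >= self.min_bp for _, ov, _ in self.overlaps_in(w0, w1))

    def pair_qualifies(self, pair: FlankPair) -> bool:
        """Does the TE have >= min_bp bases of one array in its windows?

        Overlap is summed per array across both windows, so an array
        spanning the whole element still qualifies.
        """
        u0, u1 = pair.upstream_window
        d0, d1 = pair.downstream_window
        per_array: dict[int, int] = {}
        for w0, w1 in ((u0, u1), (d0, d1)):
            for i, ov, _ in self.overlaps_in(w0, w1):
                per_array[i] = per_array.get(i, 0) + ov
        return any(v >= self.min_bp for v in per_array.values())


@dataclass
class FlankProfile:
    """Positional microsatellite occurrence around TEs of one group.

    ``position_counts[canonical][p]`` (p in 1..100) is the number of TEs
    for which a qualifying array covers oriented position p.
    """

    te_group: str
    n_te: int
    position_counts: dict[str, np.ndarray]
    proportion_with_array: float

    def to_frame(self) -> pd.DataFrame:
        data = {"position": np.arange(1, 101)}
        for cls in sorted(self.position_counts):
            data[cls] = self.position_counts[cls]
        return pd.DataFrame(data)


def _build_indexes(
    genome: Mapping[str, str],
    thresholds: Thresholds,
    periods: tuple[int, ...] = (1, 2, 3),
    arrays_by_chrom: Mapping[str, Sequence[RepeatArray]] | None = None,
) -> dict[str, ArrayIndex]:
    out = {}
    for chrom, seq in genome.items():
        if arrays_by_chrom is not None and chrom in arrays_by_chrom:
            arrs = arrays_by_chrom[chrom]
        else:
            arrs = find_arrays(
                seq,
                k_min=min(periods),
                k_max=max(periods),
                min_len_bp=thresholds.min_flank_array_bp,
                seq_id=chrom,
            )
        out[chrom] = ArrayIndex(
            arrs,
            min_bp=thresholds.min_flank_array_bp,
            window_bp=thresholds.flank_window_bp,
            periods=periods,
        )
    return out


def flank_position_profile(
    tes: Sequence[TEAnnotation],
    genome: Mapping[str, str],
    thresholds: Thresholds = Thresholds(),
    periods: tuple[int, ...] = (1, 2, 3),
    arrays_by_chrom: Mapping[str, Sequence[RepeatArray]] | None = None,
) -> dict[str, FlankProfile]:
    """Per-TE-group positional profile and associated proportion.

    A TE counts as microsatellite-associated when >= min_flank_array_bp
    bases of one perfect array (periods 1-3 by default) lie in its
    oriented +-50 bp windows; position counts increment at every
    oriented position (1-100) covered by a qualifying array.

    Raises
    ------
    ValueError
        On an empty TE set.
    """
    if not tes:
        raise ValueError("empty TE set")
    indexes = _build_indexes(genome, thresholds, periods, arrays_by_chrom)
    groups: dict[str, list[TEAnnotation]] = {}
    for te in tes:
        groups.setdefault(te.te_group, []).append(te)
    profiles: dict[str, FlankProfile] = {}
    for group, members in groups.items():
        counts: dict[str, np.ndarray] = {}
        n_with = 0
        for te in members:
            idx = indexes[te.chrom]
            pair = extract_flank_windows(
                len(genome[te.chrom]), te, thresholds
            )
            # per-array overlap summed over both windows
            per_array: dict[int, list[tuple[int, int]]] = {}
            for w0, w1 in (pair.upstream_window, pair.downstream_window):
                for i, ov, o0 in idx.overlaps_in(w0, w1):
                    per_array.setdefault(i, []).append((o0, o0 + ov))
            qualifying = {
                i: segs
                for i, segs in per_array.items()
                if sum(b - a for a, b in segs) >= thresholds.min_flank_array_bp
            }
            if qualifying:
                n_with += 1
            for i, segs in qualifying.items():
                cls = idx.arrays[i].motif_class.canonical
                vec = counts.setdefault(cls, np.zeros(100, dtype=np.int64))
                covered = set()
                for a, b in segs:
                    for g in range(a, b):
                        p = pair.oriented_position(g)
                        if p is not None:
                            covered.add(p)
                for p in covered:
                    vec[p - 1] += 1
        profiles[group] = FlankProfile(
            te_group=group,
            n_te=len(members),
            position_counts=counts,
            proportion_with_array=n_with / len(members),
        )
    return profiles


def proportion_with_array(
    tes: Sequence[TEAnnotation],
    indexes: Mapping[str, ArrayIndex],
    chrom_sizes: Mapping[str, int],
    thresholds: Thresholds = Thresholds(),
) -> float:
    """Fraction of TEs with a qualifying array in their +-50 bp windows.

    Uses the precomputed full-window interval union for untruncated
    windows and exact overlap sums otherwise (including arrays spanning
    the whole element).
    """
    if not tes:
        raise ValueError("empty TE set")
    fw = thresholds.flank_window_bp
    by_chrom: dict[str, list[TEAnnotation]] = {}
    for te in tes:
        by_chrom.setdefault(te.chrom, []).append(te)
    n_with = 0
    for chrom, members in by_chrom.items():
        idx = indexes[chrom]
        clen = chrom_sizes[chrom]
        starts = np.array([te.start for te in members], dtype=np.int64)
        ends = np.array([te.end for te in members], dtype=np.int64)
        left_ok = starts >= fw
        right_ok = ends + fw <= clen
        qual = np.zeros(len(members), dtype=bool)
        # fast path: full windows, single-array >= min_bp
        qual[left_ok] |= idx.full_window_qualifies(starts[left_ok] - fw)
        qual[right_ok] |= idx.full_window_qualifies(ends[right_ok])
        # exact fallback: truncated windows, or straddling arrays
        straddle_possible = idx.max_len > 0
        for j, te in enumerate(members):
            if qual[j]:
                continue
            truncated = not (left_ok[j] and right_ok[j])
            if truncated:
                pair = extract_flank_windows(clen, te, thresholds)
                if idx.pair_qualifies(pair):
                    qual[j] = True
                continue
            if straddle_possible and idx.max_len >= te.length:
                pair = extract_flank_windows(clen, te, thresholds)
                if idx.pair_qualifies(pair):
                    qual[j] = True
        n_with += int(qual.sum())
    return n_with / len(tes)


def shuffle_null(
    tes: Sequence[TEAnnotation],
    chrom_sizes: Mapping[str, int],
    genome: Mapping[str, str],
    n_reps: int,
    seed: int,
    thresholds: Thresholds = Thresholds(),
    periods: tuple[int, ...] = (1, 2, 3),
    arrays_by_chrom: Mapping[str, Sequence[RepeatArray]] | None = None,
) -> list[float]:
    """Null distribution of the associated proportion under repositioning.

    Each replicate places every TE at a uniform random start on its own
    chromosome (length and strand preserved, overlaps permitted) and
    recomputes the proportion of TEs with a qualifying flank array.
    Deterministic for a given seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    for te in tes:
        if te.length > chrom_sizes[te.chrom]:
            raise ValueError(
                f"TE of length {te.length} exceeds chromosome {te.chrom}"
            )
    rng = np.random.default_rng(seed)
    indexes = _build_indexes(genome, thresholds, periods, arrays_by_chrom)
    null: list[float] = []
    for _ in range(n_reps):
        placed = []
        for te in tes:
            max_start = chrom_sizes[te.chrom] - te.length
            s = int(rng.integers(0, max_start + 1))
            placed.append(
                TEAnnotation(
                    chrom=te.chrom,
                    start=s,
                    end=s + te.length,
                    strand=te.strand,
                    te_group=te.te_group,
                    family=te.family,
                    divergence_pct=te.divergence_pct,
                )
            )
        null.append(
            proportion_with_array(placed, indexes, chrom_sizes, thresholds)
        )
    return null


@dataclass
class EnrichmentResult:
    """Observed TE-flank proportion against the shuffle null."""

    te_group: str
    observed_proportion: float
    null_mean: float
    null_sd: float
    fold: float
    fold_defined: bool
    quantile: float
    n_reps: int
    seed: int
    null_samples: list[float] = field(repr=False, default_factory=list)


def enrichment(
    observed: float,
    null_samples: Sequence[float],
    te_group: str = "all",
    seed: int = 0,
) -> EnrichmentResult:
    """Fold enrichment of the observed proportion over the null mean.

    Also reports the empirical quantile of the observed value within
    the null sample.  A zero null mean with a positive observation is
    flagged (fold undefined, returned as +inf with fold_defined False).
    """
    if not len(null_samples):
        raise ValueError("null_samples must be nonempty")
    null = np.asarray(null_samples, dtype=float)
    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if len(null) > 1 else 0.0
    if mean > 0:
        fold, defined = observed / mean, True
    elif observed == 0:
        fold, defined = float("nan"), False
    else:
        fold, defined = float("inf"), False
    quantile = float((null <= observed).mean())
    return EnrichmentResult(
        te_group=te_group,
        observed_proportion=observed,
        null_mean=mean,
        null_sd=sd,
        fold=fold,
        fold_defined=defined,
        quantile=quantile,
        n_reps=len(null),
        seed=seed,
        null_samples=list(map(float, null)),
    )
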