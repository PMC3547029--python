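"""Synthetic genomes, TE landscapes, sex pairs and read sets with truth.

The generator emulates the statistical structure the analysis assumes:

* genomes with planted perfect microsatellite arrays whose length
  distributions are controllable (geometric tails, period-k phase
  spikes, start-phase bias), placed non-overlapping with a minimum
  spacing so each planted array is recoverable at exact coordinates;
* TE landscapes where elements are annotated intervals placed uniformly
  and independently of the sequence, with a controllable probability
  (``flank_bias``) of carrying a planted qualifying array in their
  +-50 bp flanks;
* male/female genome pairs identical except for array-length expansion
  of designated classes on one chromosome, with locus counts and total
  bases equal by construction;
* read sets with 454-like lengths (truncated normal, mean 400 bp).

Background sequence is i.i.d. with a configurable base composition.
After planting, accidental arrays within 100 bp of planted arrays are
destroyed by point changes (re-draws) so planted features stay maximal
and exactly recoverable; the rest of the background is left untouched,
keeping background microsatellite rates realistic.  Everything is
deterministic given the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .arrays import RepeatArray, find_arrays
from .motifs import canonical_class, revcomp, rotations
from .te import TEAnnotation

__all__ = [
    "GeometricLength",
    "UniformLength",
    "FixedLength",
    "SpikedLength",
    "ArrayPlan",
    "TEPlan",
    "ExpansionPlan",
    "GenomeSpec",
    "PlantedArray",
    "PlantedTE",
    "TruthSet",
    "simulate_genome",
    "simulate_sex_pair",
    "fragment_reads",
    "repeat_free_filler",
    "te_study_spec",
    "sex_pair_spec",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_SCRUB_RADIUS = 100  # bp around planted arrays kept free of accidental arrays
_SCRUB_MIN_BP = 8  # accidental arrays at least this long get destroyed


# --------------------------------------------------------------------------
# length models


@dataclass(frozen=True)
class GeometricLength:
    """Shifted geometric length: min + Geometric; mean is the target mean."""

    mean: float
    min: int = 10

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.mean <= self.min:
            raise ValueError("geometric mean must exceed the minimum length")
        p = 1.0 / (self.mean - self.min + 1)
        return self.min + rng.geometric(p, size=n) - 1


@dataclass(frozen=True)
class UniformLength:
    lo: int
    hi: int  # inclusive

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.integers(self.lo, self.hi + 1, size=n)


@dataclass(frozen=True)
class FixedLength:
    lengths: tuple[int, ...] | int

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        pool = np.atleast_1d(np.asarray(self.lengths))
        if len(pool) == n:
            return pool
        return rng.choice(pool, size=n)


@dataclass(frozen=True)
class SpikedLength:
    """Base distribution with a phase spike: with probability *spike_p*
    a drawn length is snapped to the nearest length congruent to
    *residue* modulo *period* (producing peaks every k bp)."""

    base: GeometricLength | UniformLength
    period: int
    residue: int
    spike_p: float = 1.0

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        L = np.asarray(self.base.draw(rng, n), dtype=np.int64)
        snap = rng.random(n) < self.spike_p
        shift = (self.residue - L[snap]) % self.period
        L[snap] = L[snap] + shift
        return L


# --------------------------------------------------------------------------
# plans and specs


@dataclass(frozen=True)
class ArrayPlan:
    """Plan for planting arrays of one motif class.

    ``motif`` is the class as observed on the forward strand; with
    probability ``strand_p`` an array is planted as (a rotation of) the
    reverse complement.  ``start_kmer`` pins the start phase; None
    rotates uniformly.
    """

    motif: str
    n: int
    length: GeometricLength | UniformLength | FixedLength | SpikedLength
    chrom: str | None = None
    strand_p: float = 0.5
    start_kmer: str | None = None


@dataclass(frozen=True)
class TEPlan:
    """TE landscape plan.

    Elements are annotated intervals placed uniformly at random,
    independent of the sequence (overlaps with arrays and other TEs
    permitted), which is exactly the null the shuffle test assumes.
    With probability ``flank_bias`` a TE gets a planted qualifying
    array in its upstream (5') flank window.
    """

    counts: Mapping[str, int]
    length: UniformLength = UniformLength(100, 300)
    strand_p: float = 0.5
    flank_bias: float = 0.0
    flank_motif: str = "A"
    flank_len: int = 15
    flank_offset: int | None = None  # gap between array end and TE boundary

    def __post_init__(self) -> None:
        if not 0.0 <= self.flank_bias <= 1.0:
            raise ValueError("flank_bias must be in [0, 1]")
        if not 0.0 <= self.strand_p <= 1.0:
            raise ValueError("strand_p must be in [0, 1]")


@dataclass(frozen=True)
class ExpansionPlan:
    chrom: str
    classes: tuple[str, ...]  # canonical class names


@dataclass(frozen=True)
class GenomeSpec:
    chrom_lengths: Mapping[str, int]
    array_plans: tuple[ArrayPlan, ...] = ()
    te_plan: TEPlan | None = None
    expansion: ExpansionPlan | None = None
    base_comp: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    min_spacing: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.base_comp) - 1.0) > 1e-9:
            raise ValueError("base composition must sum to 1")
        if any(p < 0 for p in self.base_comp):
            raise ValueError("base composition must be nonnegative")


@dataclass(frozen=True)
class PlantedArray:
    chrom: str
    start: int
    end: int
    canonical: str
    period: int
    start_kmer: str
    length_bp: int
    is_te_flank: bool = False
    targeted: bool = False

    @property
    def unit_count(self) -> int:
        return self.length_bp // self.period


@dataclass(frozen=True)
class PlantedTE:
    chrom: str
    start: int
    end: int
    te_group: str
    strand: str
    has_planted_flank_array: bool

    def annotation(self) -> TEAnnotation:
        return TEAnnotation(
            chrom=self.chrom,
            start=self.start,
            end=self.end,
            strand=self.strand,
            te_group=self.te_group,
        )


@dataclass
class TruthSet:
    arrays: list[PlantedArray]
    tes: list[PlantedTE]
    spec: GenomeSpec

    def te_annotations(self) -> list[TEAnnotation]:
        return [t.annotation() for t in self.tes]

    def arrays_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(a) for a in self.arrays])

    def tes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": t.chrom,
                    "start": t.start,
                    "end": t.end,
                    "te_group": t.te_group,
                    "strand": t.strand,
                    "has_planted_flank_array": t.has_planted_flank_array,
                }
                for t in self.tes
            ]
        )


# --------------------------------------------------------------------------
# helpers


def _periodic(start_kmer: str, length: int) -> str:
    k = len(start_kmer)
    return (start_kmer * (length // k + 2))[:length]


def _choose_base(rng: np.random.Generator, avoid: set[int]) -> int:
    choices = [b for b in range(4) if b not in avoid]
    return int(choices[rng.integers(len(choices))])


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


class _Occupancy:
    """Sorted planted intervals for spacing-aware collision checks."""

    def __init__(self, spacing: int):
        self.starts: list[int] = []
        self.ends: list[int] = []
        self.spacing = spacing

    def collides(self, start: int, end: int) -> bool:
        s = np.asarray(self.starts)
        e = np.asarray(self.ends)
        if s.size == 0:
            return False
        return bool(((start < e + self.spacing) & (end + self.spacing > s)).any())

    def add(self, start: int, end: int) -> None:
        self.starts.append(start)
        self.ends.append(end)


_CODE_OF = {"A": 0, "C": 1, "G": 2, "T": 3}


def _plant_array(codes: np.ndarray, start: int, seq: str) -> None:
    codes[start : start + len(seq)] = np.fromiter(
        (_CODE_OF[ch] for ch in seq), dtype=np.uint8, count=len(seq)
    )


def _break_flanks(
    codes: np.ndarray, start: int, end: int, k: int, rng: np.random.Generator
) -> None:
    """Ensure extending the planted array one base either way fails."""
    n = len(codes)
    if start > 0:
        avoid = {int(codes[start - 1 + k])}
        if start > 1:
            avoid.add(int(codes[start - 2]))
        if int(codes[start - 1]) in avoid:
            codes[start - 1] = _choose_base(rng, avoid)
    if end < n:
        avoid = {int(codes[end - k])}
        if end + 1 < n:
            avoid.add(int(codes[end + 1]))
        if int(codes[end]) in avoid:
            codes[end] = _choose_base(rng, avoid)


def _near_any(
    a_start: int, a_end: int, spans: Sequence[tuple[int, int]], radius: int
) -> bool:
    return any(a_start < e + radius and a_end > s - radius for s, e in spans)


def _scrub_chromosome(
    codes: np.ndarray,
    planted: Sequence[PlantedArray],
    rng: np.random.Generator,
    max_iter: int = 80,
) -> None:
    """Destroy accidental arrays within _SCRUB_RADIUS of planted arrays
    and re-assert exact recoverability of every planted array."""
    if not planted:
        return
    spans = [(p.start, p.end) for p in planted]
    planted_keys = {(p.start, p.end, p.period) for p in planted}
    planted_by_span = {(p.start, p.end): p for p in planted}
    in_planted = np.zeros(len(codes), dtype=bool)
    for s, e in spans:
        in_planted[s:e] = True
    min_scan = min(_SCRUB_MIN_BP, min(p.length_bp for p in planted))
    for _ in range(max_iter):
        found = find_arrays(_codes_to_str(codes), 1, 3, min_scan)
        found_keys = {(a.start, a.end, a.period) for a in found}
        dirty = False
        # re-break flanks of planted arrays not recovered exactly
        for (s, e), p in planted_by_span.items():
            if (s, e, p.period) not in found_keys:
                _break_flanks(codes, s, e, p.period, rng)
                dirty = True
        # point-mutate accidental arrays near planted ones
        for a in found:
            if (a.start, a.end, a.period) in planted_keys:
                continue
            if not _near_any(a.start, a.end, spans, _SCRUB_RADIUS):
                continue
            free = [i for i in range(a.start, a.end) if not in_planted[i]]
            if not free:  # fully inside a planted span: impossible by maximality
                continue
            pos = free[len(free) // 2]
            avoid = {int(codes[pos])}
            if pos > 0:
                avoid.add(int(codes[pos - 1]))
            if pos + 1 < len(codes):
                avoid.add(int(codes[pos + 1]))
            codes[pos] = _choose_base(rng, avoid)
            dirty = True
        if not dirty:
            return
    raise RuntimeError("scrub did not converge; packing too dense")


# --------------------------------------------------------------------------
# main entry points


def simulate_genome(spec: GenomeSpec) -> tuple[dict[str, str], TruthSet]:
    """Generate a genome with planted arrays and TE annotations.

    Returns (chrom -> sequence, truth).  Every planted array is
    recoverable by the scanner at exact coordinates; TEs are interval
    annotations placed uniformly, independent of the sequence, except
    that flank-biased TEs get a qualifying array written into their
    5' flank window.

    Raises
    ------
    ValueError
        When requested features cannot be packed into a chromosome at
        the required spacing ("infeasible packing").
    """
    rng = np.random.default_rng(spec.seed)
    chrom_codes: dict[str, np.ndarray] = {}
    occupancy: dict[str, _Occupancy] = {}
    comp = np.asarray(spec.base_comp)
    for chrom, clen in spec.chrom_lengths.items():
        chrom_codes[chrom] = rng.choice(4, size=clen, p=comp).astype(np.uint8)
        occupancy[chrom] = _Occupancy(spec.min_spacing)

    planted_arrays: list[PlantedArray] = []
    targeted_classes = set(spec.expansion.classes) if spec.expansion else set()

    def place_array(chrom: str, seq: str, canonical: str, start_kmer: str,
                    is_te_flank: bool = False, fixed_start: int | None = None) -> PlantedArray | None:
        codes = chrom_codes[chrom]
        occ = occupancy[chrom]
        L = len(seq)
        if fixed_start is not None:
            starts = [fixed_start]
        else:
            starts = rng.integers(0, len(codes) - L + 1, size=300).tolist()
        for s in starts:
            if occ.collides(s, s + L):
                continue
            _plant_array(codes, s, seq)
            occ.add(s, s + L)
            targeted = (
                spec.expansion is not None
                and chrom == spec.expansion.chrom
                and canonical in targeted_classes
                and not is_te_flank
            )
            pa = PlantedArray(
                chrom=chrom,
                start=int(s),
                end=int(s + L),
                canonical=canonical,
                period=len(start_kmer),
                start_kmer=start_kmer,
                length_bp=L,
                is_te_flank=is_te_flank,
                targeted=targeted,
            )
            planted_arrays.append(pa)
            return pa
        return None

    # planted background arrays
    for plan in spec.array_plans:
        chroms = (
            [plan.chrom]
            if plan.chrom is not None
            else list(spec.chrom_lengths)
        )
        canonical = canonical_class(plan.motif).canonical
        lengths = plan.length.draw(rng, plan.n)
        for i in range(plan.n):
            chrom = chroms[int(rng.integers(len(chroms)))] if len(chroms) > 1 else chroms[0]
            motif = plan.motif
            if rng.random() < plan.strand_p:
                motif = revcomp(motif)
            if plan.start_kmer is not None:
                start_kmer = plan.start_kmer
            else:
                rots = rotations(motif)
                start_kmer = rots[int(rng.integers(len(rots)))]
            L = int(lengths[i])
            if L < len(start_kmer):
                L = len(start_kmer)
            seq = _periodic(start_kmer, L)
            if place_array(chrom, seq, canonical, start_kmer) is None:
                raise ValueError(
                    f"infeasible packing: could not place array {i + 1}/{plan.n} "
                    f"of class {canonical} on {chrom} at spacing {spec.min_spacing}"
                )

    # TE landscape: uniform interval annotations, optional planted flank array
    planted_tes: list[PlantedTE] = []
    if spec.te_plan is not None:
        tp = spec.te_plan
        chroms = list(spec.chrom_lengths)
        fl_canonical = canonical_class(tp.flank_motif).canonical
        for group, n in tp.counts.items():
            te_lens = tp.length.draw(rng, n)
            for i in range(n):
                te_len = int(te_lens[i])
                strand = "-" if rng.random() < tp.strand_p else "+"
                biased = rng.random() < tp.flank_bias
                placed = False
                for _ in range(300):
                    chrom = chroms[int(rng.integers(len(chroms)))] if len(chroms) > 1 else chroms[0]
                    clen = spec.chrom_lengths[chrom]
                    if te_len > clen:
                        raise ValueError(
                            f"infeasible packing: TE length {te_len} exceeds "
                            f"chromosome {chrom}"
                        )
                    s = int(rng.integers(0, clen - te_len + 1))
                    if not biased:
                        placed = True
                        break
                    # plant a qualifying array in the 5' flank window
                    if tp.flank_offset is None:
                        gap = int(rng.integers(0, 50 - tp.flank_len + 1))
                    else:
                        gap = tp.flank_offset
                    if strand == "+":
                        a_start = s - gap - tp.flank_len
                        a_end = s - gap
                    else:
                        a_start = s + te_len + gap
                        a_end = a_start + tp.flank_len
                    if a_start < 0 or a_end > clen:
                        continue
                    if occupancy[chrom].collides(a_start, a_end):
                        continue
                    seq = _periodic(tp.flank_motif, tp.flank_len)
                    place_array(
                        chrom,
                        seq,
                        fl_canonical,
                        tp.flank_motif,
                        is_te_flank=True,
                        fixed_start=a_start,
                    )
                    placed = True
                    break
                if not placed:
                    raise ValueError(
                        f"infeasible packing: could not place biased TE on any "
                        f"chromosome (group {group})"
                    )
                planted_tes.append(
                    PlantedTE(
                        chrom=chrom,
                        start=s,
                        end=s + te_len,
                        te_group=group,
                        strand=strand,
                        has_planted_flank_array=biased,
                    )
                )

    # flank breaks, then scrub accidental arrays near planted ones
    by_chrom: dict[str, list[PlantedArray]] = {}
    for pa in planted_arrays:
        by_chrom.setdefault(pa.chrom, []).append(pa)
    for chrom, codes in chrom_codes.items():
        for pa in by_chrom.get(chrom, []):
            _break_flanks(codes, pa.start, pa.end, pa.period, rng)
        _scrub_chromosome(codes, by_chrom.get(chrom, []), rng)

    genome = {c: _codes_to_str(codes) for c, codes in chrom_codes.items()}
    planted_arrays.sort(key=lambda p: (p.chrom, p.start))
    return genome, TruthSet(arrays=planted_arrays, tes=planted_tes, spec=spec)


def _expanded_length(L: int, k: int, multiplier: float) -> int:
    """Target length after expansion, rounded to preserve the phase
    (new length congruent to the old modulo the period)."""
    delta = int(round(L * (multiplier - 1.0)))
    delta -= delta % k
    return L + delta


def simulate_sex_pair(
    spec: GenomeSpec, expansion_multiplier: float
) -> tuple[dict[str, str], dict[str, str], TruthSet, TruthSet]:
    """A "female"/"male" genome pair differing only by array expansion.

    The female genome follows *spec*; the male genome is identical
    except that the lengths of targeted-class planted arrays on the
    designated chromosome are multiplied (phase-preserving rounding).
    The female's designated chromosome is padded with a repeat-free
    filler of exactly the total expansion, so locus counts *and* total
    bases are equal by construction and per-100-Mb locus rates match
    exactly.

    Returns (female genome, male genome, female truth, male truth).
    """
    if expansion_multiplier < 1:
        raise ValueError("expansion multiplier must be >= 1")
    if spec.expansion is None:
        raise ValueError("spec.expansion must designate chromosome and classes")
    female, truth = simulate_genome(spec)
    tchrom = spec.expansion.chrom
    targeted = sorted(
        (p for p in truth.arrays if p.targeted), key=lambda p: p.start
    )
    male = dict(female)
    male_arrays: list[PlantedArray] = []
    seq = female[tchrom]
    pieces: list[str] = []
    cursor = 0
    shift = 0
    shifted: dict[tuple[int, int], tuple[int, int]] = {}
    for p in targeted:
        pieces.append(seq[cursor : p.start])
        newL = _expanded_length(p.length_bp, p.period, expansion_multiplier)
        pieces.append(_periodic(p.start_kmer, newL))
        shifted[(p.start, p.end)] = (p.start + shift, p.start + shift + newL)
        shift += newL - p.length_bp
        cursor = p.end
    pieces.append(seq[cursor:])
    male[tchrom] = "".join(pieces)
    # pad the female so total bases match exactly
    pad_rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, 0x5EAF]).generate_state(1)[0]
    )
    filler = repeat_free_filler(shift, context=female[tchrom][-9:], rng=pad_rng)
    female = dict(female)
    female[tchrom] = female[tchrom] + filler
    # truth for the male: shifted coordinates, expanded lengths
    for p in truth.arrays:
        if p.chrom != tchrom:
            male_arrays.append(p)
            continue
        if (p.start, p.end) in shifted:
            s, e = shifted[(p.start, p.end)]
            male_arrays.append(
                replace(p, start=s, end=e, length_bp=e - s)
            )
        else:
            # untargeted arrays shift by the expansion inserted before them
            d = sum(
                (shifted[(q.start, q.end)][1] - shifted[(q.start, q.end)][0])
                - q.length_bp
                for q in targeted
                if q.end <= p.start
            )
            male_arrays.append(replace(p, start=p.start + d, end=p.end + d))
    male_truth = TruthSet(
        arrays=sorted(male_arrays, key=lambda p: (p.chrom, p.start)),
        tes=truth.tes,
        spec=spec,
    )
    return female, male, truth, male_truth


def repeat_free_filler(
    n: int, context: str = "", rng: np.random.Generator | None = None
) -> str:
    """A length-n sequence free of period-1..3 arrays of 3+ units.

    Built greedily; *context* (the bases immediately upstream) is taken
    into account so no array forms across the junction, and the first
    filler base is chosen so it cannot extend any period-1..3 run
    ending at the junction.
    """
    if n <= 0:
        return ""
    if rng is None:
        rng = np.random.default_rng(0)
    buf = list(context)
    out: list[str] = []
    for i in range(n):
        order = list("ACGT")
        rng.shuffle(order)
        for c in order:
            if i == 0 and buf:
                # must not extend a run of any period ending at the junction
                if any(
                    len(buf) >= p and c == buf[-p] for p in (1, 2, 3)
                ):
                    continue
            cand = buf + [c]
            bad = False
            for p in (1, 2, 3):
                w = cand[-3 * p :]
                if len(w) == 3 * p and all(
                    w[j] == w[j + p] for j in range(2 * p)
                ):
                    bad = True
                    break
            if not bad:
                buf.append(c)
                out.append(c)
                break
        else:  # pragma: no cover - 4 letters always leave a choice
            raise RuntimeError("filler construction stuck")
    return "".join(out)


@dataclass(frozen=True)
class ReadLengthModel:
    """454-like read lengths: truncated normal."""

    mean: float = 400.0
    sd: float = 80.0
    min: int = 50
    max: int = 800

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        out = np.empty(n, dtype=np.int64)
        filled = 0
        while filled < n:
            draw = rng.normal(self.mean, self.sd, size=2 * (n - filled))
            ok = draw[(draw >= self.min) & (draw <= self.max)]
            take = min(len(ok), n - filled)
            out[filled : filled + take] = ok[:take].astype(np.int64)
            filled += take
        return out


def fragment_reads(
    genome: Mapping[str, str],
    coverage: float,
    seed: int,
    length_model: ReadLengthModel = ReadLengthModel(),
    truth: TruthSet | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Fragment a genome into uniformly placed single-end reads.

    Reads are drawn (chromosome weighted by length, start uniform)
    until total bases reach ``coverage * genome size``.  The returned
    table records each read's origin and, when *truth* is given, how
    many planted arrays it overlaps and how many of those it truncates
    (array not fully internal to the read).

    Raises
    ------
    ValueError
        If coverage is not positive or every chromosome is shorter than
        the minimum read length.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    chroms = [c for c in genome if len(genome[c]) >= length_model.min]
    if not chroms:
        raise ValueError("genome shorter than the minimum read length")
    rng = np.random.default_rng(seed)
    lens = np.array([len(genome[c]) for c in chroms], dtype=float)
    weights = lens / lens.sum()
    target = coverage * sum(len(s) for s in genome.values())
    truth_by_chrom: dict[str, list[PlantedArray]] = {}
    if truth is not None:
        for pa in truth.arrays:
            truth_by_chrom.setdefault(pa.chrom, []).append(pa)
    reads: list[tuple[str, str]] = []
    rows = []
    total = 0
    i = 0
    while total < target:
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        clen = len(genome[chrom])
        rl = int(length_model.draw(rng, 1)[0])
        rl = min(rl, clen)
        start = int(rng.integers(0, clen - rl + 1))
        end = start + rl
        rid = f"read_{i:07d}"
        reads.append((rid, genome[chrom][start:end]))
        n_overlap = n_trunc = 0
        for pa in truth_by_chrom.get(chrom, []):
            if pa.start < end and pa.end > start:
                n_overlap += 1
                if not (start < pa.start and pa.end < end):
                    n_trunc += 1
        rows.append(
            {
                "read_id": rid,
                "chrom": chrom,
                "start": start,
                "end": end,
                "n_arrays_overlapped": n_overlap,
                "n_arrays_truncated": n_trunc,
            }
        )
        total += rl
        i += 1
    return reads, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# study-condition factories (defaults used by tests and the acceptance run)


def te_study_spec(
    seed: int,
    n_te: int = 500,
    flank_bias: float = 0.0,
    chrom_len: int = 600_000,
) -> GenomeSpec:
    """TE-association study conditions: one repeat-dense chromosome.

    Background planted arrays (mono/di/tri, 10-20 bp) at ~1 per 290 bp
    emulate a microsatellite-rich genome; they give a random 50-bp
    window a substantial chance of holding a qualifying array, which is
    the regime where the fold statistic is stable at moderate TE counts.
    """
    per_group = n_te // 4
    counts = {
        "DNA": per_group,
        "LTR": per_group,
        "LINE": per_group,
        "SINE": n_te - 3 * per_group,
    }
    n_bg = max(1, round(700 * chrom_len / 600_000))  # ~1 array / 290 bp
    plans = tuple(
        ArrayPlan(motif=m, n=n_bg, length=UniformLength(10, 20))
        for m in ("A", "AC", "AAC")
    )
    return GenomeSpec(
        chrom_lengths={"chr1": chrom_len},
        array_plans=plans,
        te_plan=TEPlan(counts=counts, flank_bias=flank_bias),
        seed=seed,
    )


def sex_pair_spec(seed: int, chrom_len: int = 400_000) -> GenomeSpec:
    """Male/female study conditions: one sex chromosome, five motif
    classes planted at equal locus counts, AC designated for expansion."""
    plans = tuple(
        ArrayPlan(motif=m, n=250, length=GeometricLength(mean=30, min=12))
        for m in ("AC", "A", "AG", "AAC", "AAT")
    )
    return GenomeSpec(
        chrom_lengths={"chrY": chrom_len},
        array_plans=plans,
        expansion=ExpansionPlan(chrom="chrY", classes=("AC",)),
        seed=seed,
    )
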