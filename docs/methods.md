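# Methods

This document records the model, the numeric choices and their
defaults, the synthetic-data generator's scope, and known limitations.

## 1. Array detection (`microsat.arrays`)

`find_arrays(seq, k_min=1, k_max=3, min_len_bp=None)` reports every
maximal run of exact period-*k* repetition. Implementation: the
sequence is encoded as a numpy byte array; for each period *k* a
boolean match array `seq[i] == seq[i+k]` is reduced to runs via
`diff`/`flatnonzero`; prefix sums over the per-period match arrays
decide in O(1) per candidate whether a span also repeats at a smaller
period (in which case it is suppressed — each array is reported once at
its smallest primitive period) and whether it contains a non-ACGT base
(which splits runs). The scanner was validated against an exhaustive
brute-force enumerator (`tests/_oracles.py`) kept deliberately slow and
simple.

Per-array fields: span, motif class, the k-mer observed at the start,
the start/end k-mers, `length_bp` (partial trailing unit included),
`unit_count = length_bp // k`, and an edge label
(internal / left_terminal / right_terminal / spanning) so edge-truncated
arrays can be excluded from length-sensitive statistics.

Numeric thresholds live in one frozen `Thresholds` dataclass:

| parameter             | default | unit | used for |
|-----------------------|--------:|------|----------|
| `min_units_locus`     | 3       | units | locus definition |
| `min_flank_array_bp`  | 10      | bp   | TE-flank qualification |
| `flank_window_bp`     | 50      | bp   | TE flank window width |
| `tri_window`          | (11, 31)| bp   | trinucleotide start/end table |
| `di_min_bp`           | 14      | bp   | dinucleotide start/end table |
| `recomb_min_bp`       | 16 (strict >) | bp | recombination track |
| `recomb_window_bp`    | 20 000  | bp   | recombination track |
| `rm_max_divergence_pct` | 24.0  | %    | RepeatMasker hit filter |
| `norm_base`           | 1e8     | bp   | per-100-Mb rates |

## 2. Motif classes and phase (`microsat.motifs`)

Motifs are equivalence classes under rotation and reverse complement;
the canonical representative is the lexicographic minimum, and
non-primitive motifs are rejected. The end k-mer of an array is the
start k-mer rotated by `(L - k) mod k` — a pure arithmetic identity
that is property-tested against literal string construction.

## 3. Spectra, loci, periodicity (`microsat.spectrum`)

Length spectra are exact histograms of `length_bp`, optionally
restricted to internal arrays, normalized per 100 Mb.
`phase_periodicity` tests the distribution of `length mod k` against
uniformity with a chi-square test (scipy); it is flagged degenerate
below 5k observations and refuses period 1. `compare_groups` reports
per-class locus rates, long-array rates (default threshold 50 bp) and
their A/B ratios; zero-denominator ratios are returned as NaN with a
`*_defined` flag, never as infinities.

## 4. Start/end tables (`microsat.flanks`)

For a motif class and an inclusive length window, `start_end_table`
counts arrays into (start k-mer, end k-mer) cells, keeping the two
strands separate (an `AAC…`-starting array and a `TTG…`-starting array
are different rows). The set of feasible cells is derived from the
phase arithmetic; with the default windows this yields 18 trinucleotide
and 8 dinucleotide cells, and the table's cell sum always equals the
number of in-window arrays (conservation is asserted in tests).

## 5. TE-flank association (`microsat.te`)

Inputs: RepeatMasker `.out` (3 header lines skipped, malformed lines
counted and skipped, `C` mapped to `-`, 1-based inclusive converted to
0-based half-open, divergence-filtered) or 6-column BED. Each TE gets
two 50-bp windows mapped into a strand-oriented 1–100 frame. A TE is
microsatellite-associated when the bases of some perfect array
overlapping its windows total ≥ 10 bp. Window qualification is
vectorized: per chromosome, the union of window start positions that
would qualify is precomputed as merged intervals (`ArrayIndex`), giving
O(log n) lookups; truncated windows fall back to exact overlap sums.

The null model re-draws each TE's position uniformly on its chromosome
(length and strand preserved; overlaps permitted), recomputes the
associated proportion, and repeats `n_reps` times (default 100).
Enrichment fold = observed / null mean; a zero null mean with nonzero
observed is flagged undefined rather than reported as infinity.

## 6. Recombination track (`microsat.recomb`)

Arrays strictly longer than 16 bp (optionally restricted to one
(start, end) phase) are binned by midpoint into 20-kb tiles. The
recombination map (chrom, pos, rate in cM/Mb) is treated as
piecewise-constant; a window's rate is the increment of the cumulative
genetic map across it divided by its width. Spearman correlation is
reported; windows without map coverage are NaN and excluded, and
zero-variance inputs are flagged undefined.

## 7. Synthetic data (`microsat.simulate`)

The generator is a first-class deliverable: it produces a genome plus a
complete truth set, and every statistical module is tested against it.

- **Background** is i.i.d. with configurable base composition (default
  30/20/20/30). Accidental short arrays occur at realistic rates and
  are left in place genome-wide.
- **Planted arrays** follow per-class plans (count, length model:
  geometric, uniform, fixed, or spiked-residue; strand and start-phase
  options). Placement is rejection-sampled with a minimum spacing
  (default 20 bp). Flanking bases are set so each planted array is
  maximal exactly as planted. A local scrub then point-mutates
  accidental arrays ≥ 8 bp within 100 bp of planted features so planted
  coordinates are recovered exactly; background farther away is
  untouched. Infeasible packing raises an error rather than degrading.
- **TEs** are interval annotations placed uniformly and independently
  of the sequence (overlaps permitted) — exactly the assumption of the
  shuffle null, which makes the calibration experiment meaningful.
  With probability `flank_bias` a TE receives a planted qualifying
  array (default 15-bp poly-A) in its 5′ window, so the expected
  associated proportion is `b + (1 − b)·p` with `p` the background
  qualification probability; tests compare the recovered fold to this
  expectation computed by brute force.
- **Sex pair**: the "male" genome equals the "female" genome except
  that targeted-class arrays on the designated chromosome are extended
  by a phase-preserving multiple of the period; the female chromosome
  is padded with a repeat-free filler of exactly the total extension.
  Locus counts and total bases are therefore equal by construction and
  the per-100-Mb locus ratio is exactly 1, while the long-array ratio
  rises — the pure-expansion signature.
- **Reads**: single-end fragments with truncated-normal lengths
  (default mean 400, sd 80, clamped to [50, 800]), placed uniformly,
  chromosome chosen proportional to length. The truth table records,
  per read, how many planted arrays it overlaps and how many it
  truncates; the truncation fraction has a closed form under uniform
  placement that the tests check. No sequencing-error model is
  included.

Study-condition factories (`te_study_spec`, `sex_pair_spec`) fix the
problem sizes used by the tests and the acceptance script: a 600-kb
repeat-dense chromosome (~1 background array per 290 bp, giving a
random 50-bp window a ≈ 0.3 qualification probability — the regime
where the fold statistic is stable at 500 TEs), and a 400-kb sex
chromosome with five classes × 250 loci. These sizes are the package's
own choice, selected for statistical resolution per CPU-minute.

## 8. Determinism and seeds

Every stochastic stage takes an explicit seed; derived seeds are
produced with `numpy.random.SeedSequence` or small arithmetic and stay
below 2³¹. Identical seeds give byte-identical outputs (asserted for
genomes, reads and enrichment tables).

## 9. Limitations

- Only perfect arrays are modeled; interrupted/compound repeats are
  out of scope, so counts are conservative relative to tolerant repeat
  finders.
- The shuffle null repositions TEs independently and uniformly; it does
  not preserve TE clustering or GC-dependent insertion preferences.
- The recombination correlation is descriptive (Spearman over windows);
  no autocorrelation correction is applied.
- The read model has no sequencing errors or platform artifacts.
- `phase_periodicity` assumes a single dominant class per test; it does
  not model mixtures of phase-biased subpopulations.
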