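"""Synthetic-genome generator: determinism, exact recovery, reads."""

import math

import numpy as np
import pytest

from microsat.arrays import Thresholds, find_arrays
from microsat.simulate import (
    ArrayPlan,
    FixedLength,
    GenomeSpec,
    GeometricLength,
    ReadLengthModel,
    TEPlan,
    UniformLength,
    fragment_reads,
    repeat_free_filler,
    simulate_genome,
    simulate_sex_pair,
    sex_pair_spec,
    te_study_spec,
)

from _oracles import expected_truncated_fraction


def small_spec(seed=1):
    return GenomeSpec(
        chrom_lengths={"c": 120_000},
        array_plans=(
            ArrayPlan("AC", 150, GeometricLength(mean=25, min=12)),
            ArrayPlan("AAC", 100, UniformLength(12, 30)),
        ),
        seed=seed,
    )


class TestDeterminism:
    def test_same_seed_identical_output(self):
        g1, t1 = simulate_genome(small_spec(7))
        g2, t2 = simulate_genome(small_spec(7))
        assert g1 == g2
        assert t1.arrays == t2.arrays and t1.tes == t2.tes

    def test_different_seed_differs(self):
        g1, _ = simulate_genome(small_spec(7))
        g2, _ = simulate_genome(small_spec(8))
        assert g1 != g2

    def test_read_fragmentation_deterministic(self):
        genome, _ = simulate_genome(small_spec(3))
        r1, _ = fragment_reads(genome, 0.5, seed=11)
        r2, _ = fragment_reads(genome, 0.5, seed=11)
        assert r1 == r2


class TestPlantedRecovery:
    def test_zero_feature_genome(self):
        genome, truth = simulate_genome(
            GenomeSpec(chrom_lengths={"a": 5000, "b": 2000}, seed=2)
        )
        assert len(genome["a"]) == 5000 and len(genome["b"]) == 2000
        assert truth.arrays == [] and truth.tes == []
        assert set(genome["a"]) <= set("ACGT")

    def test_every_planted_array_recovered_exactly(self):
        genome, truth = simulate_genome(small_spec(5))
        found = {
            (a.start, a.end): a for a in find_arrays(genome["c"], 1, 3)
        }
        for p in truth.arrays:
            a = found[(p.start, p.end)]  # exact span, maximal
            assert a.motif_class.canonical == p.canonical
            assert a.start_kmer == p.start_kmer
            assert a.length_bp == p.length_bp

    def test_infeasible_packing_rejected(self):
        spec = GenomeSpec(
            chrom_lengths={"c": 2000},
            array_plans=(ArrayPlan("AC", 100, FixedLength(30)),),
            seed=1,
        )
        with pytest.raises(ValueError, match="infeasible packing"):
            simulate_genome(spec)

    def test_te_annotations_match_plan(self):
        spec = te_study_spec(9, n_te=80, chrom_len=100_000)
        genome, truth = simulate_genome(spec)
        assert len(truth.tes) == 80
        for t in truth.tes:
            assert 0 <= t.start < t.end <= len(genome[t.chrom])
            assert t.strand in "+-"

    def test_flank_bias_plants_qualifying_upstream_arrays(self):
        spec = te_study_spec(12, n_te=200, chrom_len=250_000, flank_bias=1.0)
        genome, truth = simulate_genome(spec)
        assert all(t.has_planted_flank_array for t in truth.tes)
        flank_arrays = [p for p in truth.arrays if p.is_te_flank]
        assert len(flank_arrays) == 200
        th = Thresholds()
        by_te = {(t.chrom, t.start, t.end): t for t in truth.tes}
        for p in flank_arrays:
            assert p.length_bp >= th.min_flank_array_bp
            # lies within 50 bp of some TE's 5' boundary
            near = [
                t
                for t in truth.tes
                if t.chrom == p.chrom
                and (
                    (t.strand == "+" and t.start - 50 <= p.start and p.end <= t.start)
                    or (t.strand == "-" and t.end <= p.start and p.end <= t.end + 50)
                )
            ]
            assert near, (p, len(by_te))


class TestRepeatFreeFiller:
    def test_filler_contains_no_arrays(self):
        rng = np.random.default_rng(6)
        s = repeat_free_filler(5000, rng=rng)
        assert len(s) == 5000
        assert find_arrays(s, 1, 3) == []

    def test_junction_safety(self):
        rng = np.random.default_rng(6)
        for context in ("ACACAC", "AAAA", "AACAAC", "GT"):
            s = repeat_free_filler(200, context=context, rng=rng)
            arrays = find_arrays(context + s, 1, 3)
            # nothing new forms at or across the junction
            assert all(a.end <= len(context) for a in arrays)


class TestSexPair:
    def test_multiplier_one_is_identity(self):
        f, m, _, _ = simulate_sex_pair(sex_pair_spec(4, 120_000), 1.0)
        assert f == m

    def test_multiplier_below_one_rejected(self):
        with pytest.raises(ValueError):
            simulate_sex_pair(sex_pair_spec(4, 120_000), 0.5)

    def test_expansion_targets_only_designated_class(self):
        f, m, ft, mt = simulate_sex_pair(sex_pair_spec(4, 200_000), 3.0)
        # equal total bases by construction
        assert sum(map(len, f.values())) == sum(map(len, m.values()))
        fm = {(p.chrom, p.start): p for p in ft.arrays}
        ratios = []
        for p in mt.arrays:
            q = next(
                (
                    v
                    for k, v in fm.items()
                    if v.targeted == p.targeted
                    and v.canonical == p.canonical
                ),
                None,
            )
            assert q is not None
        f_targeted = sum(p.length_bp for p in ft.arrays if p.targeted)
        m_targeted = sum(p.length_bp for p in mt.arrays if p.targeted)
        assert m_targeted / f_targeted == pytest.approx(3.0, rel=0.02)
        f_other = sum(p.length_bp for p in ft.arrays if not p.targeted)
        m_other = sum(p.length_bp for p in mt.arrays if not p.targeted)
        assert f_other == m_other

    def test_expanded_lengths_preserve_phase(self):
        _, _, ft, mt = simulate_sex_pair(sex_pair_spec(4, 200_000), 3.0)
        f_t = [p for p in ft.arrays if p.targeted]
        m_t = [p for p in mt.arrays if p.targeted]
        assert len(f_t) == len(m_t)
        for a, b in zip(f_t, m_t):
            assert (b.length_bp - a.length_bp) % a.period == 0


class TestFragmentReads:
    def test_coverage_reached(self):
        genome, _ = simulate_genome(small_spec(2))
        model = ReadLengthModel(mean=300, sd=50, min=50, max=600)
        reads, table = fragment_reads(genome, 0.8, seed=5, length_model=model)
        total = sum(len(s) for _, s in reads)
        target = 0.8 * sum(len(s) for s in genome.values())
        assert target <= total < target + model.max
        assert len(table) == len(reads)
        assert (table["end"] - table["start"]).between(50, 600).all()

    def test_truncation_fraction_matches_closed_form(self):
        spec = GenomeSpec(
            chrom_lengths={"c": 200_000},
            array_plans=(ArrayPlan("AC", 100, FixedLength(30)),),
            min_spacing=400,
            seed=14,
        )
        genome, truth = simulate_genome(spec)
        model = ReadLengthModel(mean=200, sd=0.5, min=198, max=202)
        _, table = fragment_reads(
            genome, 3.0, seed=21, length_model=model, truth=truth
        )
        n_overlap = int(table["n_arrays_overlapped"].sum())
        n_trunc = int(table["n_arrays_truncated"].sum())
        read_lengths = (table["end"] - table["start"]).tolist()
        expected = expected_truncated_fraction(30, read_lengths)
        observed = n_trunc / n_overlap
        se = math.sqrt(expected * (1 - expected) / n_overlap)
        assert abs(observed - expected) < 4 * se + 0.01

    def test_bad_inputs_rejected(self):
        genome, _ = simulate_genome(small_spec(2))
        with pytest.raises(ValueError):
            fragment_reads(genome, 0.0, seed=1)
        with pytest.raises(ValueError):
            fragment_reads({"c": "ACGT"}, 1.0, seed=1)
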