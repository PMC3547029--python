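"""TE annotation parsing, flank windows, profiles and shuffle enrichment."""

import math

import numpy as np
import pytest

from microsat.arrays import Thresholds, find_arrays
from microsat.motifs import revcomp
from microsat.simulate import (
    repeat_free_filler,
    simulate_genome,
    te_study_spec,
)
from microsat.te import (
    TEAnnotation,
    _build_indexes,
    enrichment,
    extract_flank_windows,
    flank_position_profile,
    parse_repeatmasker_out,
    parse_te_bed,
    proportion_with_array,
    shuffle_null,
)

TH = Thresholds()


class TestRepeatMaskerParser:
    def test_fixture_parsing(self, rm_out):
        tes = parse_repeatmasker_out(rm_out)
        # div 30.0 hit dropped by the 24% divergence filter
        assert len(tes) == 5
        by_family = {t.family: t for t in tes}
        alu = by_family["AluY"]
        assert (alu.chrom, alu.start, alu.end) == ("chr1", 100, 400)
        assert alu.te_group == "SINE" and alu.strand == "+"
        assert by_family["L1MA4"].strand == "-"  # C orientation
        assert by_family["L1MA4"].te_group == "LINE"
        assert by_family["LTR7"].te_group == "LTR"
        assert by_family["Helitron1"].te_group == "other"  # RC/Helitron

    def test_divergence_threshold_configurable(self, rm_out):
        tes = parse_repeatmasker_out(
            rm_out, Thresholds(rm_max_divergence_pct=31)
        )
        assert len(tes) == 6

    def test_unparseable_file_rejected(self, tmp_path):
        bad = tmp_path / "bad.out"
        bad.write_text("nothing useful\nhere either\n")
        with pytest.raises(ValueError):
            parse_repeatmasker_out(bad)

    def test_bed_fallback(self, tmp_path):
        bed = tmp_path / "tes.bed"
        bed.write_text("chr1\t100\t400\tSINE/Alu\t0\t+\nchr1\t900\t1400\tLINE\t0\t-\n")
        tes = parse_te_bed(bed)
        assert [t.te_group for t in tes] == ["SINE", "LINE"]
        assert tes[1].strand == "-"


class TestFlankWindows:
    def test_plus_strand(self):
        te = TEAnnotation("c", 1000, 2000, "+", "LINE")
        pair = extract_flank_windows(10_000, te, TH)
        assert pair.upstream_window == (950, 1000)
        assert pair.downstream_window == (2000, 2050)
        assert not pair.truncated

    def test_minus_strand_orientation(self):
        te = TEAnnotation("c", 1000, 2000, "-", "LINE")
        pair = extract_flank_windows(10_000, te, TH)
        assert pair.upstream_window == (2000, 2050)
        assert pair.downstream_window == (950, 1000)
        # position 1 is the most 5'-distal base: genomic 2049
        assert pair.oriented_position(2049) == 1
        assert pair.oriented_position(2000) == 50
        assert pair.oriented_position(999) == 51
        assert pair.oriented_position(950) == 100

    def test_truncated_at_chromosome_start(self):
        te = TEAnnotation("c", 20, 120, "+", "DNA")
        pair = extract_flank_windows(10_000, te, TH)
        assert pair.upstream_window == (0, 20)
        assert pair.truncated

    def test_te_longer_than_chromosome_rejected(self):
        te = TEAnnotation("c", 0, 500, "+", "DNA")
        with pytest.raises(ValueError):
            extract_flank_windows(400, te, TH)


def _genome_with(insertions, n=4000, seed=0):
    """Repeat-free background with sequences written at fixed offsets."""
    base = list(repeat_free_filler(n, rng=np.random.default_rng(seed)))
    for pos, s in insertions:
        base[pos : pos + len(s)] = list(s)
    return {"c": "".join(base)}


class TestFlankProfile:
    def test_planted_poly_a_at_minus_30(self):
        # every TE has a 15-bp poly-A ending 30 bp before its 5' start
        tes = [
            TEAnnotation("c", s, s + 200, "+", "LINE")
            for s in (1000, 2000, 3000)
        ]
        genome = _genome_with(
            [(s - 45, "A" * 15) for s in (1000, 2000, 3000)]
        )
        profiles = flank_position_profile(tes, genome, TH)
        prof = profiles["LINE"]
        assert prof.proportion_with_array == 1.0
        vec = prof.position_counts["A"]
        peak = {p + 1 for p in np.flatnonzero(vec == 3)}
        assert peak == set(range(6, 21))

    def test_ten_bp_overlap_rule(self):
        # 12 bp of array inside the window qualifies, 8 bp does not
        te = TEAnnotation("c", 1000, 1200, "+", "LINE")
        qual = _genome_with([(1000 - 12, "A" * 20)])  # 12 bp inside window
        not_qual = _genome_with([(1000 - 8, "A" * 20)])  # 8 bp inside
        p1 = flank_position_profile([te], qual, TH)["LINE"]
        p2 = flank_position_profile([te], not_qual, TH)["LINE"]
        assert p1.proportion_with_array == 1.0
        assert p2.proportion_with_array == 0.0

    def test_empty_te_set_rejected(self):
        with pytest.raises(ValueError):
            flank_position_profile([], {"c": "ACGT"}, TH)

    def test_orientation_invariance(self):
        spec = te_study_spec(31, n_te=60, chrom_len=80_000)
        genome, truth = simulate_genome(spec)
        tes = truth.te_annotations()
        fwd = flank_position_profile(tes, genome, TH)
        n = len(genome["chr1"])
        flipped = [
            TEAnnotation(
                "chr1",
                n - t.end,
                n - t.start,
                "-" if t.strand == "+" else "+",
                t.te_group,
            )
            for t in tes
        ]
        rc = {"chr1": revcomp(genome["chr1"])}
        rev = flank_position_profile(flipped, rc, TH)
        for group in fwd:
            assert (
                fwd[group].proportion_with_array
                == rev[group].proportion_with_array
            )
            for cls, vec in fwd[group].position_counts.items():
                assert np.array_equal(vec, rev[group].position_counts[cls])


class TestShuffleNull:
    def test_same_seed_identical(self):
        spec = te_study_spec(41, n_te=40, chrom_len=60_000)
        genome, truth = simulate_genome(spec)
        tes = truth.te_annotations()
        sizes = {c: len(s) for c, s in genome.items()}
        a = shuffle_null(tes, sizes, genome, 5, 99, TH)
        b = shuffle_null(tes, sizes, genome, 5, 99, TH)
        assert a == b
        c = shuffle_null(tes, sizes, genome, 5, 100, TH)
        assert a != c

    def test_microsatellite_free_genome_gives_zero_null(self):
        genome = {"c": repeat_free_filler(20_000, rng=np.random.default_rng(3))}
        tes = [TEAnnotation("c", 1000 * i, 1000 * i + 300, "+", "DNA")
               for i in range(1, 15)]
        sizes = {"c": 20_000}
        null = shuffle_null(tes, sizes, genome, 10, 7, TH)
        assert null == [0.0] * 10

    def test_null_mean_matches_observed_without_association(self):
        spec = te_study_spec(55, n_te=500)
        genome, truth = simulate_genome(spec)
        tes = truth.te_annotations()
        sizes = {c: len(s) for c, s in genome.items()}
        idx = _build_indexes(genome, TH)
        obs = proportion_with_array(tes, idx, sizes, TH)
        null = np.array(shuffle_null(tes, sizes, genome, 200, 17, TH))
        se = null.std(ddof=1) / math.sqrt(len(null)) + math.sqrt(
            obs * (1 - obs) / len(tes)
        )
        assert abs(obs - null.mean()) < 3 * se


class TestEnrichment:
    def test_fold_arithmetic(self):
        res = enrichment(0.16, [0.05] * 10)
        assert res.fold == pytest.approx(3.2)

    def test_fold_one_when_observed_equals_null_mean(self):
        res = enrichment(0.05, [0.04, 0.05, 0.06])
        assert res.fold == pytest.approx(1.0)

    def test_zero_null_with_positive_observed_flagged(self):
        res = enrichment(0.1, [0.0, 0.0])
        assert not res.fold_defined and math.isinf(res.fold)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            enrichment(0.1, [])
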