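import numpy as np
import pytest

from scnakit.genome import MB, Chromosome, GenomeModel, Segment, SegmentedProfile
from scnakit.instability import (
    LgaConfig,
    build_events,
    call_hrd,
    classify_events,
    count_lga,
    estimate_one_copy_cutoff,
    genomic_index,
    integrate_small_segments,
    scna_scores,
    score_profile,
    smooth_profile,
)
from scnakit.simulate import simulate_profile

from conftest import build_profile, genome_table, profile_mean_rows, profile_rows
from oracles import (
    naive_count_lga,
    naive_genomic_index,
    naive_interstitial_filter,
    naive_scna,
)


@pytest.fixture
def one_arm_genome():
    # one chromosome whose q arm is 100 Mb: handy for single-arm fixtures
    return GenomeModel((Chromosome("chr1", 110 * MB, 10 * MB),))


def arm_profile(levels_mb, start_mb=10):
    """Build a single q-arm profile from (length_mb, mean) pairs."""
    segs = []
    cursor = start_mb
    for length, mean in levels_mb:
        segs.append(("chr1", cursor, cursor + length, mean, "normal"))
        cursor += length
    assert cursor == 110
    g = GenomeModel((Chromosome("chr1", 110 * MB, 10 * MB),))
    return build_profile(g, segs), g


class TestGenomicIndex:
    def test_flat_profile(self, toy):
        prof = build_profile(toy, [])
        assert genomic_index(prof, toy) == (0.0, 0, 0)

    def test_four_alterations_two_chromosomes(self, toy):
        prof = build_profile(
            toy,
            [
                ("chr1", 0, 10, 0.6, "gain"),
                ("chr1", 20, 30, 0.6, "gain"),
                ("chr2", 0, 10, -0.6, "loss"),
                ("chr2", 20, 30, 0.6, "gain"),
            ],
        )
        gi, a, c = genomic_index(prof, toy)
        assert (a, c) == (4, 2)
        assert gi == 8.0  # 4^2 / 2

    def test_fixture_six_three_one(self, toy):
        # 6 separated gains on chr1, 3 losses on chr2, 1 gain on chr3
        spec = [("chr1", 2 + 6 * i, 5 + 6 * i, 0.6, "gain") for i in range(6)]
        spec += [("chr2", 2 + 8 * i, 6 + 8 * i, -0.6, "loss") for i in range(3)]
        spec += [("chr3", 10, 20, 0.6, "gain")]
        prof = build_profile(toy, spec)
        gi, a, c = genomic_index(prof, toy)
        oracle = naive_genomic_index(profile_rows(prof))
        assert (a, c) == (10, 3)
        assert gi == pytest.approx(100 / 3)
        assert (gi, a, c) == pytest.approx(oracle)

    def test_adjacent_same_status_merged(self, toy):
        prof = build_profile(
            toy, [("chr1", 0, 10, 0.6, "gain"), ("chr1", 10, 20, 0.7, "gain")]
        )
        _, a, c = genomic_index(prof, toy)
        assert (a, c) == (1, 1)

    def test_sex_chromosomes_excluded(self):
        g = GenomeModel((Chromosome("chr1", 100 * MB, 40 * MB), Chromosome("chrX", 100 * MB, 40 * MB)))
        prof = build_profile(g, [("chrX", 0, 50, 0.6, "gain")])
        assert genomic_index(prof, g) == (0.0, 0, 0)

    def test_matches_oracle_on_random_profiles(self, toy, rng):
        for _ in range(200):
            spec = []
            for chrom, clen in (("chr1", 100), ("chr2", 80), ("chr3", 60)):
                cursor = 0
                while cursor < clen - 5:
                    length = int(rng.integers(3, 15))
                    end = min(cursor + length, clen)
                    status = rng.choice(["gain", "loss", "normal"])
                    mean = {"gain": 0.6, "loss": -0.6, "normal": 0.0}[status]
                    spec.append((chrom, cursor, end, mean, status))
                    cursor = end
            prof = build_profile(toy, spec)
            assert genomic_index(prof, toy) == pytest.approx(
                naive_genomic_index(profile_rows(prof))
            )


class TestEvents:
    def test_single_focal_gain(self, toy):
        prof = build_profile(toy, [("chr1", 0, 12, 0.6, "gain")])  # 30% of 40 Mb p arm
        events = build_events(prof, toy)
        assert len(events) == 1
        assert events[0].arm_fraction == pytest.approx(0.30)

    def test_adjacent_same_status_merged(self, toy):
        prof = build_profile(toy, [("chr1", 0, 6, 0.6, "gain"), ("chr1", 6, 12, 0.8, "gain")])
        events = build_events(prof, toy)
        assert len(events) == 1
        assert (events[0].start, events[0].end) == (0, 12 * MB)

    def test_centromere_crossing_split(self, toy):
        prof = build_profile(toy, [("chr1", 30, 50, 0.6, "gain")])
        events = build_events(prof, toy)
        assert [(e.arm, e.start, e.end) for e in events] == [
            ("p", 30 * MB, 40 * MB),
            ("q", 40 * MB, 50 * MB),
        ]

    def test_focal_classification(self, toy):
        prof = build_profile(toy, [("chr1", 0, 12, 0.6, "gain")])
        events = classify_events(build_events(prof, toy), toy)
        assert events[0].level == "focal"

    def test_chromosome_level_both_arms(self, toy):
        # gains covering 90% of p and 85% of q, same status
        prof = build_profile(
            toy, [("chr1", 0, 36, 0.6, "gain"), ("chr1", 40, 91, 0.6, "gain")]
        )
        events = classify_events(build_events(prof, toy), toy)
        assert all(e.level == "chromosome" for e in events)

    def test_single_arm_is_arm_level(self, toy):
        prof = build_profile(toy, [("chr1", 0, 36, 0.6, "gain")])  # 90% of p only
        events = classify_events(build_events(prof, toy), toy)
        assert events[0].level == "arm"

    def test_opposite_signs_not_chromosome(self, toy):
        prof = build_profile(
            toy, [("chr1", 0, 36, 0.6, "gain"), ("chr1", 40, 91, -0.6, "loss")]
        )
        events = classify_events(build_events(prof, toy), toy)
        assert {e.level for e in events} == {"arm"}


class TestScnaScores:
    def test_no_events(self):
        assert scna_scores([]) == {
            "focal_amp": 0, "focal_del": 0, "arm_amp": 0,
            "arm_del": 0, "chrom_amp": 0, "chrom_del": 0,
        }

    def test_focal_counting(self, toy):
        spec = [("chr1", 2 + 14 * i, 10 + 14 * i, 0.6, "gain") for i in range(3)]
        spec += [("chr2", 2, 10, -0.6, "loss")]
        prof = build_profile(toy, spec)
        counts = scna_scores(classify_events(build_events(prof, toy), toy))
        assert counts["focal_amp"] == 3 and counts["focal_del"] == 1

    def test_two_chromosome_level_losses_counted_once_each(self, toy):
        spec = [
            ("chr1", 0, 40, -0.6, "loss"), ("chr1", 40, 100, -0.6, "loss"),
            ("chr2", 0, 30, -0.6, "loss"), ("chr2", 30, 80, -0.6, "loss"),
        ]
        prof = build_profile(toy, spec)
        counts = scna_scores(classify_events(build_events(prof, toy), toy))
        oracle = naive_scna(profile_rows(prof), genome_table(toy))
        assert counts["chrom_del"] == 2
        assert counts == oracle

    def test_matches_oracle_on_random_profiles(self, toy, rng):
        for _ in range(200):
            spec = []
            for chrom, clen in (("chr1", 100), ("chr2", 80), ("chr3", 60)):
                cursor = 0
                while cursor < clen:
                    length = int(rng.integers(5, 45))
                    end = min(cursor + length, clen)
                    status = rng.choice(["gain", "loss", "normal", "normal"])
                    mean = {"gain": 0.6, "loss": -0.6, "normal": 0.0}[status]
                    spec.append((chrom, cursor, end, mean, status))
                    cursor = end
            prof = build_profile(toy, spec)
            counts = scna_scores(classify_events(build_events(prof, toy), toy))
            assert counts == naive_scna(profile_rows(prof), genome_table(toy))


class TestOneCopyCutoff:
    def test_uniform_steps(self):
        # ten 10-Mb segments alternating 0/0.58: all nine steps are 0.58
        prof, g = arm_profile([(10, 0.58 if i % 2 else 0.0) for i in range(10)])
        cutoff = estimate_one_copy_cutoff(prof, g)
        assert 0.55 <= cutoff <= 0.60

    def test_bimodal_steps(self):
        # five steps at 0.6, four at 0 (below the floor): mode is at 0.6
        levels = [0.0, 0.6, 0.6, 0.0, 0.0, 0.6, 0.6, 0.0, 0.0, 0.6]
        prof, g = arm_profile([(10, lv) for lv in levels])
        cutoff = estimate_one_copy_cutoff(prof, g)
        assert 0.55 <= cutoff <= 0.65

    def test_fallback_with_two_pairs(self):
        prof, g = arm_profile([(30, 0.0), (40, 0.6), (30, 0.0)])
        assert estimate_one_copy_cutoff(prof, g) == 0.3

    def test_flat_profile_fallback(self, toy):
        prof = build_profile(toy, [])
        assert estimate_one_copy_cutoff(prof, toy) == 0.3


class TestSmoothing:
    def test_equal_mean_split_remerged(self):
        prof, g = arm_profile([(50, 0.4), (50, 0.4)])
        out = smooth_profile(prof, 0.3, g)
        qsegs = [s for s in out.segments if s.start >= 10 * MB]
        assert len(qsegs) == 1
        assert qsegs[0].mean_log2 == pytest.approx(0.4)

    def test_small_steps_merged_large_steps_kept(self):
        prof, g = arm_profile([(25, 0.0), (25, 0.1), (25, 0.7), (25, 0.1)])
        out = smooth_profile(prof, 0.3, g)
        qsegs = [s for s in out.segments if s.start >= 10 * MB]
        # 0.0/0.1 merged; 0.05/0.7 and 0.7/0.1 steps preserved
        assert len(qsegs) == 3
        assert qsegs[0].mean_log2 == pytest.approx(0.05)

    def test_split_invariance_randomized(self, rng):
        base = [(20, 0.0), (20, 0.6), (20, 0.0), (20, 0.6), (20, 0.0)]
        prof, g = arm_profile(base)
        cfg = LgaConfig()
        ref = integrate_small_segments(smooth_profile(prof, 0.3, g, cfg), 0.3, g, cfg)
        for _ in range(50):
            # re-segment each q segment into random pieces with identical means
            spec = []
            for s in prof.segments:
                if s.start < 10 * MB:
                    continue
                cuts = sorted(
                    rng.choice(np.arange(s.start + MB, s.end, MB), size=rng.integers(0, 3), replace=False)
                )
                bounds = [s.start, *map(int, cuts), s.end]
                for a, b in zip(bounds, bounds[1:]):
                    spec.append(("chr1", a / MB, b / MB, s.mean_log2, "normal"))
            split = build_profile(g, spec)
            out = integrate_small_segments(smooth_profile(split, 0.3, g, cfg), 0.3, g, cfg)
            assert count_lga(out, 0.3, g, cfg) == count_lga(ref, 0.3, g, cfg)
            got = [(s.start, s.end, round(s.mean_log2, 9)) for s in out.segments]
            want = [(s.start, s.end, round(s.mean_log2, 9)) for s in ref.segments]
            assert got == want


class TestIntegration:
    def test_interstitial_cna_absorbed(self):
        prof, g = arm_profile([(46, 0.0), (8, 0.6), (46, 0.0)])
        out = integrate_small_segments(prof, 0.3, g)
        qsegs = [s for s in out.segments if s.start >= 10 * MB]
        oracle = naive_interstitial_filter([(46, 0.0), (8, 0.6), (46, 0.0)], 0.3)
        assert len(qsegs) == len(oracle) == 1
        assert qsegs[0].mean_log2 == pytest.approx(oracle[0][1])
        assert qsegs[0].mean_log2 == pytest.approx(0.6 * 8 / 100)

    def test_small_first_segment_merges_right(self):
        prof, g = arm_profile([(2, 0.5), (98, 0.0)])
        out = integrate_small_segments(prof, 0.3, g)
        qsegs = [s for s in out.segments if s.start >= 10 * MB]
        assert len(qsegs) == 1
        assert qsegs[0].mean_log2 == pytest.approx(0.01)

    def test_no_small_segments_identity(self):
        prof, g = arm_profile([(50, 0.0), (50, 0.6)])
        out = integrate_small_segments(prof, 0.3, g)
        assert [(s.start, s.end, s.mean_log2) for s in out.segments if s.start >= 10 * MB] == [
            (10 * MB, 60 * MB, 0.0),
            (60 * MB, 110 * MB, 0.6),
        ]

    def test_matches_oracle_on_random_arms(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 8))
            lengths = rng.integers(2, 40, size=n).astype(float)
            lengths *= 100.0 / lengths.sum()
            if (lengths < 0.5).any():
                continue
            means = np.round(rng.normal(0, 0.4, size=n), 3)
            segs = list(zip(lengths, means))
            spec = []
            cursor = 10.0
            for ln, m in segs:
                spec.append(("chr1", cursor, cursor + ln, float(m), "normal"))
                cursor += ln
            spec[-1] = ("chr1", spec[-1][1], 110.0, spec[-1][3], "normal")
            g = GenomeModel((Chromosome("chr1", 110 * MB, 10 * MB),))
            prof = build_profile(g, spec)
            out = integrate_small_segments(prof, 0.3, g)
            got = [
                (round((s.end - s.start) / MB, 3), round(s.mean_log2, 6))
                for s in out.segments
                if s.start >= 10 * MB
            ]
            lens_mb = [(s.end - s.start) / MB for s in prof.segments if s.start >= 10 * MB]
            means_q = [s.mean_log2 for s in prof.segments if s.start >= 10 * MB]
            want = [
                (round(ln, 3), round(m, 6))
                for ln, m in naive_interstitial_filter(list(zip(lens_mb, means_q)), 0.3)
            ]
            assert got == want


class TestCountLga:
    def test_single_segment_arms(self, toy):
        prof = build_profile(toy, [])
        assert count_lga(prof, 0.3, toy) == 0

    def test_five_alternating_segments(self):
        prof, g = arm_profile([(20, 0.0), (20, 0.6), (20, 0.0), (20, 0.6), (20, 0.0)])
        assert count_lga(prof, 0.3, g) == 4
        assert naive_count_lga(profile_mean_rows(prof), genome_table(g), 0.3) == 4

    def test_interstitial_filtering_before_counting(self):
        # middle segment shrunk to 8 Mb between the two 0.6 plateaus: the
        # filter absorbs it into a single 48 Mb segment at (12+0+12)/48 = 0.5,
        # leaving 2 qualifying breaks (naive oracle agrees)
        prof, g = arm_profile([(26, 0.0), (20, 0.6), (8, 0.0), (20, 0.6), (26, 0.0)])
        filtered = integrate_small_segments(prof, 0.3, g)
        assert count_lga(filtered, 0.3, g) == 2
        oracle_segs = naive_interstitial_filter(
            [(26, 0.0), (20, 0.6), (8, 0.0), (20, 0.6), (26, 0.0)], 0.3
        )
        assert len(oracle_segs) == 3
        rows = []
        cursor = 10.0
        for ln, m in oracle_segs:
            rows.append(("chr1", int(cursor * MB), int((cursor + ln) * MB), m))
            cursor += ln
        assert naive_count_lga(rows, genome_table(g), 0.3) == 2

    def test_breaks_across_centromere_not_counted(self):
        g = GenomeModel((Chromosome("chr1", 100 * MB, 50 * MB),))
        prof = build_profile(g, [("chr1", 0, 50, 0.0, "normal"), ("chr1", 50, 100, 0.6, "gain")])
        assert count_lga(prof, 0.3, g) == 0

    def test_small_flank_not_counted(self):
        prof, g = arm_profile([(92, 0.0), (8, 0.6)])
        assert count_lga(prof, 0.3, g) == 0

    def test_monotonicity_one_more_break(self):
        prof1, g = arm_profile([(40, 0.0), (60, 0.6)])
        prof2, _ = arm_profile([(40, 0.0), (30, 0.6), (30, 1.2)])
        assert count_lga(prof2, 0.3, g) == count_lga(prof1, 0.3, g) + 1

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 9))
            lengths = rng.integers(5, 30, size=n).astype(float)
            lengths *= 100.0 / lengths.sum()
            means = np.round(rng.normal(0, 0.5, size=n), 3)
            spec = []
            cursor = 10.0
            for ln, m in zip(lengths, means):
                spec.append(("chr1", cursor, cursor + ln, float(m), "normal"))
                cursor += ln
            spec[-1] = ("chr1", spec[-1][1], 110.0, spec[-1][3], "normal")
            g = GenomeModel((Chromosome("chr1", 110 * MB, 10 * MB),))
            prof = build_profile(g, spec)
            cutoff = float(rng.uniform(0.1, 0.7))
            assert count_lga(prof, cutoff, g) == naive_count_lga(
                profile_mean_rows(prof), genome_table(g), cutoff
            )


class TestCallHrd:
    @pytest.mark.parametrize("lga,expected", [(18, "HRD"), (17, "HRP"), (0, "HRP"), (30, "HRD")])
    def test_threshold(self, lga, expected):
        assert call_hrd(lga) == expected

    def test_custom_threshold(self):
        assert call_hrd(10, LgaConfig(hrd_threshold=10)) == "HRD"

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            call_hrd(-1)


class TestEndToEnd:
    def test_target_18_is_hrd(self, big, rng):
        prof, _ = simulate_profile(18, 0, 0, 0, big, rng=rng)
        scores = score_profile(prof, big)
        assert scores.lga_count == 18
        assert scores.hrd_call == "HRD"

    def test_gi_invariant_formula(self, big, rng):
        for _ in range(20):
            prof, truth = simulate_profile(
                int(rng.integers(0, 20)), int(rng.integers(0, 4)),
                int(rng.integers(0, 3)), int(rng.integers(0, 3)), big, rng=rng,
            )
            s = score_profile(prof, big)
            if s.n_alterations > 0:
                assert s.genomic_index == pytest.approx(
                    s.n_alterations**2 / s.n_chromosomes_altered
                )
            else:
                assert s.genomic_index == 0.0


def test_lga_config_validation():
    with pytest.raises(ValueError):
        LgaConfig(small_segment_mb=12.0)
    with pytest.raises(ValueError):
        LgaConfig(cutoff_fallback=0.0)
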