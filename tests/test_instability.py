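"""LST counting, GIN computation and segment smoothing."""

import numpy as np
import pytest

from csflm.coverage import BinMask, NormalizedProfile, StableRegionMask
from csflm.instability import (
    ScoreParams,
    compute_gin,
    count_lst,
    score_sample,
    smooth_segments,
)
from csflm.layout import GenomeLayout
from csflm.segmentation import Segment, SegmentProfile

MB = 1_000_000


def make_segments(spec, chrom="chr1"):
    """Build a SegmentProfile from (start_mb, end_mb, mean) tuples."""
    segs = [
        Segment(
            chrom=chrom,
            start=a * MB,
            end=b * MB,
            mean=mean,
            n_bins=b - a,
            bin_indices=np.arange(a, b),
        )
        for a, b, mean in spec
    ]
    return SegmentProfile(segs)


def brute_force_lst(smoothed, min_flank=10 * MB, min_change=0.1):
    """Independent O(n) re-scan, written separately from count_lst."""
    total = 0
    by_chrom = {}
    for seg in smoothed.segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for segs in by_chrom.values():
        ordered = sorted(segs, key=lambda s: s.start)
        for idx in range(len(ordered) - 1):
            left, right = ordered[idx], ordered[idx + 1]
            long_enough = (
                left.end - left.start >= min_flank
                and right.end - right.start >= min_flank
            )
            if long_enough and abs(left.mean - right.mean) >= min_change:
                total += 1
    return total


class TestSmoothing:
    def test_large_dissimilar_segments_are_fixed_point(self):
        profile = make_segments([(0, 20, 0.0), (20, 40, 0.6), (40, 80, 0.0)])
        smoothed = smooth_segments(profile)
        assert [(s.start, s.end, s.mean) for s in smoothed.segments] == [
            (s.start, s.end, s.mean) for s in profile.segments
        ]

    def test_small_spike_absorbed_into_flat_neighbor(self):
        profile = make_segments([(0, 19, 0.0), (19, 21, 1.0), (21, 40, 0.0)])
        smoothed = smooth_segments(profile)
        assert len(smoothed.segments) == 1
        only = smoothed.segments[0]
        assert (only.start, only.end) == (0, 40 * MB)
        assert only.mean == pytest.approx(0.0, abs=1e-12)

    def test_idempotent(self):
        profile = make_segments(
            [(0, 2, 0.5), (2, 20, 0.0), (20, 25, 0.05), (25, 60, 0.7)]
        )
        once = smooth_segments(profile)
        twice = smooth_segments(once)
        assert [(s.start, s.end, s.mean) for s in once.segments] == [
            (s.start, s.end, s.mean) for s in twice.segments
        ]

    def test_lone_short_segment_flagged_terminal(self):
        profile = make_segments([(0, 2, 0.3)])
        smoothed = smooth_segments(profile)
        assert smoothed.segments[0].flag == "terminal_remnant"

    def test_similar_neighbors_merge_bin_weighted(self):
        profile = make_segments([(0, 10, 0.10), (10, 40, 0.04)])
        smoothed = smooth_segments(profile, merge_delta=0.1)
        assert len(smoothed.segments) == 1
        expected = (0.10 * 10 + 0.04 * 30) / 40
        assert smoothed.segments[0].mean == pytest.approx(expected)

    def test_bin_conservation(self):
        profile = make_segments(
            [(0, 2, 1.0), (2, 30, 0.0), (30, 32, -0.8), (32, 60, 0.02)]
        )
        smoothed = smooth_segments(profile)
        assert smoothed.n_bins_total == profile.n_bins_total


class TestCountLst:
    def test_single_segment_per_chromosome_is_zero(self):
        profile = make_segments([(0, 100, 0.3)])
        assert count_lst(smooth_segments(profile)) == 0

    def test_alternating_twelve_mb_segments(self):
        spec = [
            (0, 12, 0.0), (12, 24, 0.58), (24, 36, 0.0),
            (36, 48, 0.58), (48, 60, 0.0),
        ]
        smoothed = smooth_segments(make_segments(spec))
        assert count_lst(smoothed) == brute_force_lst(smoothed) == 4

    def test_eight_mb_flank_disqualifies_boundary(self):
        smoothed = smooth_segments(
            make_segments([(0, 8, 0.0), (8, 40, 1.0)])
        )
        assert count_lst(smoothed) == brute_force_lst(smoothed) == 0

    def test_sub_threshold_mean_change_not_counted(self):
        smoothed = smooth_segments(
            make_segments([(0, 20, 0.0), (20, 40, 0.4)])
        )
        assert count_lst(smoothed, min_change=0.5) == 0

    def test_matches_brute_force_on_random_profiles(self, rng):
        for _ in range(50):
            edges = np.sort(
                rng.choice(np.arange(1, 100), size=rng.integers(1, 8),
                           replace=False)
            )
            spec = [
                (int(a), int(b), float(rng.normal(0, 0.5)))
                for a, b in zip([0, *edges], [*edges, 100])
            ]
            smoothed = smooth_segments(make_segments(spec))
            assert count_lst(smoothed) == brute_force_lst(smoothed)


def profile_with_ratios(ratios, stable_flags):
    n = len(ratios)
    layout = GenomeLayout((("chr1", n * MB),), bin_size=MB)
    ratios = np.asarray(ratios, dtype=float)
    profile = NormalizedProfile(
        layout=layout,
        r_sample=ratios,
        r_germline=np.ones(n),
        log2_ratio=np.log2(ratios),
        mask=np.zeros(n, dtype=np.int8),
    )
    stable = StableRegionMask(layout, np.asarray(stable_flags, dtype=bool))
    return profile, stable


class TestGin:
    def test_identity_profile_gives_zero(self):
        profile, stable = profile_with_ratios(np.ones(50), np.ones(50))
        assert compute_gin(profile, stable) == 0.0

    def test_single_bin_deviation_is_hundredfold(self):
        ratios = np.ones(50)
        stable = np.ones(50, dtype=bool)
        ratios[7] = 1.5
        stable[7] = False  # deviant bin outside the baseline expectation
        profile, mask = profile_with_ratios(ratios, stable)
        assert compute_gin(profile, mask) == pytest.approx(50.0, abs=1e-9)

    def test_linear_in_deviation_scale(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 0.1, 60)
        stable = np.abs(base) < 0.02
        profile1, mask = profile_with_ratios(1 + base, stable)
        profile2, _ = profile_with_ratios(1 + 2 * base, stable)
        gin1 = compute_gin(profile1, mask)
        expectation_shift = compute_gin(profile2, mask)
        # doubling every deviation from E doubles the sum
        assert expectation_shift == pytest.approx(2 * gin1, rel=1e-9)

    def test_no_unmasked_autosomal_bins_is_error(self):
        profile, stable = profile_with_ratios(np.ones(10), np.ones(10))
        profile.mask[:] = BinMask.EXCLUDED_LOW_COVERAGE
        with pytest.raises(ValueError):
            compute_gin(profile, stable)


class TestScoreSample:
    def test_flat_noiseless_input_scores_zero(self):
        profile, stable = profile_with_ratios(np.ones(100), np.ones(100))
        scores, smoothed = score_sample(profile, stable, ScoreParams(seed=0))
        assert scores.lst == 0
        assert scores.gin == 0.0
        assert len(smoothed.segments) == 1

    def test_recovers_planted_transitions(self, small_layout,
                                          six_transition_segments):
        from tests.conftest import run_scoring

        truth, scores, _, _ = run_scoring(
            small_layout, six_transition_segments,
            tumor_fraction=0.8, depth=300, seed=12,
        )
        assert truth.true_lst == 6
        assert scores.lst == 6

    def test_monotone_recovery_in_tumor_fraction(self, small_layout,
                                                 six_transition_segments):
        """Recovery rate never decreases as tumor fraction rises (within
        binomial noise, checked on a coarse grid with modest replicates)."""
        from tests.conftest import run_scoring

        rates = []
        for tf in (0.1, 0.5, 0.9):
            hits = 0
            reps = 10
            for rep in range(reps):
                truth, scores, _, _ = run_scoring(
                    small_layout, six_transition_segments,
                    tumor_fraction=tf, depth=300, seed=1000 + rep,
                )
                hits += scores.lst == truth.true_lst
            rates.append(hits / reps)
        # allow one replicate of slack between neighboring grid points
        assert rates[1] >= rates[0] - 0.1
        assert rates[2] >= rates[1] - 0.1

    def test_gin_scale_free(self, small_layout, six_transition_segments):
        from csflm.coverage import (
            correct_gc,
            identify_stable_regions,
            normalize_and_ratio,
        )
        from csflm.simulate import SimulationConfig, simulate_bin_counts

        config = SimulationConfig(
            small_layout, mean_depth_per_bin=500, tumor_fraction=0.6,
            segments=six_transition_segments, seed=3,
        )
        germline, sample, truth = simulate_bin_counts(config)
        germline = correct_gc(germline)
        sample = correct_gc(sample)
        stable = identify_stable_regions(germline, truth.het_snps)
        base = compute_gin(
            normalize_and_ratio(sample, germline, stable), stable
        )
        sample_scaled = correct_gc(
            type(sample)(small_layout, sample.counts * 11.0)
        )
        scaled = compute_gin(
            normalize_and_ratio(sample_scaled, germline, stable), stable
        )
        assert scaled == pytest.approx(base, rel=1e-6)
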