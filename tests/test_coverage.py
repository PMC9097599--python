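"""Fragment binning, GC correction, stable regions, normalization."""

import warnings

import numpy as np
import pandas as pd
import pysam
import pytest

from csflm.coverage import (
    BinMask,
    BinnedCoverageProfile,
    HetSNPTable,
    StableRegionParams,
    bin_fragments,
    correct_gc,
    identify_stable_regions,
    normalize_and_ratio,
)
from csflm.layout import GenomeLayout

MB = 1_000_000


# ---------------------------------------------------------------------------
# tiny BAM fixtures are built programmatically at test time
# ---------------------------------------------------------------------------

def build_bam(path, reads, chromosomes):
    """Write and index a coordinate-sorted BAM from (chrom, pos, mapq,
    flags) tuples. ``flags`` may include 'dup'."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in chromosomes],
    }
    refs = {name: i for i, (name, _) in enumerate(chromosomes)}
    reads = sorted(reads, key=lambda r: (refs[r[0]], r[1]))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for i, (chrom, pos, mapq, *flags) in enumerate(reads):
            read = pysam.AlignedSegment(bam.header)
            read.query_name = f"r{i}"
            read.query_sequence = "ACGT" * 10
            read.query_qualities = pysam.qualitystring_to_array("I" * 40)
            read.reference_id = refs[chrom]
            read.reference_start = pos
            read.mapping_quality = mapq
            read.cigarstring = "40M"
            read.flag = 0
            if "dup" in flags:
                read.flag |= 0x400
            bam.write(read)
    pysam.index(str(path))


@pytest.fixture()
def tiny_layout():
    gc = np.full(9, 0.45)
    return GenomeLayout(
        (("chr1", 3 * MB), ("chr2", 3 * MB), ("chrX", 3 * MB)),
        bin_size=MB,
        gc=gc,
    )


class TestBinFragments:
    def test_counts_by_leftmost_coordinate(self, tmp_path, tiny_layout):
        reads = (
            [("chr1", 100_000 + i, 60) for i in range(4)]
            + [("chr1", int(1.5 * MB) + i, 60) for i in range(3)]
            + [("chr2", int(2.2 * MB) + i, 60) for i in range(3)]
        )
        bam = tmp_path / "t.bam"
        build_bam(bam, reads, tiny_layout.chromosomes)
        profile = bin_fragments(bam, tiny_layout)
        assert profile.counts[tiny_layout.bin_index("chr1", 0)] == 4
        assert profile.counts[tiny_layout.bin_index("chr1", int(1.5 * MB))] == 3
        assert profile.counts[tiny_layout.bin_index("chr2", int(2.2 * MB))] == 3
        assert profile.counts.sum() == 10

    def test_empty_file_gives_all_zero(self, tmp_path, tiny_layout):
        bam = tmp_path / "empty.bam"
        build_bam(bam, [], tiny_layout.chromosomes)
        profile = bin_fragments(bam, tiny_layout)
        assert profile.counts.sum() == 0

    def test_sex_chromosome_reads_are_masked(self, tmp_path, tiny_layout):
        bam = tmp_path / "x.bam"
        build_bam(bam, [("chrX", 100, 60)], tiny_layout.chromosomes)
        profile = bin_fragments(bam, tiny_layout)
        assert profile.counts[profile.unmasked].sum() == 0
        assert (profile.mask[tiny_layout.chrom_slice("chrX")]
                == BinMask.EXCLUDED_SEX).all()

    def test_low_mapq_and_duplicates_excluded(self, tmp_path, tiny_layout):
        reads = [
            ("chr1", 100, 60),
            ("chr1", 200, 10),          # below MAPQ 30
            ("chr1", 300, 60, "dup"),   # duplicate
        ]
        bam = tmp_path / "f.bam"
        build_bam(bam, reads, tiny_layout.chromosomes)
        profile = bin_fragments(bam, tiny_layout)
        assert profile.counts.sum() == 1

    def test_disjoint_chromosomes_rejected(self, tmp_path, tiny_layout):
        bam = tmp_path / "other.bam"
        build_bam(bam, [("chr9", 100, 60)], (("chr9", MB),))
        with pytest.raises(ValueError, match="no chromosomes shared"):
            bin_fragments(bam, tiny_layout)

    def test_chr_prefix_tolerance(self, tmp_path, tiny_layout):
        bam = tmp_path / "bare.bam"
        build_bam(bam, [("1", 100, 60)], (("1", 3 * MB),))
        profile = bin_fragments(bam, tiny_layout)
        assert profile.counts[tiny_layout.bin_index("chr1", 0)] == 1


class TestCorrectGc:
    def test_constant_gc_preserves_proportions(self):
        layout = GenomeLayout((("chr1", 100 * MB),), gc=np.full(100, 0.4))
        rng = np.random.default_rng(0)
        counts = rng.poisson(1000, 100)
        profile = BinnedCoverageProfile(layout, counts)
        corrected = correct_gc(profile)
        ratio = corrected.corrected[corrected.unmasked] / counts[corrected.unmasked]
        assert np.allclose(ratio, ratio[0], rtol=1e-9)

    def test_removes_exponential_gc_bias(self, small_layout):
        rng = np.random.default_rng(1)
        gc = small_layout.gc_filled
        mu = 1000 * np.exp(1.5 * (gc - 0.5))
        profile = BinnedCoverageProfile(small_layout, rng.poisson(mu))
        corrected = correct_gc(profile)
        ok = corrected.unmasked
        slope = np.polyfit(gc[ok], corrected.corrected[ok], 1)[0]
        assert abs(slope) / corrected.corrected[ok].mean() < 0.05

    def test_all_zero_counts_warns(self, small_layout):
        profile = BinnedCoverageProfile(small_layout, np.zeros(small_layout.n_bins))
        with pytest.warns(UserWarning, match="zero"):
            corrected = correct_gc(profile)
        assert np.all(corrected.corrected == 0)

    def test_too_few_bins_rejected(self):
        layout = GenomeLayout((("chr1", 10 * MB),), gc=np.full(10, 0.4))
        profile = BinnedCoverageProfile(layout, np.ones(10))
        with pytest.raises(ValueError, match="50"):
            correct_gc(profile)

    def test_idempotent(self, small_layout):
        rng = np.random.default_rng(2)
        gc = small_layout.gc_filled
        counts = rng.poisson(800 * np.exp(gc - 0.5))
        once = correct_gc(BinnedCoverageProfile(small_layout, counts))
        twice = correct_gc(once)
        ok = twice.unmasked
        rel = np.abs(twice.corrected[ok] - once.corrected[ok]) / once.corrected[ok]
        assert rel.max() < 1e-6


def flat_snps(layout, vaf=0.5):
    rows = []
    for chrom, length in layout.chromosomes:
        if layout.is_sex(chrom):
            continue
        for pos in range(500_000, length, MB):
            rows.append((chrom, pos, vaf, 100))
    return HetSNPTable(pd.DataFrame(rows, columns=["chrom", "pos", "vaf", "depth"]))


def flat_corrected(layout, value=1000.0):
    profile = BinnedCoverageProfile(layout, np.full(layout.n_bins, value))
    profile.corrected = profile.counts.copy()
    return profile


class TestStableRegions:
    def test_flat_germline_all_stable(self, small_layout):
        stable = identify_stable_regions(
            flat_corrected(small_layout), flat_snps(small_layout)
        )
        assert stable.n_stable == int((~small_layout.sex_mask).sum())

    def test_skewed_vaf_region_is_unstable(self, small_layout):
        snps = flat_snps(small_layout)
        table = snps.table.copy()
        inside = (
            (table["chrom"] == "chr1")
            & (table["pos"] >= 40 * MB)
            & (table["pos"] < 60 * MB)
        )
        table.loc[inside, "vaf"] = 0.95
        stable = identify_stable_regions(
            flat_corrected(small_layout), HetSNPTable(table)
        )
        sl = small_layout.chrom_slice("chr1")
        assert not stable.stable[sl][40:60].any()
        assert stable.stable[sl][:40].all()

    def test_coverage_spike_is_unstable(self, small_layout):
        profile = flat_corrected(small_layout)
        sl = small_layout.chrom_slice("chr2")
        profile.corrected[sl.start + 50 : sl.start + 55] *= 3
        stable = identify_stable_regions(profile, flat_snps(small_layout))
        assert not stable.stable[sl.start + 50 : sl.start + 55].any()
        assert stable.stable[sl.start : sl.start + 50].all()

    def test_no_stable_bins_is_an_error(self, small_layout):
        with pytest.raises(ValueError, match="[Pp]aram"):
            identify_stable_regions(
                flat_corrected(small_layout), flat_snps(small_layout, vaf=0.9)
            )

    def test_intervals_are_contiguous_bed(self, small_layout):
        stable = identify_stable_regions(
            flat_corrected(small_layout), flat_snps(small_layout)
        )
        intervals = stable.intervals()
        assert (intervals["end"] > intervals["start"]).all()
        total_bins = sum(
            (row.end - row.start) // MB for row in intervals.itertuples()
        )
        assert total_bins == stable.n_stable


class TestNormalize:
    def make_pair(self, layout, sample_counts, germline_counts):
        sample = BinnedCoverageProfile(layout, sample_counts)
        sample.corrected = sample.counts.copy()
        germline = BinnedCoverageProfile(layout, germline_counts)
        germline.corrected = germline.counts.copy()
        stable = identify_stable_regions(germline, flat_snps(layout))
        return sample, germline, stable

    def test_identical_sample_and_germline_give_zero_log2(self, small_layout):
        counts = np.full(small_layout.n_bins, 900.0)
        sample, germline, stable = self.make_pair(small_layout, counts, counts)
        profile = normalize_and_ratio(sample, germline, stable)
        assert np.allclose(profile.log2_ratio[profile.unmasked], 0.0)

    def test_doubled_region_gives_log2_of_one(self, small_layout):
        # doubled region excluded from the stable baseline ("stable
        # elsewhere"): the log2 ratio there is exactly log2(2) = 1
        germ = np.full(small_layout.n_bins, 1000.0)
        samp = germ.copy()
        sl = small_layout.chrom_slice("chr1")
        samp[sl.start + 20 : sl.start + 40] *= 2
        sample, germline, stable = self.make_pair(small_layout, samp, germ)
        stable.stable[sl.start + 20 : sl.start + 40] = False
        profile = normalize_and_ratio(sample, germline, stable)
        region = profile.log2_ratio[sl.start + 20 : sl.start + 40]
        assert region == pytest.approx(1.0, abs=1e-9)

    def test_zero_germline_bin_is_masked_not_infinite(self, small_layout):
        germ = np.full(small_layout.n_bins, 1000.0)
        germ[5] = 0.0
        samp = np.full(small_layout.n_bins, 1000.0)
        sample, germline, stable = self.make_pair(small_layout, samp, germ)
        profile = normalize_and_ratio(sample, germline, stable)
        assert profile.mask[5] == BinMask.EXCLUDED_LOW_COVERAGE
        assert np.isfinite(profile.log2_ratio[profile.unmasked]).all()

    def test_scaling_invariance(self, small_layout):
        rng = np.random.default_rng(3)
        germ = rng.poisson(1000, small_layout.n_bins).astype(float)
        samp = rng.poisson(1000, small_layout.n_bins).astype(float)
        sample, germline, stable = self.make_pair(small_layout, samp, germ)
        base = normalize_and_ratio(sample, germline, stable)
        scaled_sample, germline2, stable2 = self.make_pair(
            small_layout, samp * 37.0, germ
        )
        scaled = normalize_and_ratio(scaled_sample, germline2, stable2)
        ok = base.unmasked
        assert np.allclose(scaled.log2_ratio[ok], base.log2_ratio[ok], atol=1e-12)
        assert np.allclose(scaled.r_sample[ok], base.r_sample[ok], atol=1e-12)

    def test_stable_mean_is_exactly_one(self, small_layout):
        rng = np.random.default_rng(4)
        germ = rng.poisson(1000, small_layout.n_bins).astype(float)
        samp = rng.poisson(1500, small_layout.n_bins).astype(float)
        sample, germline, stable = self.make_pair(small_layout, samp, germ)
        profile = normalize_and_ratio(sample, germline, stable)
        assert profile.r_sample[stable.stable].mean() == pytest.approx(1, abs=1e-9)
        assert profile.r_germline[stable.stable].mean() == pytest.approx(1, abs=1e-9)

    def test_layout_mismatch_rejected(self, small_layout, tiny_layout):
        sample = flat_corrected(small_layout)
        germline = flat_corrected(tiny_layout)
        stable = identify_stable_regions(
            flat_corrected(small_layout), flat_snps(small_layout)
        )
        with pytest.raises(ValueError, match="layout"):
            normalize_and_ratio(sample, germline, stable)
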