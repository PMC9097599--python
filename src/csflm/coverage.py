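"""Binned coverage: fragment counting, GC correction, stable-region
normalization and log2 copy ratios.

The shallow-WGS copy-number pipeline starts here: aligned fragments (or a
pre-binned count table) are tiled into contiguous 1-Mb windows with sex
chromosomes masked, GC bias is removed by local regression, "stable"
chromosomal stretches — flat coverage and heterozygous-SNP VAF near 0.5 —
are identified from the germline sample, and each sample's coverage is
rescaled so the stable-region mean is 1 before forming per-bin
sample/germline log2 ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .layout import GenomeLayout, strip_chr


class BinMask(IntEnum):
    """Why a bin is excluded from normalization (0 = usable)."""

    OK = 0
    EXCLUDED_SEX = 1
    EXCLUDED_LOW_COVERAGE = 2
    EXCLUDED_UNSTABLE = 3


@dataclass
class BinnedCoverageProfile:
    """Per-window read counts along the genome for one sample."""

    layout: GenomeLayout
    counts: np.ndarray
    corrected: np.ndarray | None = None
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.layout.n_bins,):
            raise ValueError("counts length does not match layout bins")
        if np.any(self.counts < 0):
            raise ValueError("negative bin counts")
        if self.mask is None:
            self.mask = np.where(
                self.layout.sex_mask, BinMask.EXCLUDED_SEX, BinMask.OK
            ).astype(np.int8)
        else:
            self.mask = np.asarray(self.mask, dtype=np.int8).copy()
            self.mask[self.layout.sex_mask] = BinMask.EXCLUDED_SEX
        if self.corrected is not None:
            self.corrected = np.asarray(self.corrected, dtype=float)

    @property
    def unmasked(self) -> np.ndarray:
        return self.mask == BinMask.OK

    @property
    def values(self) -> np.ndarray:
        """GC-corrected values if available, else raw counts."""
        return self.counts if self.corrected is None else self.corrected

    def to_frame(self) -> pd.DataFrame:
        table = self.layout.bins()
        table["count"] = self.counts
        if self.corrected is not None:
            table["corrected"] = self.corrected
        table["mask"] = [BinMask(m).name.lower() for m in self.mask]
        return table

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, layout: GenomeLayout | None = None,
                 sample_id: str = "") -> "BinnedCoverageProfile":
        table = pd.read_csv(path, sep="\t")
        if "count" not in table.columns:
            raise ValueError("bin-count table missing 'count' column")
        if layout is None:
            layout = GenomeLayout.from_tsv(path)
        return cls(layout, table["count"].to_numpy(), sample_id=sample_id)


@dataclass
class HetSNPTable:
    """Heterozygous germline SNP allele fractions (1-based positions)."""

    table: pd.DataFrame  # columns: chrom, pos, vaf, depth

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "vaf", "depth"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"SNP table missing columns: {sorted(missing)}")
        vaf = self.table["vaf"]
        if ((vaf < 0) | (vaf > 1)).any():
            raise ValueError("SNP VAF outside [0, 1]")
        if (self.table["depth"] < 1).any():
            raise ValueError("SNP depth must be >= 1")

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_tsv(cls, path) -> "HetSNPTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def bin_indices(self, layout: GenomeLayout) -> np.ndarray:
        """Global bin index of each SNP (positions converted to 0-based)."""
        idx = np.empty(len(self.table), dtype=int)
        for i, (chrom, pos) in enumerate(
            zip(self.table["chrom"], self.table["pos"])
        ):
            idx[i] = layout.bin_index(str(chrom), int(pos) - 1)
        return idx


@dataclass
class StableRegionParams:
    """Thresholds quantifying a "relatively stable" chromosomal run.

    A maximal run of at least ``min_run`` bins is stable when its corrected
    coverage has coefficient of variation <= ``cv_max``, every bin lies
    within ``rel_tol`` (fractional) of the run median, and every
    heterozygous SNP in the run has |VAF - 0.5| <= ``vaf_tol``.
    """

    cv_max: float = 0.12
    rel_tol: float = 0.15
    vaf_tol: float = 0.08
    min_run: int = 10


@dataclass
class StableRegionMask:
    layout: GenomeLayout
    stable: np.ndarray  # per-bin boolean

    def __post_init__(self) -> None:
        self.stable = np.asarray(self.stable, dtype=bool)
        if self.stable.shape != (self.layout.n_bins,):
            raise ValueError("stable mask length mismatch")

    @property
    def n_stable(self) -> int:
        return int(self.stable.sum())

    def intervals(self) -> pd.DataFrame:
        """Contiguous stable intervals as a BED-like table (0-based)."""
        bins = self.layout.bins()
        rows = []
        for chrom in self.layout.chrom_names:
            sl = self.layout.chrom_slice(chrom)
            flags = self.stable[sl]
            starts = bins["start"].to_numpy()[sl]
            ends = bins["end"].to_numpy()[sl]
            i = 0
            while i < len(flags):
                if flags[i]:
                    j = i
                    while j + 1 < len(flags) and flags[j + 1]:
                        j += 1
                    rows.append((chrom, int(starts[i]), int(ends[j])))
                    i = j + 1
                else:
                    i += 1
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def to_bed(self, path) -> None:
        self.intervals().to_csv(path, sep="\t", index=False, header=False)


@dataclass
class NormalizedProfile:
    """Stable-region-normalized representation and log2 sample/germline ratio.

    ``r_sample`` and ``r_germline`` are dimensionless coverages rescaled so
    that each sample's mean over stable bins is exactly 1; ``log2_ratio`` is
    log2(r_sample / r_germline) per bin, finite on all unmasked bins.
    """

    layout: GenomeLayout
    r_sample: np.ndarray
    r_germline: np.ndarray
    log2_ratio: np.ndarray
    mask: np.ndarray
    sample_id: str = ""

    @property
    def unmasked(self) -> np.ndarray:
        return self.mask == BinMask.OK

    @property
    def ratio(self) -> np.ndarray:
        """Per-bin normalized representation r_sample / r_germline."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.r_sample / self.r_germline

    def to_frame(self) -> pd.DataFrame:
        table = self.layout.bins()[["chrom", "start", "end"]]
        table["r_sample"] = self.r_sample
        table["r_germline"] = self.r_germline
        table["log2_ratio"] = self.log2_ratio
        table["mask"] = [BinMask(m).name.lower() for m in self.mask]
        return table

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def bin_fragments(
    alignments,
    layout: GenomeLayout,
    min_mapq: int = 30,
    exclude_duplicates: bool = True,
    sample_id: str = "",
) -> BinnedCoverageProfile:
    """Count aligned fragments per genomic window.

    Each passing fragment contributes one count to the bin containing its
    leftmost mapped coordinate. For paired-end data only the first read of
    each properly tracked pair is counted so a template is never counted
    twice. Unmapped, secondary, supplementary, duplicate (optional) and
    low-MAPQ reads are skipped. Chromosome naming is chr-prefix tolerant.

    ``alignments`` is a path to a coordinate-sorted, indexed BAM/SAM or an
    open :class:`pysam.AlignmentFile`.
    """
    import pysam

    handle = (
        alignments
        if isinstance(alignments, pysam.AlignmentFile)
        else pysam.AlignmentFile(str(alignments))
    )
    layout_bare = {strip_chr(name) for name in layout.chrom_names}
    file_bare = {strip_chr(name) for name in handle.references}
    if handle.references and not (layout_bare & file_bare):
        raise ValueError(
            "no chromosomes shared between alignment file and layout"
        )
    counts = np.zeros(layout.n_bins, dtype=float)
    for read in handle.fetch(until_eof=True):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if exclude_duplicates and read.is_duplicate:
            continue
        if read.mapping_quality < min_mapq:
            continue
        if read.is_paired and read.is_read2:
            continue  # one count per template
        if strip_chr(read.reference_name) not in layout_bare:
            continue
        counts[layout.bin_index(read.reference_name, read.reference_start)] += 1
    return BinnedCoverageProfile(layout, counts, sample_id=sample_id)


def correct_gc(
    profile: BinnedCoverageProfile,
    layout: GenomeLayout | None = None,
    frac: float = 0.4,
    min_bins: int = 50,
) -> BinnedCoverageProfile:
    """Remove GC bias by local (LOESS-style) regression of count on GC.

    Fits count ~ f(gc) over unmasked bins, divides each count by the fitted
    value and rescales so the median corrected value equals the median raw
    count. Bins whose GC lies outside the fitted support are masked
    ``excluded_low_coverage``.
    """
    layout = layout or profile.layout
    gc = layout.gc_filled
    mask = profile.mask.copy()
    ok = mask == BinMask.OK
    if ok.sum() < min_bins:
        raise ValueError(
            f"only {int(ok.sum())} unmasked bins; need >= {min_bins} for a "
            "reliable GC fit"
        )
    counts = profile.counts
    if not np.any(counts[ok] > 0):
        warnings.warn("all unmasked counts are zero; GC correction is a no-op")
        return replace(profile, corrected=counts.copy(), mask=mask)

    if np.ptp(gc[ok]) < 1e-9:  # constant GC: nothing to fit, no bias
        corrected = counts.astype(float).copy()
        corrected[~ok] = 0.0
        return replace(profile, corrected=corrected, mask=mask)

    fitted_xy = lowess(counts[ok], gc[ok], frac=frac, return_sorted=True)
    xs, ys = fitted_xy[:, 0], fitted_xy[:, 1]
    lo, hi = xs.min(), xs.max()
    corrected = np.zeros_like(counts)
    support = (gc >= lo) & (gc <= hi)
    out_of_support = ok & ~support
    mask[out_of_support] = BinMask.EXCLUDED_LOW_COVERAGE
    ok = mask == BinMask.OK

    expected = np.interp(gc[ok], xs, ys)
    expected = np.maximum(expected, 1e-12)
    ratio = counts[ok] / expected
    scale = np.median(counts[ok]) / max(np.median(ratio), 1e-12)
    corrected[ok] = ratio * scale
    return replace(profile, corrected=corrected, mask=mask)


def identify_stable_regions(
    germline: BinnedCoverageProfile,
    snps: HetSNPTable,
    params: StableRegionParams | None = None,
) -> StableRegionMask:
    """Find stable chromosomal regions in the germline sample.

    Stable regions serve as the normalization baseline: coverage flat
    (run CV and per-bin deviation bounded) and heterozygous SNP VAFs near
    0.5 (balanced alleles, no germline copy-number change).
    """
    params = params or StableRegionParams()
    if germline.corrected is None:
        raise ValueError("germline profile must be GC-corrected first")
    if len(snps) == 0:
        raise ValueError("SNP table is empty")

    layout = germline.layout
    snp_bad = np.zeros(layout.n_bins, dtype=bool)
    idx = snps.bin_indices(layout)
    bad = np.abs(snps.table["vaf"].to_numpy() - 0.5) > params.vaf_tol
    np.add.at(snp_bad, idx[bad], True)

    candidate = germline.unmasked & ~snp_bad
    values = germline.corrected
    stable = np.zeros(layout.n_bins, dtype=bool)

    def accept_run(indices: np.ndarray) -> None:
        if len(indices) < params.min_run:
            return
        run_vals = values[indices]
        med = np.median(run_vals)
        if med <= 0:
            return
        within = np.abs(run_vals - med) <= params.rel_tol * med
        # deviant bins split the run; recurse on the kept sub-runs
        if not within.all():
            for sub in _contiguous_true(indices, within):
                accept_run(sub)
            return
        mean = run_vals.mean()
        cv = run_vals.std() / mean if mean > 0 else np.inf
        if cv <= params.cv_max:
            stable[indices] = True

    for chrom in layout.chrom_names:
        sl = layout.chrom_slice(chrom)
        flags = candidate[sl]
        global_idx = np.arange(sl.start, sl.stop)
        for sub in _contiguous_true(global_idx, flags):
            accept_run(sub)

    if not stable.any():
        raise ValueError(
            "no stable regions found; review StableRegionParams thresholds "
            "(cv_max/rel_tol/vaf_tol/min_run) against the germline profile"
        )
    return StableRegionMask(layout, stable)


def _contiguous_true(indices: np.ndarray, flags: np.ndarray) -> list[np.ndarray]:
    """Maximal runs of indices where flags is True (indices are contiguous)."""
    runs: list[np.ndarray] = []
    current: list[int] = []
    for i, flag in zip(indices, flags):
        if flag:
            current.append(int(i))
        elif current:
            runs.append(np.asarray(current))
            current = []
    if current:
        runs.append(np.asarray(current))
    return runs


def normalize_and_ratio(
    sample: BinnedCoverageProfile,
    germline: BinnedCoverageProfile,
    stable: StableRegionMask,
    germline_floor: float = 0.1,
) -> NormalizedProfile:
    """Rescale to the stable-region mean and form log2 sample/germline ratios.

    Each sample's corrected coverage is divided by its own mean over stable
    bins ("adjusted to the mean coverage of stable chromosomal regions"),
    making both representations dimensionless with stable-region mean 1.
    Bins where the germline representation falls below ``germline_floor``
    are masked rather than producing unbounded ratios.
    """
    if sample.layout.chromosomes != germline.layout.chromosomes:
        raise ValueError("sample and germline layouts differ")
    if stable.n_stable == 0:
        raise ValueError("stable mask is empty")
    layout = sample.layout
    mask = np.maximum(sample.mask, germline.mask).astype(np.int8)

    def normalized(profile: BinnedCoverageProfile) -> np.ndarray:
        values = profile.values
        baseline = values[stable.stable].mean()
        if baseline <= 0:
            raise ValueError("stable-region mean coverage is not positive")
        return values / baseline

    r_sample = normalized(sample)
    r_germline = normalized(germline)
    low = (mask == BinMask.OK) & (r_germline < germline_floor)
    mask[low] = BinMask.EXCLUDED_LOW_COVERAGE

    log2_ratio = np.full(layout.n_bins, np.nan)
    ok = mask == BinMask.OK
    log2_ratio[ok] = np.log2(r_sample[ok] / r_germline[ok])
    return NormalizedProfile(
        layout, r_sample, r_germline, log2_ratio, mask,
        sample_id=sample.sample_id,
    )
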