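"""Synthetic inputs with known ground truth for every pipeline stage.

The cohort's raw sequencing data are controlled-access, so every consumer
of this package's pipeline is exercised on simulated data that emulates the
relevant structure of shallow-WGS cfDNA: binned coverage with multiplicative
GC bias and overdispersed (negative-binomial) count noise, segmental copy-
number aberrations diluted by tumor fraction, germline-unstable regions
with skewed heterozygous-SNP allele fractions, bimodal fragment-length
mixtures (tumor-like ~145 bp vs mononucleosomal ~167 bp), paired
compartment variant sets with shared and private calls, and two-group
exponential survival with censoring. Everything is seeded and
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import BinnedCoverageProfile, HetSNPTable
from .layout import GenomeLayout
from .survival import SurvivalRecord
from .variants import SampleVariantSet, VariantCall

MB = 1_000_000


@dataclass(frozen=True)
class CNSegment:
    """One simulated copy-number aberration (0-based half-open bp)."""

    chrom: str
    start: int
    end: int
    copy_number: int
    compartment: str = "tumor"  # "tumor" | "germline"

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise ValueError("copy number must be >= 0")
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")
        if self.compartment not in ("tumor", "germline"):
            raise ValueError("compartment must be tumor or germline")


@dataclass
class SimulationConfig:
    """Knobs of the binned-coverage simulator.

    Expected count in bin i is
    ``mean_depth * exp(gc_bias_coeff * (gc_i - 0.5)) * [(1-tf)*2 + tf*cn_i] / 2``
    for the cfDNA sample (germline copy number replaces the bracket for the
    germline profile), drawn with negative-binomial noise of variance
    ``mu * (1 + dispersion * mu)``.
    """

    layout: GenomeLayout
    mean_depth_per_bin: float = 10_000.0  # ~3x WGS, PE150, 1-Mb bins
    tumor_fraction: float = 0.6
    segments: tuple[CNSegment, ...] = ()
    gc_bias_coeff: float = 1.0
    dispersion: float = 0.003
    seed: int | None = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        self.segments = tuple(self.segments)
        for compartment in ("tumor", "germline"):
            by_chrom: dict[str, list[CNSegment]] = {}
            for seg in self.segments:
                if seg.compartment == compartment:
                    by_chrom.setdefault(seg.chrom, []).append(seg)
            for segs in by_chrom.values():
                segs.sort(key=lambda s: s.start)
                for a, b in zip(segs, segs[1:]):
                    if b.start < a.end:
                        raise ValueError(
                            f"overlapping {compartment} segments on {a.chrom}"
                        )


@dataclass
class TruthSet:
    """Ground truth recorded alongside a simulated profile pair."""

    true_breakpoints: list[tuple[str, int]]
    true_lst: int
    true_segment_means: np.ndarray  # expected log2 ratio per bin
    unstable_germline_regions: list[tuple[str, int, int]]
    het_snps: HetSNPTable | None = None


def _copy_number_per_bin(
    layout: GenomeLayout, segments: tuple[CNSegment, ...], compartment: str
) -> np.ndarray:
    """Copy number of each bin (bin assigned the state at its midpoint)."""
    cn = np.full(layout.n_bins, 2.0)
    bins = layout.bins()
    mid = (bins["start"].to_numpy() + bins["end"].to_numpy()) // 2
    offsets = layout.chrom_offsets()
    for seg in segments:
        if seg.compartment != compartment:
            continue
        sl = layout.chrom_slice(seg.chrom)
        local_mid = mid[sl]
        inside = (local_mid >= seg.start) & (local_mid < seg.end)
        cn[offsets[seg.chrom] : offsets[seg.chrom] + len(local_mid)][inside] = (
            seg.copy_number
        )
    return cn


def _true_lst_from_spec(
    layout: GenomeLayout,
    segments: tuple[CNSegment, ...],
    tumor_fraction: float,
    min_len: int = 3 * MB,
    min_flank: int = 10 * MB,
) -> tuple[int, list[tuple[str, int]]]:
    """Brute-force scan of the segment specification.

    Builds the bp-resolution expected copy-number map per chromosome,
    absorbs runs shorter than ``min_len`` into the closer-copy-number
    neighbor, merges equal neighbors, and counts boundaries between runs of
    at least ``min_flank`` on each side. With zero tumor fraction no
    boundary carries signal and the count is 0.
    """
    if tumor_fraction == 0:
        return 0, []
    breakpoints: list[tuple[str, int]] = []
    lst = 0
    for chrom, length in layout.chromosomes:
        if layout.is_sex(chrom):
            continue
        cuts = {0, length}
        for seg in segments:
            if seg.compartment == "tumor" and seg.chrom == chrom:
                cuts.update((seg.start, min(seg.end, length)))
        edges = sorted(cuts)
        runs: list[list] = []  # [start, end, cn]
        for a, b in zip(edges, edges[1:]):
            mid = (a + b) // 2
            cn = 2
            for seg in segments:
                if (
                    seg.compartment == "tumor"
                    and seg.chrom == chrom
                    and seg.start <= mid < seg.end
                ):
                    cn = seg.copy_number
            if runs and runs[-1][2] == cn:
                runs[-1][1] = b
            else:
                runs.append([a, b, cn])
        # absorb short runs into the closer-copy-number neighbor
        while True:
            short = [
                (r[1] - r[0], i)
                for i, r in enumerate(runs)
                if r[1] - r[0] < min_len
            ]
            if not short or len(runs) == 1:
                break
            _, i = min(short)
            neighbors = [j for j in (i - 1, i + 1) if 0 <= j < len(runs)]
            j = min(neighbors, key=lambda k: abs(runs[k][2] - runs[i][2]))
            lo, hi = min(i, j), max(i, j)
            runs[lo:hi + 1] = [[runs[lo][0], runs[hi][1], runs[j][2]]]
            merged = True
            while merged:
                merged = False
                for k in range(len(runs) - 1):
                    if runs[k][2] == runs[k + 1][2]:
                        runs[k:k + 2] = [[runs[k][0], runs[k + 1][1], runs[k][2]]]
                        merged = True
                        break
        for left, right in zip(runs, runs[1:]):
            if (
                left[1] - left[0] >= min_flank
                and right[1] - right[0] >= min_flank
                and left[2] != right[2]
            ):
                lst += 1
                breakpoints.append((chrom, left[1]))
    return lst, breakpoints


def _nb_counts(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    """Gamma-Poisson draw with variance mu * (1 + dispersion * mu)."""
    mu = np.clip(mu, 1e-9, None)
    if dispersion == 0:
        return rng.poisson(mu).astype(float)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam).astype(float)


def simulate_bin_counts(
    config: SimulationConfig,
) -> tuple[BinnedCoverageProfile, BinnedCoverageProfile, TruthSet]:
    """Simulate a matched germline/cfDNA binned-coverage pair.

    Returns (germline, sample, truth); identical config (including seed)
    reproduces identical profiles. Het-SNP allele fractions are attached to
    the truth set: ~0.5 in balanced regions, skewed inside germline-
    aberrant regions.
    """
    layout = config.layout
    rng = np.random.default_rng(config.seed)
    gc_bias = np.exp(config.gc_bias_coeff * (layout.gc_filled - 0.5))
    tf = config.tumor_fraction

    cn_tumor = _copy_number_per_bin(layout, config.segments, "tumor")
    cn_germ = _copy_number_per_bin(layout, config.segments, "germline")

    mixture = ((1 - tf) * 2 + tf * cn_tumor) / 2.0
    mu_sample = config.mean_depth_per_bin * gc_bias * mixture
    mu_germ = config.mean_depth_per_bin * gc_bias * (cn_germ / 2.0)

    sample_counts = _nb_counts(rng, mu_sample, config.dispersion)
    germ_counts = _nb_counts(rng, mu_germ, config.dispersion)

    germline = BinnedCoverageProfile(layout, germ_counts, sample_id="germline")
    sample = BinnedCoverageProfile(layout, sample_counts, sample_id="sample")

    true_lst, breakpoints = _true_lst_from_spec(
        layout, config.segments, tf
    )
    with np.errstate(divide="ignore"):
        expected_log2 = np.log2(np.clip(mixture, 1e-12, None)) - np.log2(
            np.clip(cn_germ / 2.0, 1e-12, None)
        )
    unstable = [
        (s.chrom, s.start, s.end)
        for s in config.segments
        if s.compartment == "germline" and s.copy_number != 2
    ]
    snps = _simulate_het_snps(layout, unstable, rng)
    truth = TruthSet(
        true_breakpoints=breakpoints,
        true_lst=true_lst,
        true_segment_means=expected_log2,
        unstable_germline_regions=unstable,
        het_snps=snps,
    )
    return germline, sample, truth


def _simulate_het_snps(
    layout: GenomeLayout,
    unstable: list[tuple[str, int, int]],
    rng: np.random.Generator,
    spacing: int = 500_000,
) -> HetSNPTable:
    """Het-SNP VAF table: balanced (~0.5) except in germline-aberrant spans."""
    rows = []
    for chrom, length in layout.chromosomes:
        if layout.is_sex(chrom):
            continue
        for pos0 in range(spacing // 2, length, spacing):
            in_unstable = any(
                c == chrom and a <= pos0 < b for c, a, b in unstable
            )
            if in_unstable:
                vaf = 0.95 if rng.random() < 0.5 else 0.05
                vaf += rng.normal(0, 0.02)
            else:
                vaf = rng.normal(0.5, 0.02)
            rows.append(
                (chrom, pos0 + 1, float(np.clip(vaf, 0.0, 1.0)),
                 int(rng.integers(80, 400)))
            )
    return HetSNPTable(
        pd.DataFrame(rows, columns=["chrom", "pos", "vaf", "depth"])
    )


# ---------------------------------------------------------------------------
# fragment lengths
# ---------------------------------------------------------------------------

SHORT_MODE_BP = 145.0  # tumor-like sub-mononucleosomal mode
MONO_MODE_BP = 167.0   # mononucleosomal mode
MODE_SD_BP = 10.0


@dataclass
class FragmentLengthSample:
    lengths: np.ndarray
    compartment: str = "CSF"
    mixture_weight_short: float = 0.5

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=int)
        if np.any((self.lengths < 20) | (self.lengths > 600)):
            raise ValueError("fragment lengths outside [20, 600]")

    def to_tsv(self, path) -> None:
        pd.Series(self.lengths, name="length").to_csv(path, sep="\t", index=False)


def simulate_fragments(
    n: int,
    weight_short: float,
    seed: int | None = 0,
    compartment: str = "CSF",
) -> FragmentLengthSample:
    """Draw cfDNA fragment lengths from a two-normal mixture.

    ``weight_short`` is the probability mass of the short (~145 bp)
    tumor-like component; the remainder sits on the mononucleosomal
    ~167 bp mode. Lengths are rounded to integers and clipped to [20, 600].
    """
    if n < 1:
        raise ValueError("need n >= 1 fragments")
    if not 0.0 <= weight_short <= 1.0:
        raise ValueError("weight_short must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    short = rng.random(n) < weight_short
    modes = np.where(short, SHORT_MODE_BP, MONO_MODE_BP)
    lengths = np.clip(np.rint(rng.normal(modes, MODE_SD_BP)), 20, 600)
    return FragmentLengthSample(
        lengths.astype(int), compartment=compartment,
        mixture_weight_short=weight_short,
    )


# ---------------------------------------------------------------------------
# paired variants
# ---------------------------------------------------------------------------

_SIM_GENES = (
    "EGFR", "TP53", "KRAS", "ALK", "ERBB2", "MET", "BRAF", "PIK3CA",
    "STK11", "KEAP1", "RB1", "PTEN", "CDKN2A", "NF1", "SMARCA4", "ARID1A",
)
_BASES = "ACGT"


def simulate_paired_variants(
    n_shared: int,
    n_csf_only: int,
    n_plasma_only: int,
    vaf_ranges: dict | None = None,
    seed: int | None = 0,
    patient_id: str = "SIM",
) -> tuple[SampleVariantSet, SampleVariantSet]:
    """Build matched CSF/plasma variant sets with a known partition.

    The true partition sizes are exactly the three requested counts: every
    generated call passes the default filters (VAF >= 0.1%, >= 4 unique
    reads, somatic), and nucleotide changes are unique across categories so
    the shared/private structure cannot collapse. CSF VAFs are drawn high
    (ctDNA-enriched compartment), plasma VAFs low, unless ``vaf_ranges``
    overrides ``{"CSF": (lo, hi), "plasma": (lo, hi)}``.
    """
    for name, count in (
        ("n_shared", n_shared), ("n_csf_only", n_csf_only),
        ("n_plasma_only", n_plasma_only),
    ):
        if count < 0:
            raise ValueError(f"{name} must be >= 0")
    ranges = {"CSF": (0.01, 0.6), "plasma": (0.001, 0.05)}
    if vaf_ranges:
        ranges.update(vaf_ranges)
    rng = np.random.default_rng(seed)
    total = n_shared + n_csf_only + n_plasma_only
    positions = rng.choice(np.arange(1000, 1000 + 10 * max(total, 1), 10),
                           size=total, replace=False) if total else []

    def make_call(i: int, compartment: str) -> VariantCall:
        pos = int(positions[i])
        ref, alt = rng.choice(list(_BASES), size=2, replace=False)
        lo, hi = ranges[compartment]
        return VariantCall(
            sample_id=f"{patient_id}-{compartment}",
            gene=_SIM_GENES[i % len(_SIM_GENES)],
            var_class="SNV",
            vaf=float(rng.uniform(lo, hi)),
            unique_reads=int(rng.integers(4, 500)),
            chrom="chr7",
            pos=pos,
            ref=str(ref),
            alt=str(alt),
            nt_change=f"{pos}{ref}>{alt}",
            protein_change=f"p{i}",
        )

    csf_calls: list[VariantCall] = []
    plasma_calls: list[VariantCall] = []
    for i in range(n_shared):
        call = make_call(i, "CSF")
        csf_calls.append(call)
        # same alteration, compartment-specific VAF and support
        lo, hi = ranges["plasma"]
        plasma_calls.append(
            VariantCall(
                sample_id=f"{patient_id}-plasma",
                gene=call.gene, var_class="SNV",
                vaf=float(rng.uniform(lo, hi)),
                unique_reads=int(rng.integers(4, 500)),
                chrom=call.chrom, pos=call.pos, ref=call.ref, alt=call.alt,
                nt_change=call.nt_change, protein_change=call.protein_change,
            )
        )
    for i in range(n_shared, n_shared + n_csf_only):
        csf_calls.append(make_call(i, "CSF"))
    for i in range(n_shared + n_csf_only, total):
        plasma_calls.append(make_call(i, "plasma"))

    return (
        SampleVariantSet.from_calls("CSF", patient_id, csf_calls),
        SampleVariantSet.from_calls("plasma", patient_id, plasma_calls),
    )


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def simulate_survival(
    n_per_group: int,
    median_high: float,
    median_low: float,
    censor_rate: float = 0.0,
    seed: int | None = 0,
) -> list[SurvivalRecord]:
    """Two-group exponential survival with independent censoring.

    Event times are exponential with the requested group medians
    (rate = ln 2 / median); "high" is the high-instability, short-survival
    group. Censoring times are uniform on (0, c_max) and independent of the
    event times, with c_max solved so the expected censored fraction equals
    ``censor_rate`` (informative censoring would bias the KM median).
    """
    if median_high <= 0 or median_low <= 0:
        raise ValueError("group medians must be positive")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    records: list[SurvivalRecord] = []
    for group, median, score_loc in (
        ("high_lst", median_high, 22.0),
        ("low_lst", median_low, 8.0),
    ):
        rate = np.log(2) / median
        times = rng.exponential(1.0 / rate, size=n_per_group)
        if censor_rate > 0:
            # P(censored) = (1 - exp(-rate*c)) / (rate*c) for C ~ U(0, c)
            from scipy.optimize import brentq

            x = brentq(
                lambda v: -np.expm1(-v) / v - censor_rate, 1e-9, 1e6
            )
            censor_times = rng.uniform(0, x / rate, size=n_per_group)
        else:
            censor_times = np.full(n_per_group, np.inf)
        censored = censor_times < times
        observed = np.minimum(times, censor_times)
        observed = np.maximum(observed, 1e-6)
        scores = rng.normal(score_loc, 2.0, size=n_per_group)
        for i in range(n_per_group):
            records.append(
                SurvivalRecord(
                    patient_id=f"{group}-{i:04d}",
                    time=float(observed[i]),
                    event=not bool(censored[i]),
                    group=group,
                    score=float(scores[i]),
                )
            )
    return records


def write_survival_tsv(records: list[SurvivalRecord], path) -> None:
    pd.DataFrame(
        [(r.patient_id, r.time, int(r.event), r.score, r.group) for r in records],
        columns=["patient_id", "time", "event", "score", "group"],
    ).to_csv(path, sep="\t", index=False)
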