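"""Genome-instability statistics from segmented shallow-WGS profiles.

Two per-sample scores:

* **LST** (large-scale state transition count): after smoothing away
  sub-3-Mb copy-number events, the number of within-chromosome breakpoints
  between adjacent segments that are each at least 10 Mb long and differ in
  mean log2 ratio by at least ``min_change``. High LST counts indicate
  large-scale chromosomal rearrangement of the kind associated with
  homologous-recombination deficiency.

* **GIN** (genome instability number): the sum over unmasked autosomal bins
  of the absolute deviation of the normalized genomic representation
  (sample/germline coverage ratio) from its expectation over stable
  regions, reported on a x100 scale.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .coverage import NormalizedProfile, StableRegionMask
from .segmentation import Segment, SegmentProfile, segment_profile

MB = 1_000_000


@dataclass
class SmoothedSegments(SegmentProfile):
    """Segments after short-event absorption and similar-neighbor merging."""


@dataclass
class InstabilityScores:
    lst: int
    gin: float
    n_bins_used: int
    sample_id: str = ""
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "lst": self.lst,
            "gin": self.gin,
            "n_bins_used": self.n_bins_used,
            "params": self.params,
        }


@dataclass
class ScoreParams:
    """Tunables of the segment → smooth → count pipeline.

    Lengths in bp; log2 thresholds dimensionless. ``min_change`` is the
    smallest mean log2 shift accepted as a genuine state transition: below
    the shallow-WGS noise floor a boundary is not a credible copy-number
    change.
    """

    alpha: float = 0.01
    min_bins: int = 2
    n_perm: int = 1000
    min_len: int = 3 * MB
    merge_delta: float = 0.1
    min_flank: int = 10 * MB
    min_change: float = 0.1
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "min_bins": self.min_bins,
            "n_perm": self.n_perm,
            "min_len": self.min_len,
            "merge_delta": self.merge_delta,
            "min_flank": self.min_flank,
            "min_change": self.min_change,
            "seed": self.seed,
        }


def _combine(a: Segment, b: Segment, mean: float, weight: int,
             flag: str) -> Segment:
    indices = None
    if a.bin_indices is not None and b.bin_indices is not None:
        indices = np.concatenate([a.bin_indices, b.bin_indices])
    seg = Segment(
        chrom=a.chrom,
        start=min(a.start, b.start),
        end=max(a.end, b.end),
        mean=mean,
        n_bins=a.n_bins + b.n_bins,
        bin_indices=indices,
        flag=flag,
    )
    seg.weight = weight  # bins whose values still back the mean
    return seg


def _smooth_chromosome(
    segs: list[Segment], min_len: int, merge_delta: float
) -> list[Segment]:
    segs = [copy.copy(s) for s in segs]
    for s in segs:
        s.weight = s.n_bins
    while True:
        changed = False
        # filter the shortest sub-threshold segment: its bins extend the
        # closer-mean neighbor but are dropped from that neighbor's mean, so
        # a small-scale event leaves the surrounding copy state untouched
        while True:
            short = [
                (s.length, i) for i, s in enumerate(segs) if s.length < min_len
            ]
            if not short or len(segs) == 1:
                break
            _, i = min(short)
            victim = segs[i]
            neighbors = []
            if i > 0:
                neighbors.append(i - 1)
            if i < len(segs) - 1:
                neighbors.append(i + 1)
            j = min(neighbors, key=lambda k: abs(segs[k].mean - victim.mean))
            lo, hi = min(i, j), max(i, j)
            merged = _combine(
                segs[lo], segs[hi], mean=segs[j].mean, weight=segs[j].weight,
                flag="absorbed_short",
            )
            segs[lo : hi + 1] = [merged]
            changed = True
        # merge adjacent segments with near-identical means (weighted mean
        # over the bins still backing each side)
        i = 0
        while i < len(segs) - 1:
            a, b = segs[i], segs[i + 1]
            if abs(a.mean - b.mean) < merge_delta:
                w = a.weight + b.weight
                mean = (a.mean * a.weight + b.mean * b.weight) / w
                segs[i : i + 2] = [
                    _combine(a, b, mean=mean, weight=w, flag="merged_similar")
                ]
                changed = True
            else:
                i += 1
        if not changed:
            break
    if len(segs) == 1 and segs[0].length < min_len:
        segs[0].flag = "terminal_remnant"
    return segs


def smooth_segments(
    segments: SegmentProfile,
    min_len: int = 3 * MB,
    merge_delta: float = 0.1,
) -> SmoothedSegments:
    """Filter small-scale copy-number variation out of a segment profile.

    Iterates to a fixed point: the shortest segment below ``min_len``
    (default 3 Mb) is absorbed into the flanking neighbor whose mean is
    closer (bin-weighted mean recomputed), then adjacent segments whose
    means differ by less than ``merge_delta`` are merged. A short segment
    that is alone on its chromosome has no neighbor and survives flagged
    ``terminal_remnant``.
    """
    out: list[Segment] = []
    by_chrom: dict[str, list[Segment]] = {}
    for seg in segments.segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom_segs in by_chrom.values():
        out.extend(_smooth_chromosome(chrom_segs, min_len, merge_delta))
    return SmoothedSegments(out, sample_id=segments.sample_id)


def count_lst(
    smoothed: SmoothedSegments,
    min_flank: int = 10 * MB,
    min_change: float = 0.1,
) -> int:
    """Count large-scale state transitions in a smoothed segment profile.

    A boundary between two adjacent within-chromosome segments counts when
    both flanking segments span at least ``min_flank`` (default 10 Mb) and
    their mean log2 ratios differ by at least ``min_change``. Chromosome
    ends are never boundaries.
    """
    lst = 0
    by_chrom: dict[str, list[Segment]] = {}
    for seg in smoothed.segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for segs in by_chrom.values():
        for a, b in zip(segs, segs[1:]):
            if (
                a.length >= min_flank
                and b.length >= min_flank
                and abs(a.mean - b.mean) >= min_change
            ):
                lst += 1
    return lst


def compute_gin(
    profile: NormalizedProfile, stable: StableRegionMask
) -> float:
    """Genome instability number of a normalized profile.

    The expectation E is the mean sample/germline representation ratio over
    stable unmasked bins; GIN is ``sum over unmasked autosomal bins of
    100 * |ratio_i - E|``. Identical sample and germline give exactly 0.
    """
    ok = profile.unmasked & ~profile.layout.sex_mask
    if not ok.any():
        raise ValueError("no unmasked autosomal bins")
    ratio = profile.ratio
    baseline = ok & stable.stable
    if not baseline.any():
        raise ValueError("no stable unmasked bins to define the expectation")
    expectation = ratio[baseline].mean()
    return float(100.0 * np.abs(ratio[ok] - expectation).sum())


def score_sample(
    profile: NormalizedProfile,
    stable: StableRegionMask,
    params: ScoreParams | None = None,
) -> tuple[InstabilityScores, SmoothedSegments]:
    """Full instability scoring: segment, smooth, count LST, compute GIN."""
    params = params or ScoreParams()
    raw = segment_profile(
        profile,
        alpha=params.alpha,
        min_bins=params.min_bins,
        n_perm=params.n_perm,
        seed=params.seed,
    )
    smoothed = smooth_segments(
        raw, min_len=params.min_len, merge_delta=params.merge_delta
    )
    lst = count_lst(
        smoothed, min_flank=params.min_flank, min_change=params.min_change
    )
    gin = compute_gin(profile, stable)
    scores = InstabilityScores(
        lst=lst,
        gin=gin,
        n_bins_used=int((profile.unmasked & ~profile.layout.sex_mask).sum()),
        sample_id=profile.sample_id,
        params=params.to_dict(),
    )
    return scores, smoothed
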