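"""Shared fixtures: small synthetic genomes and full pipeline runs."""

from __future__ import annotations

import numpy as np
import pytest

from csflm.coverage import (
    correct_gc,
    identify_stable_regions,
    normalize_and_ratio,
)
from csflm.instability import ScoreParams, score_sample
from csflm.layout import GenomeLayout
from csflm.simulate import CNSegment, SimulationConfig, simulate_bin_counts

MB = 1_000_000


@pytest.fixture(scope="session")
def small_layout() -> GenomeLayout:
    """Four 120-Mb autosomes with smoothly varying GC, 1-Mb bins."""
    return GenomeLayout.synthetic(n_autosomes=4, chrom_length=120 * MB, seed=7)


@pytest.fixture(scope="session")
def six_transition_segments() -> tuple[CNSegment, ...]:
    """Three interstitial events, each contributing two >=10-Mb-flank
    transitions: six qualifying breakpoints in total."""
    return (
        CNSegment("chr1", 30 * MB, 60 * MB, 3),
        CNSegment("chr2", 40 * MB, 80 * MB, 1),
        CNSegment("chr3", 30 * MB, 60 * MB, 4),
    )


def run_scoring(layout, segments, tumor_fraction, depth, seed,
                score_params: ScoreParams | None = None):
    """Simulate a pair and run the full scoring pipeline; returns
    (truth, scores, stable, profile)."""
    config = SimulationConfig(
        layout=layout,
        mean_depth_per_bin=depth,
        tumor_fraction=tumor_fraction,
        segments=segments,
        seed=seed,
    )
    germline, sample, truth = simulate_bin_counts(config)
    germline = correct_gc(germline)
    sample = correct_gc(sample)
    stable = identify_stable_regions(germline, truth.het_snps)
    profile = normalize_and_ratio(sample, germline, stable)
    params = score_params or ScoreParams(seed=seed)
    scores, smoothed = score_sample(profile, stable, params)
    return truth, scores, stable, profile


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240817)
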