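"""Survival association of instability scores: median split, Kaplan–Meier,
log-rank, fixed-horizon survival rates.

The product-limit estimation and the log-rank statistic are delegated to
lifelines; this module adds the cohort conventions (ties at the median
cutoff go to the high-instability group, ">"-prefixed follow-up times are
right-censored) and a step-function evaluation of survival at a horizon.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

HIGH_GROUP = "high_lst"
LOW_GROUP = "low_lst"


@dataclass
class SurvivalRecord:
    patient_id: str
    time: float  # months
    event: bool  # True = death observed
    group: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"survival time must be > 0 ({self.patient_id})")


@dataclass
class KMCurve:
    """Kaplan–Meier step function.

    ``times``/``survival`` define a right-continuous step function starting
    at S(0) = 1. ``median`` is the smallest time with S(t) <= 0.5, or None
    when the curve never crosses 0.5.
    """

    times: np.ndarray
    survival: np.ndarray
    median: float | None
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        """S(t): the step value just after the last event time <= t."""
        if t < 0:
            raise ValueError("time must be >= 0")
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival})


def records_to_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.patient_id, r.time, r.event, r.group, r.score) for r in records],
        columns=["patient_id", "time", "event", "group", "score"],
    )


def read_survival_tsv(path) -> list[SurvivalRecord]:
    table = pd.read_csv(path, sep="\t")
    missing = {"patient_id", "time", "event"} - set(table.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    return [
        SurvivalRecord(
            patient_id=str(row["patient_id"]),
            time=float(row["time"]),
            event=bool(row["event"]),
            group=row.get("group") if isinstance(row.get("group"), str) else None,
            score=float(row["score"]) if "score" in row and pd.notna(row["score"]) else None,
        )
        for row in table.to_dict("records")
    ]


def dichotomize_by_median(scores: dict[str, float]) -> dict[str, str]:
    """Split patients at the sample median of their scores.

    A patient whose score is >= the median goes to the high-instability
    group (the cutoff itself belongs to "high"). The median is the standard
    sample median (mean of central order statistics for even n).
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 patients to dichotomize")
    cutoff = float(np.median(list(scores.values())))
    return {
        pid: HIGH_GROUP if value >= cutoff else LOW_GROUP
        for pid, value in scores.items()
    }


def km_estimate(records: list[SurvivalRecord]) -> KMCurve:
    """Product-limit survival curve.

    Censored times reduce the risk set without introducing steps; with no
    censoring the curve equals the empirical survival function.
    """
    if not records:
        raise ValueError("no survival records")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    fitter = KaplanMeierFitter()
    fitter.fit(times, event_observed=events)
    grid = fitter.survival_function_.index.to_numpy(dtype=float)
    surv = fitter.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    median = float(fitter.median_survival_time_)
    return KMCurve(
        times=grid,
        survival=surv,
        median=None if math.isinf(median) else median,
        n=len(records),
        n_events=int(events.sum()),
    )


def log_rank(
    a: list[SurvivalRecord], b: list[SurvivalRecord]
) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square with 1 df, p-value).

    At each distinct event time the observed-minus-expected event count in
    group ``a`` is accumulated with its hypergeometric variance. With no
    events anywhere the test is undefined and (0, 1) is returned with a
    warning.
    """
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    events_a = sum(r.event for r in a)
    events_b = sum(r.event for r in b)
    if events_a + events_b == 0:
        warnings.warn("no events in either group; log-rank undefined, p = 1")
        return 0.0, 1.0
    result = logrank_test(
        [r.time for r in a], [r.time for r in b],
        event_observed_A=[r.event for r in a],
        event_observed_B=[r.event for r in b],
    )
    return float(result.test_statistic), float(result.p_value)


def survival_rate_at(curve: KMCurve, horizon: float = 6.0) -> float:
    """Survival probability S(horizon) read off the KM step function."""
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    return curve.survival_at(horizon)
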