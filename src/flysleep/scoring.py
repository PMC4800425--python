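"""Sleep-bout scoring and animal-period summaries.

Fly sleep is scored from beam-break counts with the standard inactivity
rule: a sleep bout is a maximal run of consecutive minutes with zero
activity lasting at least ``min_sleep_minutes`` (default 5).  An activity
bout is a maximal run of minutes with a positive count; no minimum length
is applied, mirroring the sleep definition without the threshold.

Runs that cross a day/night boundary (ZT 0 or ZT 720) are split at the
boundary and each segment keeps its parent's sleep/activity state without
re-applying the length threshold — the animal was asleep throughout, and
this convention keeps total sleep additive across periods.

The unit of downstream analysis is the *animal-period pair*: one animal's
totals for one 12-hour day or night.  Each pair carries total sleep, sleep
bout count and mean sleep bout length, linked by the exact identity
``total_sleep = bout_count * mean_bout_length``.  Cohort aggregation uses
the mean-of-means convention: per-pair mean bout lengths are averaged
unweighted across pairs, never pooled across bouts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .dam import DAY_MINUTES, ActivityTrace

logger = logging.getLogger(__name__)

SLEEP = "sleep"
ACTIVITY = "activity"
DAY = "day"
NIGHT = "night"

#: Minimum run of inactive minutes that counts as sleep.
DEFAULT_MIN_SLEEP_MINUTES = 5


@dataclass(frozen=True)
class Bout:
    """A maximal (boundary-split) run of sleep or activity."""

    animal_id: str
    kind: str  # SLEEP or ACTIVITY
    day_index: int
    period: str  # DAY or NIGHT
    start_zt_minute: int
    length: int


@dataclass
class AnimalPeriodSummary:
    """One animal's sleep totals for one 12-hour day or night.

    ``mean_bout_length`` is ``None`` when the animal slept no bouts; when
    present it satisfies ``total_sleep == bout_count * mean_bout_length``
    exactly.
    """

    animal_id: str
    day_index: int
    period: str
    total_sleep: float
    bout_count: int
    mean_bout_length: float | None
    genotype: str | None = None

    def __post_init__(self):
        if self.period not in (DAY, NIGHT):
            raise ValueError(f"period must be {DAY!r} or {NIGHT!r}")
        if not 0 <= self.total_sleep <= DAY_MINUTES:
            raise ValueError("total_sleep must lie in [0, 720] minutes")
        if self.bout_count < 0:
            raise ValueError("bout_count must be non-negative")
        if self.bout_count == 0:
            if self.total_sleep != 0 or self.mean_bout_length is not None:
                raise ValueError("zero bouts require zero sleep and undefined mean")
        else:
            if self.mean_bout_length is None:
                raise ValueError("mean_bout_length required when bout_count > 0")
            if not np.isclose(self.total_sleep, self.bout_count * self.mean_bout_length):
                raise ValueError("total_sleep must equal bout_count * mean_bout_length")


@dataclass
class CohortSummary:
    """Experiment-level averages for one genotype/period condition."""

    genotype: str
    period: str
    mean_total_sleep: float
    sd_total_sleep: float
    mean_bout_length: float
    sd_bout_length: float
    mean_bout_count: float
    sd_bout_count: float
    n_pairs: int


def _period_of(zt_minute: int) -> str:
    return DAY if zt_minute < DAY_MINUTES else NIGHT


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in ``mask`` as (start, stop) half-open pairs."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def score_sleep(
    trace: ActivityTrace, min_sleep_minutes: int = DEFAULT_MIN_SLEEP_MINUTES
) -> list[Bout]:
    """Score a trace into sleep and activity bouts.

    Sleep bouts are maximal zero-count runs of at least ``min_sleep_minutes``;
    activity bouts are maximal positive-count runs.  Both are split at
    day/night boundaries with each segment keeping its parent's state.
    Minutes in zero runs shorter than the threshold belong to neither kind
    (awake but inactive).
    """
    if len(trace) == 0:
        raise ValueError("cannot score an empty trace")
    if min_sleep_minutes < 1:
        raise ValueError("min_sleep_minutes must be >= 1")

    counts = trace.counts
    zt = trace.zt_minute
    day = trace.day_index
    # one label per (day, period) block so runs can be split at boundaries
    block = day * 2 + (zt >= DAY_MINUTES)

    bouts: list[Bout] = []

    def emit(start: int, stop: int, kind: str) -> None:
        # split [start, stop) wherever the (day, period) block changes
        seg_start = start
        for i in range(start + 1, stop):
            if block[i] != block[i - 1]:
                bouts.append(
                    Bout(trace.animal_id, kind, int(day[seg_start]), _period_of(zt[seg_start]),
                         int(zt[seg_start]), i - seg_start)
                )
                seg_start = i
        bouts.append(
            Bout(trace.animal_id, kind, int(day[seg_start]), _period_of(zt[seg_start]),
                 int(zt[seg_start]), stop - seg_start)
        )

    for start, stop in _runs(counts == 0):
        if stop - start >= min_sleep_minutes:
            emit(start, stop, SLEEP)
    for start, stop in _runs(counts > 0):
        emit(start, stop, ACTIVITY)

    bouts.sort(key=lambda b: (b.day_index, 0 if b.period == DAY else 1, b.start_zt_minute))
    return bouts


def summarize_period(
    bouts: Iterable[Bout],
    animal_id: str,
    day_index: int,
    period: str,
    genotype: str | None = None,
) -> AnimalPeriodSummary:
    """Collapse one animal-period's sleep bouts into a summary record."""
    lengths = []
    for b in bouts:
        if b.animal_id != animal_id:
            raise ValueError(f"bout from animal {b.animal_id!r}, expected {animal_id!r}")
        if b.kind == SLEEP and b.day_index == day_index and b.period == period:
            lengths.append(b.length)
    total = float(sum(lengths))
    count = len(lengths)
    mean = total / count if count else None
    return AnimalPeriodSummary(animal_id, day_index, period, total, count, mean, genotype)


def summarize_trace(
    trace: ActivityTrace,
    min_sleep_minutes: int = DEFAULT_MIN_SLEEP_MINUTES,
    genotype: str | None = None,
) -> list[AnimalPeriodSummary]:
    """Score a trace and summarize every complete 720-minute period in it.

    Partial periods at the trace edges are skipped: totals from a truncated
    window would not be comparable with full 12-hour periods.
    """
    bouts = score_sleep(trace, min_sleep_minutes)
    block = trace.day_index * 2 + (trace.zt_minute >= DAY_MINUTES)
    out = []
    for blk in np.unique(block):
        if (block == blk).sum() != DAY_MINUTES:
            continue
        day_index = int(blk) // 2
        period = NIGHT if blk % 2 else DAY
        out.append(summarize_period(bouts, trace.animal_id, day_index, period, genotype))
    return out


def no_terminal_activity(trace: ActivityTrace) -> str | None:
    """Default health rule: flag animals with no activity in the final 12 h.

    A fly that stops breaking the beam entirely toward the end of the
    recording is far more likely dead than asleep; its apparent "sleep"
    would otherwise inflate every downstream statistic.
    """
    window = trace.counts[-DAY_MINUTES:]
    if not window.any():
        return "no-terminal-activity"
    return None


HealthRule = Callable[[ActivityTrace], "str | None"]


def health_filter(
    traces: Iterable[ActivityTrace], rule: HealthRule = no_terminal_activity
) -> tuple[list[ActivityTrace], list[tuple[ActivityTrace, str]]]:
    """Partition traces into (kept, excluded-with-reason) by a health rule.

    Exclusion is per animal and total: if the rule fires, every period of
    that animal is removed from the analysis.
    """
    kept: list[ActivityTrace] = []
    excluded: list[tuple[ActivityTrace, str]] = []
    for trace in traces:
        reason = rule(trace)
        if reason is None:
            kept.append(trace)
        else:
            logger.info("excluding %s: %s", trace.animal_id, reason)
            excluded.append((trace, reason))
    return kept, excluded


def _sample_sd(values: np.ndarray) -> float:
    if len(values) < 2:
        logger.warning("standard deviation of a single observation reported as 0")
        return 0.0
    return float(np.std(values, ddof=1))


def aggregate_cohort(
    summaries: Sequence[AnimalPeriodSummary], genotype: str, period: str
) -> CohortSummary:
    """Mean-of-means cohort statistics over animal-period pairs.

    Mean bout length is averaged unweighted over pairs with at least one
    bout (an average of per-pair averages); total-sleep and bout-count
    statistics run over all pairs.  SDs are sample SDs (ddof=1).
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("cannot aggregate an empty cohort")
    for s in summaries:
        if s.period != period:
            raise ValueError(f"summary with period {s.period!r} in {period!r} cohort")
        if s.genotype is not None and s.genotype != genotype:
            raise ValueError(f"summary with genotype {s.genotype!r} in {genotype!r} cohort")

    totals = np.array([s.total_sleep for s in summaries], dtype=float)
    counts = np.array([s.bout_count for s in summaries], dtype=float)
    means = np.array(
        [s.mean_bout_length for s in summaries if s.bout_count > 0], dtype=float
    )
    if len(means) == 0:
        mean_bl, sd_bl = float("nan"), float("nan")
    else:
        mean_bl, sd_bl = float(np.mean(means)), _sample_sd(means)

    return CohortSummary(
        genotype=genotype,
        period=period,
        mean_total_sleep=float(np.mean(totals)),
        sd_total_sleep=_sample_sd(totals),
        mean_bout_length=mean_bl,
        sd_bout_length=sd_bl,
        mean_bout_count=float(np.mean(counts)),
        sd_bout_count=_sample_sd(counts),
        n_pairs=len(summaries),
    )


# ---------------------------------------------------------------------------
# tabular interchange

SUMMARY_COLUMNS = [
    "animal_id",
    "genotype",
    "day_index",
    "period",
    "total_sleep_min",
    "bout_count",
    "mean_bout_length_min",
]


def summaries_to_frame(summaries: Iterable[AnimalPeriodSummary]) -> pd.DataFrame:
    """Animal-period summaries as a DataFrame (CSV interchange layout)."""
    rows = [
        {
            "animal_id": s.animal_id,
            "genotype": s.genotype,
            "day_index": s.day_index,
            "period": s.period,
            "total_sleep_min": s.total_sleep,
            "bout_count": s.bout_count,
            "mean_bout_length_min": s.mean_bout_length,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def frame_to_summaries(frame: pd.DataFrame) -> list[AnimalPeriodSummary]:
    """Inverse of :func:`summaries_to_frame`."""
    out = []
    for row in frame.itertuples(index=False):
        mean = row.mean_bout_length_min
        if mean is not None and (isinstance(mean, float) and np.isnan(mean)):
            mean = None
        genotype = row.genotype if isinstance(row.genotype, str) else None
        out.append(
            AnimalPeriodSummary(
                animal_id=str(row.animal_id),
                day_index=int(row.day_index),
                period=str(row.period),
                total_sleep=float(row.total_sleep_min),
                bout_count=int(row.bout_count),
                mean_bout_length=mean,
                genotype=genotype,
            )
        )
    return out


def bouts_to_frame(bouts: Iterable[Bout]) -> pd.DataFrame:
    """Bout records as a DataFrame."""
    return pd.DataFrame(
        [
            {
                "animal_id": b.animal_id,
                "kind": b.kind,
                "day_index": b.day_index,
                "period": b.period,
                "start_zt_minute": b.start_zt_minute,
                "length_min": b.length,
            }
            for b in bouts
        ],
        columns=["animal_id", "kind", "day_index", "period", "start_zt_minute", "length_min"],
    )


def cohort_to_frame(cohorts: Iterable[CohortSummary]) -> pd.DataFrame:
    """Cohort summaries as a DataFrame."""
    return pd.DataFrame([c.__dict__ for c in cohorts])
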