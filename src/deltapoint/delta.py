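"""The Delta point layer: a doubly stochastic Poisson view of suspected
change points.

BOCPD over-declares on noisy data, so the monitored span is tiled with
intervals of user-chosen length j and the declared change points are treated
as a Cox (doubly stochastic Poisson) counting process whose stochastic
intensity Lambda(t) is the change-point mass of the run-length posterior,
Lambda(t) = p(r_t = 0 | y_1:t).  Per interval i the layer computes the count
C_i, the average attached run length r-bar_i, the integrated intensity
m_i = sum of Lambda over the interval, and the Poisson probability of the
observed count.  The interval with the fewest change points and the longest
average run length is the one most likely to contain a representative change
of the generative process rather than noise; within it, the change point with
the longest run length is the single Delta point.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats

from .bocpd import RunLengthTrajectory, SuspectedChangePoint
from .errors import ConfigError, ParameterError

__all__ = [
    "IntervalSpec",
    "IntervalStats",
    "DeltaPointResult",
    "partition_intervals",
    "interval_statistics",
    "integrated_intensity",
    "interval_count_probability",
    "expected_count",
    "conditioned_score",
    "compute_interval_stats",
    "select_delta_point",
]


@dataclasses.dataclass(frozen=True)
class IntervalSpec:
    """Half-open-left time interval (start, end]."""

    start: int  # exclusive
    end: int  # inclusive
    index: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ConfigError(f"interval end {self.end} must exceed start {self.start}")

    def contains(self, t: int) -> bool:
        return self.start < t <= self.end

    def __len__(self) -> int:
        return self.end - self.start


@dataclasses.dataclass(frozen=True)
class IntervalStats:
    """Per-interval summary: count C_i, average run length, integrated
    intensity m_i, Poisson count probability and diagnostic score."""

    interval: IntervalSpec
    count: int
    avg_runlength: float | None
    integrated_intensity: float
    count_prob: float
    score: float | None


@dataclasses.dataclass(frozen=True)
class DeltaPointResult:
    """The selected interval and the single Delta point (or an explicit
    no-detection outcome when no change point was ever suspected)."""

    selected_interval: IntervalSpec | None
    delta_time: int | None
    delta_runlength: int | None
    all_stats: tuple[IntervalStats, ...]
    suspected: tuple[SuspectedChangePoint, ...]

    @property
    def found(self) -> bool:
        return self.delta_time is not None


def partition_intervals(monitor_start: int, monitor_end: int, j: int) -> list[IntervalSpec]:
    """Tile (monitor_start, monitor_end] with intervals of length j.

    ``monitor_start`` is the exclusive left edge of the first interval.  A
    shorter remainder interval at the end is retained — dropping data would
    bias detection near the end of the series.
    """
    if j < 1:
        raise ConfigError(f"interval length j must be >= 1, got {j}")
    if monitor_end <= monitor_start:
        raise ConfigError("monitor_end must exceed monitor_start")
    out = []
    i = 1
    start = monitor_start
    while start < monitor_end:
        end = min(start + j, monitor_end)
        out.append(IntervalSpec(start=start, end=end, index=i))
        start = end
        i += 1
    return out


def interval_statistics(
    cps: list[SuspectedChangePoint], interval: IntervalSpec
) -> tuple[int, float | None]:
    """Count C_i and average run length r-bar_i of the points in an interval.

    The average is undefined (None) for an empty interval.
    """
    inside = [c.run_length for c in cps if interval.contains(c.time)]
    if not inside:
        return 0, None
    return len(inside), float(np.mean(inside))


def integrated_intensity(traj: RunLengthTrajectory, interval: IntervalSpec) -> float:
    """Discrete-time integral of the intensity over (start, end]:
    the sum of p(r_t = 0 | y_1:t) at each monitored step in the interval."""
    times = traj.times
    if interval.start < traj.t_start or interval.end > times[-1]:
        raise ConfigError(
            f"interval ({interval.start}, {interval.end}] outside trajectory span "
            f"({traj.t_start}, {times[-1]}]"
        )
    mask = (times > interval.start) & (times <= interval.end)
    return float(np.sum(traj.cp_probs[mask]))


def interval_count_probability(m: float, k: int) -> float:
    """Poisson probability of observing k change points given integrated
    intensity m: m^k e^{-m} / k!."""
    if not (np.isfinite(m) and m >= 0):
        raise ParameterError(f"integrated intensity must be >= 0, got {m}")
    if k < 0 or int(k) != k:
        raise ParameterError(f"count must be a non-negative integer, got {k}")
    if m == 0.0:
        return 1.0 if k == 0 else 0.0
    return float(np.exp(stats.poisson.logpmf(int(k), m)))


def expected_count(traj: RunLengthTrajectory, interval: IntervalSpec) -> float:
    """Expected number of declared change points in the interval.

    For the Cox process this equals the expectation of the integrated
    intensity, which in the discrete setting is ``integrated_intensity``
    itself.
    """
    return integrated_intensity(traj, interval)


def conditioned_score(stats_: IntervalStats) -> float:
    """Diagnostic score log P(C_i; m_i) + log r-bar_i.

    Larger means the interval is more likely to hold the Delta point; this is
    a report-level diagnostic, not the selection criterion (selection is the
    lexicographic fewest-count / longest-average-run-length rule).
    """
    if stats_.count < 1 or stats_.avg_runlength is None:
        raise ParameterError("score undefined for an interval with no change points")
    if stats_.integrated_intensity == 0.0:
        # Count >= 1 with zero intensity: log pmf is -inf; guard with a floor.
        return -np.inf
    return float(stats.poisson.logpmf(stats_.count, stats_.integrated_intensity)
                 + math.log(stats_.avg_runlength))


def compute_interval_stats(
    cps: list[SuspectedChangePoint],
    intervals: list[IntervalSpec],
    traj: RunLengthTrajectory,
) -> list[IntervalStats]:
    """Assemble the full per-interval table."""
    out = []
    for iv in intervals:
        count, avg = interval_statistics(cps, iv)
        m = integrated_intensity(traj, iv)
        st = IntervalStats(interval=iv, count=count, avg_runlength=avg,
                           integrated_intensity=m,
                           count_prob=interval_count_probability(m, count),
                           score=None)
        if count >= 1:
            st = dataclasses.replace(st, score=conditioned_score(st))
        out.append(st)
    return out


def select_delta_point(
    cps: list[SuspectedChangePoint],
    intervals: list[IntervalSpec],
    traj: RunLengthTrajectory,
) -> DeltaPointResult:
    """Pick the Delta point.

    Among intervals containing at least one suspected change point, select
    the one with the longest average run length, ties broken by the fewest
    change points, then by the earliest start.  (The fewest-count / longest-
    average criterion is a joint one; average run length leads the ordering
    because a long completed run is direct evidence of a stable preceding
    regime, whereas a small count alone can be a lone noise blip isolated in
    its interval.)  Within the selected interval the change point with the
    longest run length (ties: earliest) is the Delta point.  With no
    suspected change points anywhere the result is an explicit no-detection
    outcome.
    """
    all_stats = compute_interval_stats(cps, intervals, traj)
    nonempty = [s for s in all_stats if s.count >= 1]
    if not nonempty:
        return DeltaPointResult(selected_interval=None, delta_time=None,
                                delta_runlength=None, all_stats=tuple(all_stats),
                                suspected=tuple(cps))
    best = min(nonempty,
               key=lambda s: (-s.avg_runlength, s.count, s.interval.start))
    inside = [c for c in cps if best.interval.contains(c.time)]
    delta = min(inside, key=lambda c: (-c.run_length, c.time))
    return DeltaPointResult(selected_interval=best.interval,
                            delta_time=delta.time,
                            delta_runlength=delta.run_length,
                            all_stats=tuple(all_stats),
                            suspected=tuple(cps))
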