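"""Group and individual vocal-activity metrics: rates, bursts, burst summaries.

The group rate series is computed in 60 s windows advancing by 30 s
(half-overlapping).  Bursts are maximal periods in which the windowed rate
strictly exceeds 110% of a reference rate — by default the mean rate over
the whole recording.  Six summary metrics describe the burst structure of
a session.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .session_io import EventTable

DEFAULT_WINDOW_S = 60.0
DEFAULT_STEP_S = 30.0
DEFAULT_BURST_FACTOR = 1.10


def overall_rate(table: EventTable, duration_s: float) -> float:
    """Group vocalization rate: total vocalizations / recording duration (voc/s)."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return len(table) / duration_s


def per_bird_counts(table: EventTable, bird_ids=None) -> dict[str, int]:
    """Vocalization count per bird; zero for listed birds without events."""
    counts = table.df["bird_id"].value_counts().to_dict() if len(table) else {}
    if bird_ids is not None:
        counts = {b: int(counts.get(b, 0)) for b in bird_ids}
    return {b: int(c) for b, c in counts.items()}


@dataclass
class RateSeries:
    """Sliding-window vocalization rates (voc/s) over half-open windows."""

    window_start_times: np.ndarray
    rates: np.ndarray
    window_length_s: float = DEFAULT_WINDOW_S
    step_s: float = DEFAULT_STEP_S

    def __post_init__(self) -> None:
        self.window_start_times = np.asarray(self.window_start_times, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if len(self.window_start_times) != len(self.rates):
            raise ValueError("start times and rates differ in length")
        if (self.rates < 0).any():
            raise ValueError("rates must be non-negative")

    @property
    def n_windows(self) -> int:
        return len(self.rates)


def sliding_rate(
    table: EventTable,
    duration_s: float,
    window_length_s: float = DEFAULT_WINDOW_S,
    step_s: float = DEFAULT_STEP_S,
) -> RateSeries:
    """Rate in windows ``[k*step, k*step + window_length)``.

    An event is counted in a window if its onset falls inside it.  Windows
    advance while they still cover new time; the last window may extend
    past the recording end by less than one step.
    """
    if not (window_length_s >= step_s > 0):
        raise ValueError("need window_length_s >= step_s > 0")
    n_windows = max(1, math.ceil((duration_s - window_length_s) / step_s) + 1)
    starts = np.arange(n_windows) * step_s
    onsets = table.df["start_s"].to_numpy() if len(table) else np.empty(0)
    counts = np.array(
        [np.count_nonzero((onsets >= s) & (onsets < s + window_length_s)) for s in starts]
    )
    return RateSeries(starts, counts / window_length_s, window_length_s, step_s)


@dataclass
class Burst:
    """A high-activity period of the group rate series."""

    start_s: float
    end_s: float
    n_vocalizations: int
    mean_rate_in_burst: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class BurstSet:
    bursts: list[Burst] = field(default_factory=list)
    reference_rate: float = 0.0
    factor: float = DEFAULT_BURST_FACTOR

    def __len__(self) -> int:
        return len(self.bursts)

    def __iter__(self):
        return iter(self.bursts)


def extract_bursts(
    series: RateSeries,
    reference_rate: float,
    table: EventTable,
    factor: float = DEFAULT_BURST_FACTOR,
) -> BurstSet:
    """Bursts: unions of windows whose rate strictly exceeds ``factor * reference``.

    Flagged windows whose intervals overlap or touch are unioned into one
    burst ``[first flagged window start, last flagged window end)``.  The
    per-burst vocalization count and mean rate come from events of
    ``table`` whose onsets fall within the burst.
    """
    if reference_rate < 0:
        raise ValueError("reference rate must be non-negative")
    flagged = series.rates > factor * reference_rate
    intervals = [
        (s, s + series.window_length_s)
        for s, f in zip(series.window_start_times, flagged)
        if f
    ]
    merged: list[list[float]] = []
    for lo, hi in intervals:  # already sorted by window start
        if merged and lo <= merged[-1][1]:  # overlap or touch
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])

    onsets = table.df["start_s"].to_numpy() if len(table) else np.empty(0)
    bursts = []
    for lo, hi in merged:
        n = int(np.count_nonzero((onsets >= lo) & (onsets < hi)))
        bursts.append(Burst(lo, hi, max(n, 0), n / (hi - lo)))
    return BurstSet(bursts, reference_rate=reference_rate, factor=factor)


@dataclass
class BurstMetricSet:
    """The six burst summary metrics of one recording.

    Metrics that are undefined for the session (no bursts, or a single
    burst for the inter-burst interval) are NaN and listed in
    ``undefined``.
    """

    n_bursts: int
    mean_rate_in_bursts: float
    mean_burst_duration_s: float
    total_burst_duration_s: float
    mean_interburst_interval_s: float
    latency_to_first_burst_s: float
    undefined: tuple[str, ...] = ()

    FIELDS = (
        "n_bursts",
        "mean_rate_in_bursts",
        "mean_burst_duration_s",
        "total_burst_duration_s",
        "mean_interburst_interval_s",
        "latency_to_first_burst_s",
    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{f: getattr(self, f) for f in self.FIELDS}])


def burst_metrics(bursts: BurstSet, duration_s: float) -> BurstMetricSet:
    """Summarize a burst set: count, rates, durations, spacing, latency."""
    items = sorted(bursts.bursts, key=lambda b: b.start_s)
    for a, b in zip(items, items[1:]):
        if b.start_s < a.end_s:
            raise ValueError("bursts overlap")
    n = len(items)
    if n == 0:
        nan = float("nan")
        return BurstMetricSet(0, nan, nan, nan, nan, nan,
                              undefined=tuple(BurstMetricSet.FIELDS[1:]))
    durations = [b.duration_s for b in items]
    total = float(sum(durations))
    if total > duration_s:
        raise ValueError("total burst duration exceeds the session duration")
    undefined: list[str] = []
    if n >= 2:
        interburst = float(np.mean([b.start_s - a.end_s for a, b in zip(items, items[1:])]))
    else:
        interburst = float("nan")
        undefined.append("mean_interburst_interval_s")
    return BurstMetricSet(
        n_bursts=n,
        mean_rate_in_bursts=float(np.mean([b.mean_rate_in_burst for b in items])),
        mean_burst_duration_s=float(np.mean(durations)),
        total_burst_duration_s=total,
        mean_interburst_interval_s=interburst,
        latency_to_first_burst_s=float(items[0].start_s),
        undefined=tuple(undefined),
    )


def session_activity(
    table: EventTable,
    duration_s: float,
    window_length_s: float = DEFAULT_WINDOW_S,
    step_s: float = DEFAULT_STEP_S,
    burst_factor: float = DEFAULT_BURST_FACTOR,
) -> tuple[BurstMetricSet, dict[str, int]]:
    """End-to-end activity summary: burst metrics plus per-bird counts."""
    series = sliding_rate(table, duration_s, window_length_s, step_s)
    ref = overall_rate(table, duration_s)
    bursts = extract_bursts(series, ref, table, factor=burst_factor)
    return burst_metrics(bursts, duration_s), per_bird_counts(table)
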