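"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

BASAL = "basal"
DRUG = "drug"
CONDITIONS = (BASAL, DRUG)


class UnusableSeriesError(ValueError):
    """Raised when a series cannot survive preprocessing (too few usable beats)."""


class DegenerateEmbeddingError(ValueError):
    """Raised when a cosine similarity is requested for a zero-norm embedding."""


@dataclass(frozen=True)
class FilterRange:
    """Physiological plausibility band for RR intervals, in seconds.

    Values inside the closed interval [lo, hi] are kept; values outside are
    treated as artifacts and interpolated over.
    """

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.lo < self.hi):
            raise ValueError(f"require 0 < lo < hi, got lo={self.lo}, hi={self.hi}")

    def contains(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (x >= self.lo) & (x <= self.hi)


@dataclass
class RRSeries:
    """RR-interval time series for one subject/condition/age segment.

    ``intervals[i]`` is the time between beats i and i+1 in seconds.  When
    ``times`` is present it holds the beat timestamps t_i (length
    len(intervals)+1) and intervals[i] == times[i+1] - times[i].
    """

    subject_id: str
    condition: str
    age_months: float
    intervals: np.ndarray
    times: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1:
            raise ValueError("intervals must be one-dimensional")
        if self.intervals.size and np.any(self.intervals <= 0):
            raise ValueError("all RR intervals must be positive")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.size != self.intervals.size + 1:
                raise ValueError("times must have length len(intervals) + 1")
            if not np.allclose(np.diff(self.times), self.intervals, rtol=0, atol=1e-9):
                raise ValueError("times and intervals are inconsistent")

    def __len__(self) -> int:
        return int(self.intervals.size)

    @property
    def origin(self) -> float:
        """Timestamp of the first beat (0 when the series is standalone)."""
        return float(self.times[0]) if self.times is not None else 0.0

    def onsets(self) -> np.ndarray:
        """Cumulative onset time of each interval, relative to series start."""
        return np.concatenate(([0.0], np.cumsum(self.intervals[:-1])))

    def with_intervals(self, intervals: np.ndarray, rebuild_times: bool = True) -> "RRSeries":
        intervals = np.asarray(intervals, dtype=float)
        times = None
        if rebuild_times:
            times = self.origin + np.concatenate(([0.0], np.cumsum(intervals)))
        return replace(self, intervals=intervals, times=times)


@dataclass
class HeartbeatWindow:
    """A contiguous, non-overlapping block of ``n_beats`` RR intervals."""

    intervals: np.ndarray
    n_beats: int
    subject_id: str
    condition: str
    age_months: float
    window_index: int

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.size != self.n_beats:
            raise ValueError(
                f"window holds {self.intervals.size} intervals, expected {self.n_beats}"
            )

    @property
    def key(self) -> str:
        """Stable provenance reference used in pair/split manifests."""
        return f"{self.subject_id}/{self.condition}/{self.age_months:g}/{self.window_index}"


@dataclass
class WindowPair:
    """Two heartbeat windows plus the ground-truth label y (1 = same subject)."""

    first: HeartbeatWindow
    second: HeartbeatWindow
    y: int = field(init=False)

    def __post_init__(self) -> None:
        if self.first.n_beats != self.second.n_beats:
            raise ValueError("paired windows must have equal n_beats")
        # Label derives from subject identity only, never from other metadata.
        self.y = int(self.first.subject_id == self.second.subject_id)
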