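"""From peak times or raw RR series to filtered, fixed-length heartbeat windows.

The pipeline: difference R-peak times into RR intervals, replace
physiologically implausible intervals by linear interpolation between the
nearest in-range beats (range filter 0.05-0.24 s, i.e. 250-1200 bpm),
discard the transient at the start of drug segments (first 2 min), and cut
the series into non-overlapping windows of a fixed number of beats.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from rrverify.types import (
    DRUG,
    FilterRange,
    HeartbeatWindow,
    RRSeries,
    UnusableSeriesError,
)

#: Physiological RR band for mice: 0.05 s (1200 bpm) to 0.24 s (250 bpm).
DEFAULT_FILTER = FilterRange(0.05, 0.24)

#: Seconds discarded from the start of drug segments to avoid transients.
DEFAULT_DRUG_TRANSIENT = 120.0


def rr_from_peaks(
    peak_times: np.ndarray,
    subject_id: str = "S0",
    condition: str = "basal",
    age_months: float = 0.0,
) -> RRSeries:
    """Difference beat timestamps t_i into RR intervals RR(t_i) = t_{i+1} - t_i."""
    t = np.asarray(peak_times, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("need at least two peak timestamps")
    if np.any(np.diff(t) <= 0):
        raise ValueError("peak times must be strictly increasing")
    return RRSeries(
        subject_id=subject_id,
        condition=condition,
        age_months=age_months,
        intervals=np.diff(t),
        times=t,
    )


def range_filter(series: RRSeries, frange: FilterRange = DEFAULT_FILTER) -> RRSeries:
    """Replace out-of-range RR intervals by linear interpolation.

    Interpolation is linear in beat index over interval values; out-of-range
    runs at either boundary are filled flat from the single nearest in-range
    value.  Values exactly at the bounds are kept.  Length is conserved, and
    the operation is idempotent.
    """
    x = series.intervals
    ok = frange.contains(x)
    n_ok = int(ok.sum())
    if n_ok < 2:
        raise UnusableSeriesError(
            f"only {n_ok} in-range interval(s) in series {series.subject_id}; "
            "cannot interpolate"
        )
    if n_ok == x.size:
        return series
    idx = np.arange(x.size)
    filled = x.copy()
    filled[~ok] = np.interp(idx[~ok], idx[ok], x[ok])
    return series.with_intervals(filled)


def drop_transient(series: RRSeries, exclusion: Optional[float] = None) -> RRSeries:
    """Remove the leading transient: all intervals with onset time < exclusion.

    Onset is cumulative RR time from the segment start.  By default drug
    segments lose their first 120 s and basal segments are untouched.
    """
    if exclusion is None:
        exclusion = DEFAULT_DRUG_TRANSIENT if series.condition == DRUG else 0.0
    if exclusion < 0:
        raise ValueError("exclusion must be non-negative")
    if exclusion == 0.0:
        return series
    # tolerance so accumulated floating-point error at the boundary does not
    # drop one beat more than the exclusion asks for
    keep = series.onsets() >= exclusion - 1e-9
    if not keep.any():
        raise UnusableSeriesError(
            f"exclusion of {exclusion} s removes the entire series "
            f"({series.subject_id}, {series.condition})"
        )
    return series.with_intervals(series.intervals[keep])


def segment_windows(series: RRSeries, n_beats: int) -> List[HeartbeatWindow]:
    """Cut the series into consecutive disjoint windows of ``n_beats`` intervals.

    The trailing remainder shorter than ``n_beats`` is discarded; a series
    shorter than one window yields an empty list.
    """
    if n_beats < 2:
        raise ValueError("n_beats must be at least 2")
    n_win = len(series) // n_beats
    return [
        HeartbeatWindow(
            intervals=series.intervals[k * n_beats : (k + 1) * n_beats],
            n_beats=n_beats,
            subject_id=series.subject_id,
            condition=series.condition,
            age_months=series.age_months,
            window_index=k,
        )
        for k in range(n_win)
    ]


def preprocess_series(
    series: RRSeries,
    n_beats: int,
    frange: FilterRange = DEFAULT_FILTER,
    exclusion: Optional[float] = None,
) -> List[HeartbeatWindow]:
    """Full pipeline: transient exclusion, range filter, windowing."""
    return segment_windows(range_filter(drop_transient(series, exclusion), frange), n_beats)
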