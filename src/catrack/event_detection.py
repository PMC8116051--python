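"""Hysteresis segmentation of calcium signaling events and event statistics.

A cell is signaling when its calcium ratio sits at least ``delta_high``
above the background ratio for at least ``min_consecutive`` consecutive
timepoints; the event ends at the first of ``min_consecutive`` consecutive
timepoints back below ``background + delta_low``. The background ratio is
the mean ratio of tracks imaged under nonselecting conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .track_model import CalciumTrace

__all__ = [
    "DetectionParams",
    "SignalingEvent",
    "EventSet",
    "BackgroundEstimationError",
    "estimate_background",
    "detect_events",
    "detect_events_table",
    "first_complete_event_durations",
    "percent_elevated_timepoints",
    "event_frequency",
    "events_to_frame",
]


class BackgroundEstimationError(ValueError):
    """No nonselecting traces available to estimate the background ratio."""


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds for event segmentation and frequency counting.

    Attributes
    ----------
    background : float or None
        Background calcium ratio B; ``None`` means "estimate from
        nonselecting tracks" (the reference value for the supported
        indicator/system is 0.675).
    delta_high : float
        Trigger offset above background (event starts at >= B + delta_high).
    delta_low : float
        Release offset (event ends when ratio returns below B + delta_low).
    min_consecutive : int
        Consecutive timepoints required both to trigger and to release.
    quiescence_gap_s : float
        Minimum nonsignaling gap separating events counted for frequency;
        closer events are merged into one.
    smooth_window : int
        Optional trailing rolling-mean window applied to the ratio before
        thresholding (1 = raw, the default).
    """

    background: float | None = None
    delta_high: float = 0.2
    delta_low: float = 0.1
    min_consecutive: int = 2
    quiescence_gap_s: float = 240.0
    smooth_window: int = 1

    def __post_init__(self) -> None:
        if not self.delta_high > self.delta_low > 0:
            raise ValueError("must have delta_high > delta_low > 0")
        if self.min_consecutive < 2:
            raise ValueError("min_consecutive must be >= 2")
        if self.quiescence_gap_s <= 0:
            raise ValueError("quiescence_gap_s must be > 0")
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")


@dataclass
class SignalingEvent:
    """One segmented calcium event on a track.

    ``start_frame`` is the first of the consecutive trigger timepoints;
    ``end_frame`` (when complete) is the first of the consecutive released
    timepoints, so the event occupies the half-open span
    [start_frame, end_frame) and ``duration_s = (end - start) * dt``.
    """

    track_id: str
    run_id: str
    start_frame: int
    end_frame: int | None
    complete: bool
    duration_s: float | None

    def __post_init__(self) -> None:
        if self.complete:
            assert self.end_frame is not None and self.end_frame > self.start_frame
            assert self.duration_s is not None and self.duration_s > 0


@dataclass
class EventSet:
    """Events grouped by (run, track) plus the cumulative track time.

    ``cumulative_track_time_s`` is the sum of individual track durations
    (last minus first timepoint) over all compiled tracks, whether or not
    they contain events; it is the denominator for event frequency.
    """

    events_by_track: dict[tuple[str, str], list[SignalingEvent]] = field(default_factory=dict)
    cumulative_track_time_s: float = 0.0

    @property
    def events(self) -> list[SignalingEvent]:
        return [ev for evs in self.events_by_track.values() for ev in evs]

    def n_events(self) -> int:
        return sum(len(v) for v in self.events_by_track.values())


def estimate_background(
    traces: Iterable[CalciumTrace], scope: str = "pooled"
) -> float | dict[str, float]:
    """Mean calcium ratio over all timepoints of nonselecting tracks.

    Parameters
    ----------
    traces : iterable of CalciumTrace
        Any mix of conditions; only ``condition == "nonselecting"`` traces
        contribute.
    scope : {"pooled", "per_run"}
        Pooled returns one scalar; per_run returns ``{run_id: B}``.

    Raises
    ------
    BackgroundEstimationError
        If no nonselecting timepoints are available; supply the background
        explicitly in that case.
    """
    ns = [t for t in traces if t.condition == "nonselecting" and len(t)]
    if not ns:
        raise BackgroundEstimationError(
            "no nonselecting traces to estimate background from; "
            "pass an explicit background ratio"
        )
    if scope == "pooled":
        return float(np.concatenate([t.ratio for t in ns]).mean())
    if scope == "per_run":
        out: dict[str, list[np.ndarray]] = {}
        for t in ns:
            out.setdefault(t.run_id, []).append(t.ratio)
        return {run: float(np.concatenate(chunks).mean()) for run, chunks in out.items()}
    raise ValueError(f"unknown scope {scope!r}")


def _smoothed(ratio: np.ndarray, window: int) -> np.ndarray:
    if window == 1:
        return ratio
    return pd.Series(ratio).rolling(window, min_periods=1).mean().to_numpy()


def detect_events(
    trace: CalciumTrace, params: DetectionParams, background: float | None = None
) -> list[SignalingEvent]:
    """Segment signaling events on one trace by hysteresis thresholding.

    Scans left to right: an event starts at the first of
    ``min_consecutive`` consecutive timepoints with ratio
    >= background + delta_high; once triggered it ends at the first of
    ``min_consecutive`` consecutive timepoints with ratio
    < background + delta_low (``complete=True``) or at the end of the track
    without such a pair (``complete=False``, no end or duration). Scanning
    resumes after the release pair.
    """
    B = background if background is not None else params.background
    if B is None:
        raise ValueError("background ratio required: set params.background or pass background=")
    r = _smoothed(np.asarray(trace.ratio, dtype=float), params.smooth_window)
    if not np.all(np.isfinite(r)):
        raise ValueError(f"non-finite ratio values in track {trace.track_id}")
    n = len(r)
    m = params.min_consecutive
    high = r >= B + params.delta_high
    low = r < B + params.delta_low
    frames = np.asarray(trace.frames)
    times = np.asarray(trace.times_s, dtype=float)

    # dt for durations; falls back to 0 for single-point traces (no events anyway)
    events: list[SignalingEvent] = []
    i = 0
    while i <= n - m:
        if all(high[i : i + m]):
            start = i
            j = start + 1
            end = None
            while j <= n - m:
                if all(low[j : j + m]):
                    end = j
                    break
                j += 1
            if end is None:
                events.append(
                    SignalingEvent(
                        trace.track_id, trace.run_id, int(frames[start]), None, False, None
                    )
                )
                break
            events.append(
                SignalingEvent(
                    trace.track_id,
                    trace.run_id,
                    int(frames[start]),
                    int(frames[end]),
                    True,
                    float(times[end] - times[start]),
                )
            )
            i = end + m
        else:
            i += 1
    return events


def detect_events_table(
    traces: Sequence[CalciumTrace], params: DetectionParams, background: float | None = None
) -> EventSet:
    """Run :func:`detect_events` over traces and compile an :class:`EventSet`."""
    es = EventSet()
    for tr in traces:
        es.events_by_track[(tr.run_id, tr.track_id)] = detect_events(tr, params, background)
        if len(tr) >= 2:
            es.cumulative_track_time_s += float(tr.times_s[-1] - tr.times_s[0])
    return es


def first_complete_event_durations(event_set: EventSet) -> list[float]:
    """Durations (s) of each track's first event, kept only when complete.

    A track whose first event is incomplete contributes nothing, even if a
    later event is complete: only the first signaling event per track enters
    duration statistics, and only events with a defined beginning and end.
    """
    out = []
    for evs in event_set.events_by_track.values():
        if evs and evs[0].complete:
            out.append(float(evs[0].duration_s))
    return out


def percent_elevated_timepoints(
    traces_by_condition: Mapping[str, Sequence[CalciumTrace]],
    params: DetectionParams,
    background: float | None = None,
) -> dict[str, float]:
    """Fraction of timepoints with ratio >= background + delta_high, per condition.

    Per-timepoint classification with no persistence requirement. Empty
    conditions are excluded with a warning.
    """
    B = background if background is not None else params.background
    if B is None:
        raise ValueError("background ratio required")
    out: dict[str, float] = {}
    for cond, traces in traces_by_condition.items():
        values = [np.asarray(t.ratio, float) for t in traces if len(t)]
        if not values:
            warnings.warn(f"condition {cond!r} has no timepoints; excluded")
            continue
        r = np.concatenate(values)
        out[cond] = float(np.mean(r >= B + params.delta_high))
    return out


def _merged_event_count(evs: Sequence[SignalingEvent], dt_s: float, gap_s: float) -> int:
    """Count events after merging those separated by < gap_s of nonsignaling.

    Track boundaries bound quiescence, so truncated events count. The gap
    between consecutive events spans [end of previous, start of next) in
    frames; an incomplete event extends to the track end and terminates
    counting for its track.
    """
    if not evs:
        return 0
    count = 1
    prev_end = evs[0].end_frame
    for ev in evs[1:]:
        if prev_end is None:  # previous event truncated: nothing can follow
            break
        gap = (ev.start_frame - prev_end) * dt_s
        if gap >= gap_s:
            count += 1
        prev_end = ev.end_frame
    return count


def event_frequency(
    event_set: EventSet, params: DetectionParams, frame_interval_s: float = 10.0
) -> tuple[float, float]:
    """Events per minute over the cumulative track time, and its reciprocal.

    Hysteresis events on the same track separated by less than
    ``params.quiescence_gap_s`` of nonsignaling merge into one counted
    event; track boundaries count as bounding quiescence. Returns
    ``(events_per_min, min_per_event)``; ``min_per_event`` is ``inf`` when
    no events were counted.
    """
    if event_set.cumulative_track_time_s <= 0:
        raise ZeroDivisionError("cumulative track time must be > 0")
    n = sum(
        _merged_event_count(evs, frame_interval_s, params.quiescence_gap_s)
        for evs in event_set.events_by_track.values()
    )
    total_min = event_set.cumulative_track_time_s / 60.0
    freq = n / total_min
    return freq, (float("inf") if n == 0 else total_min / n)


def events_to_frame(event_set: EventSet) -> pd.DataFrame:
    """Flatten an EventSet into a run_id/track_id/start/end/complete/duration table."""
    rows = [
        {
            "run_id": ev.run_id,
            "track_id": ev.track_id,
            "start_frame": ev.start_frame,
            "end_frame": ev.end_frame if ev.end_frame is not None else pd.NA,
            "complete": ev.complete,
            "duration_s": ev.duration_s if ev.duration_s is not None else pd.NA,
        }
        for ev in event_set.events
    ]
    return pd.DataFrame(
        rows,
        columns=["run_id", "track_id", "start_frame", "end_frame", "complete", "duration_s"],
    )
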