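"""Event-onset-aligned kinetics and per-track pause-index statistics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .event_detection import EventSet, SignalingEvent
from .track_model import CalciumTrace, SpeedTrace

__all__ = [
    "AlignedProfile",
    "PauseRecord",
    "align_events",
    "pause_index",
    "pause_records",
    "summarize_kinetics",
]


@dataclass
class AlignedProfile:
    """Mean calcium ratio and speed relative to event onset (rel_time 0).

    Negative relative times are pre-onset context. ``n_cells``/``n_speed``
    give the number of tracks contributing ratio/speed data at each
    relative timepoint; means and SDs are NaN where no track contributes.
    """

    rel_time_s: np.ndarray
    mean_ratio: np.ndarray
    sd_ratio: np.ndarray
    mean_speed: np.ndarray
    sd_speed: np.ndarray
    n_cells: np.ndarray
    n_speed: np.ndarray

    def __len__(self) -> int:
        return len(self.rel_time_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rel_time_s": self.rel_time_s,
                "mean_ratio": self.mean_ratio,
                "sd_ratio": self.sd_ratio,
                "mean_speed": self.mean_speed,
                "sd_speed": self.sd_speed,
                "n_cells": self.n_cells,
                "n_speed": self.n_speed,
            }
        )


@dataclass
class PauseRecord:
    """Per-track signaling vs nonsignaling mean speeds (um/min).

    ``pause_index = mean_speed_nonsignaling - mean_speed_signaling``;
    positive values indicate migratory pausing during signaling.
    """

    track_id: str
    run_id: str
    condition: str
    mean_speed_signaling: float
    mean_speed_nonsignaling: float

    @property
    def pause_index(self) -> float:
        return self.mean_speed_nonsignaling - self.mean_speed_signaling


def _ragged_mean(stack: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    arr = np.vstack(stack)
    n = np.sum(~np.isnan(arr), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # empty slices -> NaN
        mean = np.nanmean(arr, axis=0)
        sd = np.nanstd(arr, axis=0, ddof=0)
    return mean, sd, n


def align_events(
    traces: Sequence[CalciumTrace],
    speeds: Sequence[SpeedTrace],
    event_set: EventSet,
    window_pre_s: float = 60.0,
    window_post_s: float = 600.0,
    frame_interval_s: float = 10.0,
    *,
    all_events: bool = False,
    use_smoothed_speed: bool = True,
) -> AlignedProfile:
    """Average ratio and speed across tracks aligned at event onset.

    Each aligned unit is a track's first event onset (or every event onset
    with ``all_events=True``). For each relative timepoint in
    [-window_pre_s, +window_post_s] (step = one frame interval) the mean is
    taken over the tracks that have data there (ragged averaging); per-
    timepoint contributing-track counts are reported alongside.

    Aligned speed curves use the smoothed speed by default; pass
    ``use_smoothed_speed=False`` for the instantaneous speed.
    """
    if window_pre_s < 0 or window_post_s < 0:
        raise ValueError("alignment windows must be >= 0")
    k_pre = int(round(window_pre_s / frame_interval_s))
    k_post = int(round(window_post_s / frame_interval_s))
    offsets = np.arange(-k_pre, k_post + 1)
    rel_time = offsets * frame_interval_s

    trace_map = {(t.run_id, t.track_id): t for t in traces}
    speed_map = {(s.run_id, s.track_id): s for s in speeds}

    ratio_rows: list[np.ndarray] = []
    speed_rows: list[np.ndarray] = []
    for key, evs in event_set.events_by_track.items():
        if not evs or key not in trace_map:
            continue
        onsets = [ev.start_frame for ev in (evs if all_events else evs[:1])]
        tr = trace_map[key]
        sp = speed_map.get(key)
        for onset in onsets:
            row_r = np.full(len(offsets), np.nan)
            target = onset + offsets
            idx = np.searchsorted(tr.frames, target)
            ok = (idx < len(tr.frames)) & (tr.frames[np.minimum(idx, len(tr.frames) - 1)] == target)
            row_r[ok] = tr.ratio[idx[ok]]
            ratio_rows.append(row_r)

            row_s = np.full(len(offsets), np.nan)
            if sp is not None and len(sp):
                vals = sp.speed_smooth if use_smoothed_speed else sp.speed_inst
                idx = np.searchsorted(sp.frames, target)
                ok = (idx < len(sp.frames)) & (
                    sp.frames[np.minimum(idx, len(sp.frames) - 1)] == target
                )
                row_s[ok] = vals[idx[ok]]
            speed_rows.append(row_s)

    if not ratio_rows:
        warnings.warn("no signaling tracks to align; empty profile")
        empty = np.empty(0)
        return AlignedProfile(empty, empty, empty, empty, empty, np.empty(0, int), np.empty(0, int))

    mean_r, sd_r, n_r = _ragged_mean(ratio_rows)
    mean_s, sd_s, n_s = _ragged_mean(speed_rows)
    return AlignedProfile(rel_time, mean_r, sd_r, mean_s, sd_s, n_r, n_s)


def _signaling_mask(frames: np.ndarray, events: Sequence[SignalingEvent]) -> np.ndarray:
    mask = np.zeros(len(frames), dtype=bool)
    for ev in events:
        if ev.complete:
            mask |= (frames >= ev.start_frame) & (frames < ev.end_frame)
        else:
            mask |= frames >= ev.start_frame
    return mask


def pause_index(
    speed_trace: SpeedTrace, events: Sequence[SignalingEvent]
) -> PauseRecord | None:
    """Per-track pause record: nonsignaling minus signaling mean speed.

    Timepoints inside any event span (trigger to release; truncated events
    run to track end) are signaling, all others nonsignaling; both means
    use the instantaneous (unsmoothed) speed. Tracks that are entirely
    signaling or entirely nonsignaling are undefined and return ``None``
    with a warning.
    """
    if not events or len(speed_trace) == 0:
        return None
    mask = _signaling_mask(speed_trace.frames, events)
    if mask.all() or not mask.any():
        warnings.warn(
            f"track {speed_trace.track_id}: entirely "
            f"{'signaling' if mask.all() else 'nonsignaling'}; pause index undefined"
        )
        return None
    return PauseRecord(
        track_id=speed_trace.track_id,
        run_id=speed_trace.run_id,
        condition=speed_trace.condition,
        mean_speed_signaling=float(speed_trace.speed_inst[mask].mean()),
        mean_speed_nonsignaling=float(speed_trace.speed_inst[~mask].mean()),
    )


def pause_records(
    speeds: Sequence[SpeedTrace], event_set: EventSet
) -> list[PauseRecord]:
    """Pause records for every track with at least one event (where defined)."""
    out = []
    for sp in speeds:
        evs = event_set.events_by_track.get((sp.run_id, sp.track_id), [])
        rec = pause_index(sp, evs)
        if rec is not None:
            out.append(rec)
    return out


def summarize_kinetics(
    pause_recs: Mapping[str, Sequence[PauseRecord]],
    durations: Mapping[str, Sequence[float]],
    frequencies: Mapping[str, float],
    percent_elevated: Mapping[str, float],
) -> pd.DataFrame:
    """Per-condition summary of signaling statistics.

    One row per condition (sorted by name): number of signaling cells,
    mean +/- SD first-event duration, mean +/- SD pause index, event
    frequency, and fraction of elevated timepoints. Conditions appearing in
    any input are included; missing quantities are NaN.
    """
    conditions = sorted(
        set(pause_recs) | set(durations) | set(frequencies) | set(percent_elevated)
    )
    rows = []
    for cond in conditions:
        recs = list(pause_recs.get(cond, []))
        durs = np.asarray(list(durations.get(cond, [])), dtype=float)
        pis = np.asarray([r.pause_index for r in recs], dtype=float)
        rows.append(
            {
                "condition": cond,
                "n_signaling_cells": len(recs),
                "mean_duration_s": durs.mean() if durs.size else np.nan,
                "sd_duration_s": durs.std(ddof=0) if durs.size else np.nan,
                "mean_pause_index": pis.mean() if pis.size else np.nan,
                "sd_pause_index": pis.std(ddof=0) if pis.size else np.nan,
                "events_per_min": frequencies.get(cond, np.nan),
                "frac_elevated_timepoints": percent_elevated.get(cond, np.nan),
            }
        )
    cols = [
        "condition",
        "n_signaling_cells",
        "mean_duration_s",
        "sd_duration_s",
        "mean_pause_index",
        "sd_pause_index",
        "events_per_min",
        "frac_elevated_timepoints",
    ]
    return pd.DataFrame(rows, columns=cols)


def plot_profile(profile: AlignedProfile, path: str, title: str | None = None) -> None:
    """Write a mean +/- SD band plot (ratio top, speed bottom) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(6, 5))
    t = profile.rel_time_s
    ax1.plot(t, profile.mean_ratio, color="tab:purple")
    ax1.fill_between(
        t,
        profile.mean_ratio - profile.sd_ratio,
        profile.mean_ratio + profile.sd_ratio,
        alpha=0.3,
        color="tab:purple",
    )
    ax1.set_ylabel("Ca ratio")
    ax2.plot(t, profile.mean_speed, color="tab:green")
    ax2.fill_between(
        t,
        profile.mean_speed - profile.sd_speed,
        profile.mean_speed + profile.sd_speed,
        alpha=0.3,
        color="tab:green",
    )
    ax2.set_ylabel("speed (um/min)")
    ax2.set_xlabel("time from event onset (s)")
    if title:
        ax1.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
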