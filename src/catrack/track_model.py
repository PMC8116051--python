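"""Cell-track tables and per-track derived quantities (calcium ratio, speed).

A track table holds one row per (track, frame) with 3D position in microns
and the two raw fluorescence channels of a ratiometric calcium indicator.
Derived traces are the bound/unbound ratio and the instantaneous /
window-smoothed speed.

Conventions
-----------
* Frames are 0-based integers; ``time_s = frame * frame_interval_s``.
* Speed at frame 0 is undefined: speed traces start at the second frame of
  a track and use the trailing (backward) displacement.
* Tracks with internal frame gaps are split into contiguous fragments at
  read time; fragment ids get a ``#<k>`` suffix.
* Units are fixed: positions in um, times in seconds, speeds in um/min.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionParams",
    "TrackTable",
    "CalciumTrace",
    "SpeedTrace",
    "TrackValidationError",
    "TrackFormatError",
    "read_tracks",
    "write_tracks",
    "compute_ratio",
    "compute_speed",
    "export_timepoint_table",
]

REQUIRED_COLUMNS = (
    "run_id",
    "condition",
    "track_id",
    "frame",
    "x_um",
    "y_um",
    "z_um",
    "ca_bound",
    "ca_unbound",
)

CONDITIONS = ("selecting", "nonselecting")


class TrackFormatError(ValueError):
    """Input file does not have the expected columns."""


class TrackValidationError(ValueError):
    """Track data violates an invariant (duplicate frame, bad channel value, ...)."""


@dataclass(frozen=True)
class AcquisitionParams:
    """Imaging acquisition parameters.

    Parameters
    ----------
    frame_interval_s : float
        Seconds between consecutive frames (default 10 s).
    speed_smoothing_window : int
        Trailing window, in timepoints, for the smoothed speed (default 2,
        i.e. a 20 s average at the default frame interval).
    """

    frame_interval_s: float = 10.0
    speed_smoothing_window: int = 2

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.speed_smoothing_window < 1:
            raise ValueError("speed_smoothing_window must be >= 1")


@dataclass
class CalciumTrace:
    """Per-track bound/unbound calcium ratio time series."""

    track_id: str
    run_id: str
    condition: str
    frames: np.ndarray
    times_s: np.ndarray
    ratio: np.ndarray

    def __len__(self) -> int:
        return len(self.ratio)


@dataclass
class SpeedTrace:
    """Per-track speed time series (um/min).

    ``speed_inst[i]`` is the displacement from the previous frame divided by
    the frame interval; entries correspond to ``frames`` starting at the
    track's second frame, so a speed trace is one element shorter than the
    track it derives from. ``speed_smooth`` is a trailing rolling mean over
    ``speed_smoothing_window`` available values.
    """

    track_id: str
    run_id: str
    condition: str
    frames: np.ndarray
    times_s: np.ndarray
    speed_inst: np.ndarray
    speed_smooth: np.ndarray

    def __len__(self) -> int:
        return len(self.speed_inst)


@dataclass
class TrackTable:
    """Validated collection of per-timepoint track records.

    Wraps a :class:`pandas.DataFrame` with columns ``run_id, condition,
    track_id, frame, time_s, x_um, y_um, z_um, ca_bound, ca_unbound``,
    sorted by (run_id, track_id, frame).
    """

    df: pd.DataFrame
    params: AcquisitionParams = field(default_factory=AcquisitionParams)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.df
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise TrackFormatError(f"missing required columns: {missing}")
        if "time_s" not in df.columns:
            df["time_s"] = df["frame"].to_numpy(float) * self.params.frame_interval_s
        bad_cond = set(df["condition"].unique()) - set(CONDITIONS)
        if bad_cond:
            raise TrackValidationError(
                f"unknown condition labels {sorted(bad_cond)}; expected {CONDITIONS}"
            )
        if (df["frame"] < 0).any():
            row = df.index[df["frame"] < 0][0]
            raise TrackValidationError(f"negative frame index at row {row}")
        nonpos = df["ca_unbound"] <= 0
        if nonpos.any():
            row = df.index[nonpos][0]
            raise TrackValidationError(f"nonpositive ca_unbound at row {row}")
        if (df["ca_bound"] < 0).any():
            row = df.index[df["ca_bound"] < 0][0]
            raise TrackValidationError(f"negative ca_bound at row {row}")
        dup = df.duplicated(subset=["run_id", "track_id", "frame"])
        if dup.any():
            row = df.index[dup][0]
            raise TrackValidationError(f"duplicate (run, track, frame) at row {row}")
        per_track = df.groupby(["run_id", "track_id"], sort=False)
        n_conditions = per_track["condition"].nunique()
        if (n_conditions > 1).any():
            key = n_conditions.index[n_conditions > 1][0]
            raise TrackValidationError(f"track {key} has mixed condition labels")
        self.df = df.sort_values(["run_id", "track_id", "frame"], kind="stable").reset_index(
            drop=True
        )

    # -- access helpers -------------------------------------------------

    def groups(self) -> Iterable[tuple[tuple[str, str], pd.DataFrame]]:
        """Iterate (``(run_id, track_id)``, per-track frame-sorted frame)."""
        yield from self.df.groupby(["run_id", "track_id"], sort=True)

    @property
    def n_tracks(self) -> int:
        return self.df.groupby(["run_id", "track_id"]).ngroups

    def __len__(self) -> int:
        return len(self.df)


def _split_gapped_tracks(df: pd.DataFrame) -> pd.DataFrame:
    """Split tracks at frame gaps > 1 into contiguous fragments.

    Fragment track ids get a ``#<k>`` suffix (k = 1-based fragment index);
    tracks without gaps keep their original id.
    """
    parts: list[pd.DataFrame] = []
    for (_, _), grp in df.groupby(["run_id", "track_id"], sort=False):
        frames = grp["frame"].to_numpy()
        breaks = np.flatnonzero(np.diff(frames) > 1)
        if len(breaks) == 0:
            parts.append(grp)
            continue
        bounds = np.concatenate([[0], breaks + 1, [len(grp)]])
        for k in range(len(bounds) - 1):
            frag = grp.iloc[bounds[k] : bounds[k + 1]].copy()
            frag["track_id"] = frag["track_id"].astype(str) + f"#{k + 1}"
            parts.append(frag)
    return pd.concat(parts, ignore_index=True) if parts else df


def read_tracks(
    path: str | Path,
    params: AcquisitionParams | None = None,
    *,
    sep: str | None = None,
    split_gaps: bool = True,
) -> TrackTable:
    """Read a delimited-text track table.

    Parameters
    ----------
    path : path
        Comma- or tab-delimited file with a header naming at least
        ``run_id, condition, track_id, frame, x_um, y_um, z_um, ca_bound,
        ca_unbound``. ``time_s`` is filled from the frame index if absent.
    params : AcquisitionParams, optional
        Frame interval and smoothing window; defaults apply if omitted.
    sep : str, optional
        Field delimiter; sniffed from the header line when not given.
    split_gaps : bool
        Split tracks at frame gaps larger than one interval (default True).

    Raises
    ------
    TrackFormatError
        If a required column is missing.
    TrackValidationError
        If any invariant is violated (the message names the offending row).
    """
    params = params or AcquisitionParams()
    path = Path(path)
    if sep is None:
        header = path.open().readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"{path}: missing required columns: {missing}")
    df["run_id"] = df["run_id"].astype(str)
    df["track_id"] = df["track_id"].astype(str)
    df["frame"] = df["frame"].astype(int)
    if split_gaps:
        df = _split_gapped_tracks(df.sort_values(["run_id", "track_id", "frame"]))
    return TrackTable(df, params)


def write_tracks(tracks: TrackTable, path: str | Path, *, sep: str = ",") -> None:
    """Write a track table as delimited text (lossless round-trip)."""
    cols = list(REQUIRED_COLUMNS) + ["time_s"]
    tracks.df[cols].to_csv(path, sep=sep, index=False)


def read_imaris_export(
    position_path: str | Path,
    bound_path: str | Path,
    unbound_path: str | Path,
    *,
    run_id: str,
    condition: str,
    params: AcquisitionParams | None = None,
) -> TrackTable:
    """Compatibility reader for spot-tracking exports split across sheets.

    Each input is delimited text keyed by ``TrackID`` and ``Time`` (1-based
    frame index): the position sheet carries ``Position X/Y/Z`` columns and
    the two intensity sheets carry an intensity value column apiece (the
    first column that is not a key is used).
    """
    params = params or AcquisitionParams()

    def _load(p: str | Path) -> pd.DataFrame:
        sep = "\t" if "\t" in Path(p).open().readline() else ","
        return pd.read_csv(p, sep=sep)

    pos = _load(position_path)
    for col in ("TrackID", "Time"):
        if col not in pos.columns:
            raise TrackFormatError(f"{position_path}: missing key column {col}")
    rename = {}
    for axis in "XYZ":
        cands = [c for c in pos.columns if c.lower().replace(" ", "") == f"position{axis.lower()}"]
        if not cands:
            raise TrackFormatError(f"{position_path}: missing Position {axis} column")
        rename[cands[0]] = f"{axis.lower()}_um"
    pos = pos.rename(columns=rename)

    def _intensity(p: str | Path, name: str) -> pd.DataFrame:
        t = _load(p)
        value_cols = [c for c in t.columns if c not in ("TrackID", "Time")]
        if not value_cols:
            raise TrackFormatError(f"{p}: no intensity value column")
        return t[["TrackID", "Time", value_cols[0]]].rename(columns={value_cols[0]: name})

    merged = pos.merge(_intensity(bound_path, "ca_bound"), on=["TrackID", "Time"])
    merged = merged.merge(_intensity(unbound_path, "ca_unbound"), on=["TrackID", "Time"])
    df = pd.DataFrame(
        {
            "run_id": run_id,
            "condition": condition,
            "track_id": merged["TrackID"].astype(str),
            "frame": merged["Time"].astype(int) - 1,
            "x_um": merged["x_um"],
            "y_um": merged["y_um"],
            "z_um": merged["z_um"],
            "ca_bound": merged["ca_bound"],
            "ca_unbound": merged["ca_unbound"],
        }
    )
    return TrackTable(_split_gapped_tracks(df.sort_values(["track_id", "frame"])), params)


def compute_ratio(tracks: TrackTable) -> list[CalciumTrace]:
    """Per-track calcium ratio r_t = ca_bound_t / ca_unbound_t."""
    traces = []
    for (run_id, track_id), grp in tracks.groups():
        traces.append(
            CalciumTrace(
                track_id=track_id,
                run_id=run_id,
                condition=grp["condition"].iloc[0],
                frames=grp["frame"].to_numpy(int),
                times_s=grp["time_s"].to_numpy(float),
                ratio=grp["ca_bound"].to_numpy(float) / grp["ca_unbound"].to_numpy(float),
            )
        )
    return traces


def compute_speed(tracks: TrackTable, params: AcquisitionParams | None = None) -> list[SpeedTrace]:
    """Per-track instantaneous and smoothed speed in um/min.

    The instantaneous speed at frame ``i`` (``i >= 1``) is the Euclidean
    displacement from frame ``i-1`` divided by the elapsed time, converted
    to um/min. The smoothed speed is a trailing rolling mean over
    ``params.speed_smoothing_window`` values (partial windows at the start
    use the values available).

    Single-point tracks yield an empty speed trace with a warning.
    """
    params = params or tracks.params
    w = params.speed_smoothing_window
    out = []
    for (run_id, track_id), grp in tracks.groups():
        if len(grp) < 2:
            warnings.warn(f"track {track_id} (run {run_id}) has a single point; empty speed trace")
            out.append(
                SpeedTrace(
                    track_id, run_id, grp["condition"].iloc[0],
                    np.empty(0, int), np.empty(0), np.empty(0), np.empty(0),
                )
            )
            continue
        xyz = grp[["x_um", "y_um", "z_um"]].to_numpy(float)
        times = grp["time_s"].to_numpy(float)
        disp = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        dt = np.diff(times)
        speed = disp / dt * 60.0
        smooth = (
            pd.Series(speed).rolling(w, min_periods=1).mean().to_numpy()
        )
        out.append(
            SpeedTrace(
                track_id=track_id,
                run_id=run_id,
                condition=grp["condition"].iloc[0],
                frames=grp["frame"].to_numpy(int)[1:],
                times_s=times[1:],
                speed_inst=speed,
                speed_smooth=smooth,
            )
        )
    return out


def _event_mask(frames: np.ndarray, events, track_last_frame: int) -> np.ndarray:
    """Boolean in-event flag for the given frames.

    Complete events cover the half-open span [start_frame, end_frame);
    incomplete events extend to the end of the track.
    """
    mask = np.zeros(len(frames), dtype=bool)
    for ev in events:
        end = ev.end_frame if ev.complete else track_last_frame + 1
        mask |= (frames >= ev.start_frame) & (frames < end)
    return mask


def export_timepoint_table(
    tracks: TrackTable,
    traces: Sequence[CalciumTrace],
    speeds: Sequence[SpeedTrace],
    events_by_track: Mapping[tuple[str, str], Sequence] | None = None,
) -> pd.DataFrame:
    """Flatten tracks plus derived traces into one row per (track, timepoint).

    The output carries the raw columns plus ``ratio``, ``speed_inst``,
    ``speed_smooth`` (NaN at each track's first frame) and a boolean
    ``in_event`` column (False everywhere when no events are given) —
    a flow-cytometry-like table for gating-style analysis.
    """
    trace_map = {(t.run_id, t.track_id): t for t in traces}
    speed_map = {(s.run_id, s.track_id): s for s in speeds}
    keys = {(r, t) for (r, t), _ in tracks.groups()}
    if set(trace_map) - keys or set(speed_map) - keys:
        raise TrackValidationError("trace/speed track ids do not match the track table")

    rows = []
    for (run_id, track_id), grp in tracks.groups():
        key = (run_id, track_id)
        if key not in trace_map or key not in speed_map:
            raise TrackValidationError(f"missing derived trace for track {key}")
        tr, sp = trace_map[key], speed_map[key]
        block = grp.copy()
        block["ratio"] = tr.ratio
        inst = np.full(len(grp), np.nan)
        smooth = np.full(len(grp), np.nan)
        if len(sp):
            idx = np.searchsorted(grp["frame"].to_numpy(int), sp.frames)
            inst[idx] = sp.speed_inst
            smooth[idx] = sp.speed_smooth
        block["speed_inst"] = inst
        block["speed_smooth"] = smooth
        evs = (events_by_track or {}).get(key, [])
        block["in_event"] = _event_mask(
            grp["frame"].to_numpy(int), evs, int(grp["frame"].iloc[-1])
        )
        rows.append(block)
    if not rows:
        cols = list(REQUIRED_COLUMNS) + ["time_s", "ratio", "speed_inst", "speed_smooth", "in_event"]
        return pd.DataFrame(columns=cols)
    return pd.concat(rows, ignore_index=True)
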