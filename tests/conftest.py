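from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from catrack.track_model import AcquisitionParams, CalciumTrace, TrackTable


def make_table(
    tracks: dict[str, np.ndarray | list],
    *,
    condition: str = "selecting",
    run_id: str = "r1",
    frame_interval_s: float = 10.0,
    positions: dict[str, np.ndarray] | None = None,
    unbound: float = 1.5,
) -> TrackTable:
    """Build a TrackTable from per-track ratio vectors (and optional xyz)."""
    blocks = []
    for tid, ratios in tracks.items():
        ratios = np.asarray(ratios, dtype=float)
        n = len(ratios)
        if positions and tid in positions:
            xyz = np.asarray(positions[tid], dtype=float)
        else:
            xyz = np.zeros((n, 3))
        blocks.append(
            pd.DataFrame(
                {
                    "run_id": run_id,
                    "condition": condition,
                    "track_id": tid,
                    "frame": np.arange(n),
                    "x_um": xyz[:, 0],
                    "y_um": xyz[:, 1],
                    "z_um": xyz[:, 2],
                    "ca_bound": ratios * unbound,
                    "ca_unbound": unbound,
                }
            )
        )
    return TrackTable(
        pd.concat(blocks, ignore_index=True),
        AcquisitionParams(frame_interval_s=frame_interval_s),
    )


def make_trace(
    ratios,
    *,
    track_id: str = "t1",
    run_id: str = "r1",
    condition: str = "selecting",
    frame_interval_s: float = 10.0,
) -> CalciumTrace:
    r = np.asarray(ratios, dtype=float)
    frames = np.arange(len(r))
    return CalciumTrace(track_id, run_id, condition, frames, frames * frame_interval_s, r)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_table():
    """Two short tracks, one of each condition."""
    sel = make_table({"a": [0.9, 0.9, 0.6, 0.6]}, condition="selecting")
    non = make_table({"b": [0.65, 0.7, 0.675]}, condition="nonselecting", run_id="r2")
    return TrackTable(pd.concat([sel.df, non.df], ignore_index=True))
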