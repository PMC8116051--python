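"""Independent reference implementations used only to check the package.

These deliberately use a different formulation from the library code: the
event scan below precomputes the full sets of trigger and release positions
and walks them, rather than scanning statefully.
"""

from __future__ import annotations

import numpy as np


def brute_force_events(
    ratio, background: float, delta_high: float = 0.2, delta_low: float = 0.1,
    min_consecutive: int = 2,
) -> list[tuple[int, int | None]]:
    """Enumerate hysteresis events as (start_index, end_index_or_None).

    A position i is a trigger position if all of ratio[i : i+m] are
    >= background + delta_high; a release position if all of
    ratio[j : j+m] are < background + delta_low. Events: the earliest
    trigger at or after the cursor starts an event; the earliest release
    strictly after the start ends it; the cursor jumps past the release
    pair. A started event with no release runs to the end (end=None).
    """
    r = np.asarray(ratio, dtype=float)
    n = len(r)
    m = min_consecutive
    hi = background + delta_high
    lo = background + delta_low
    triggers = [i for i in range(n - m + 1) if all(r[i + k] >= hi for k in range(m))]
    releases = [j for j in range(n - m + 1) if all(r[j + k] < lo for k in range(m))]
    events: list[tuple[int, int | None]] = []
    cursor = 0
    while True:
        starts = [i for i in triggers if i >= cursor]
        if not starts:
            break
        start = starts[0]
        ends = [j for j in releases if j > start]
        if not ends:
            events.append((start, None))
            break
        end = ends[0]
        events.append((start, end))
        cursor = end + m
    return events


def random_walk_trace(rng: np.random.Generator, n: int, background: float) -> np.ndarray:
    """Random-walk ratio trace wandering around the background level."""
    steps = rng.normal(0.0, 0.08, n)
    r = background + np.cumsum(steps)
    # soft pull back toward background so both thresholds get exercised
    r = background + (r - background) * 0.8 + rng.normal(0, 0.05, n)
    return np.clip(r, 0.01, None)
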