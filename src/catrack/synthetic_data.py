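"""Simulators: cell tracks with ground-truth calcium events, and expression
matrices with planted gene signatures.

The track simulator emits the same delimited-text schema that
:mod:`catrack.track_model` reads, so every downstream stage can be exercised
end to end against known ground truth. Event counts per track are Poisson
with mean ``event_rate_per_min x track_minutes``; events are placed by
rejection sampling subject to a refractory separation, so the realized
onset rate is unbiased with respect to the nominal rate (up to rare
placement failures on crowded tracks).

Randomness: one :class:`numpy.random.Generator` seeded from ``rng_seed``
drives every stream, in a fixed order (per track: event count, durations,
onsets, ratio noise, unbound channel, headings, step speeds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .track_model import AcquisitionParams, TrackTable

__all__ = [
    "TrackSimParams",
    "GroundTruth",
    "EventSpan",
    "ExprSimParams",
    "simulate_tracks",
    "simulate_expression",
]


@dataclass(frozen=True)
class TrackSimParams:
    """Parameters for the cell-track simulator.

    Ratio model: baseline + amplitude * shape(t) + Gaussian noise, where
    shape is 1 inside an event and 0 outside ("square", the default) or a
    one-frame rise followed by exponential decay ("rise_decay").
    Motility model: persistent random walk; per-step speed is drawn around
    ``speed_base_um_min``, reduced by ``speed_drop_during_event_um_min``
    for steps landing on in-event frames, and clipped at zero.
    """

    n_tracks: int = 100
    duration_s: float = 1200.0
    frame_interval_s: float = 10.0
    baseline_ratio: float = 0.675
    ratio_noise_sd: float = 0.03
    event_rate_per_min: float = 1.0 / 75.0
    event_duration_mean_s: float = 240.0
    event_shape: str = "square"
    event_amplitude: float = 0.3
    refractory_s: float = 300.0
    speed_base_um_min: float = 6.0
    speed_sd: float = 1.0
    speed_drop_during_event_um_min: float = 3.0
    motility_persistence: float = 0.6
    condition: str = "selecting"
    run_id: str = "sim"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tracks < 1 or self.duration_s <= 0 or self.frame_interval_s <= 0:
            raise ValueError("n_tracks, duration_s and frame_interval_s must be positive")
        if self.event_rate_per_min < 0 or self.event_duration_mean_s <= 0:
            raise ValueError("event rate must be >= 0 and mean duration > 0")
        if self.refractory_s <= 0:
            raise ValueError("refractory_s must be > 0")
        if not 0.0 <= self.motility_persistence <= 1.0:
            raise ValueError("motility_persistence must be in [0, 1]")
        if self.event_shape not in ("square", "rise_decay"):
            raise ValueError("event_shape must be 'square' or 'rise_decay'")


@dataclass(frozen=True)
class EventSpan:
    """One injected event: frames [start, end), truncated if clipped at track end."""

    start_frame: int
    end_frame: int
    truncated: bool


@dataclass
class GroundTruth:
    """Injected events and per-timepoint flags for a simulated track set."""

    spans_by_track: dict[tuple[str, str], list[EventSpan]] = field(default_factory=dict)
    in_event_by_track: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    amplitude: float = 0.0
    speed_drop_um_min: float = 0.0

    def n_events(self) -> int:
        return sum(len(v) for v in self.spans_by_track.values())

    def complete_durations_s(self, frame_interval_s: float) -> list[float]:
        """Durations of non-truncated injected events, in seconds."""
        return [
            (sp.end_frame - sp.start_frame) * frame_interval_s
            for spans in self.spans_by_track.values()
            for sp in spans
            if not sp.truncated
        ]

    def first_complete_durations_s(self, frame_interval_s: float) -> list[float]:
        """Per-track duration of the first injected event when not truncated."""
        out = []
        for spans in self.spans_by_track.values():
            if spans and not spans[0].truncated:
                out.append((spans[0].end_frame - spans[0].start_frame) * frame_interval_s)
        return out


def _place_events(
    rng: np.random.Generator, n_frames: int, rate_per_frame: float,
    mean_dur_frames: float, refr_frames: int,
) -> list[EventSpan]:
    """Draw a Poisson number of events and place them without overlap.

    Onsets are uniform over frames [0, n_frames - 2] (so every event has at
    least two in-track frames); accepted placements keep >= refr_frames
    between the end of one event and the start of the next. Placement
    failures after many attempts drop the event (rare at realistic rates).
    """
    k = rng.poisson(rate_per_frame * n_frames)
    spans: list[tuple[int, int]] = []
    for _ in range(k):
        dur = max(2, int(round(rng.exponential(mean_dur_frames))))
        placed = False
        for _attempt in range(200):
            start = int(rng.integers(0, n_frames - 1))
            end = start + dur
            ok = all(
                end + refr_frames <= s or e + refr_frames <= start for s, e in spans
            )
            if ok:
                spans.append((start, end))
                placed = True
                break
        if not placed:
            warnings.warn("could not place an event without overlap; dropped")
    spans.sort()
    return [
        EventSpan(s, min(e, n_frames), truncated=e > n_frames) for s, e in spans
    ]


def _event_shape_profile(
    shape: str, n_frames: int, spans: Sequence[EventSpan], decay_tau_frames: float
) -> np.ndarray:
    prof = np.zeros(n_frames)
    for sp in spans:
        if shape == "square":
            prof[sp.start_frame : sp.end_frame] = 1.0
        else:  # rise_decay: one-frame rise to 1, exponential decay over the span
            length = sp.end_frame - sp.start_frame
            t = np.arange(length, dtype=float)
            prof[sp.start_frame : sp.end_frame] = np.maximum(
                prof[sp.start_frame : sp.end_frame], np.exp(-t / decay_tau_frames)
            )
    return prof


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def simulate_tracks(params: TrackSimParams) -> tuple[TrackTable, GroundTruth]:
    """Simulate a track table with known calcium events and motility.

    Returns the table plus a :class:`GroundTruth` with the injected event
    spans, per-timepoint in-event flags, and the injected amplitude and
    speed drop. The two fluorescence channels are emitted such that
    bound/unbound exactly equals the intended ratio.
    """
    if params.event_amplitude <= 0.2 and params.event_rate_per_min > 0:
        warnings.warn(
            "event amplitude <= 0.2: events may be undetectable at default thresholds"
        )
    rng = np.random.default_rng(params.rng_seed)
    dt = params.frame_interval_s
    n_frames = int(round(params.duration_s / dt)) + 1
    rate_per_frame = params.event_rate_per_min * dt / 60.0
    refr_frames = max(1, int(round(params.refractory_s / dt)))
    mean_dur_frames = params.event_duration_mean_s / dt
    decay_tau = max(mean_dur_frames / 3.0, 1.0)

    gt = GroundTruth(
        amplitude=params.event_amplitude,
        speed_drop_um_min=params.speed_drop_during_event_um_min,
    )
    frames = np.arange(n_frames)
    blocks = []
    for i in range(params.n_tracks):
        track_id = f"t{i:04d}"
        key = (params.run_id, track_id)
        spans = (
            _place_events(rng, n_frames, rate_per_frame, mean_dur_frames, refr_frames)
            if params.event_rate_per_min > 0
            else []
        )
        shape = _event_shape_profile(params.event_shape, n_frames, spans, decay_tau)
        in_event = shape > 0 if params.event_shape == "square" else np.zeros(n_frames, bool)
        if params.event_shape != "square":
            for sp in spans:
                in_event[sp.start_frame : sp.end_frame] = True
        gt.spans_by_track[key] = spans
        gt.in_event_by_track[key] = in_event

        ratio = (
            params.baseline_ratio
            + params.event_amplitude * shape
            + rng.normal(0.0, params.ratio_noise_sd, n_frames)
        )
        ratio = np.maximum(ratio, 1e-3)
        unbound = np.exp(rng.normal(np.log(1.5), 0.1, n_frames))
        bound = ratio * unbound

        headings = np.empty((n_frames - 1, 3))
        fresh = _random_unit_vectors(rng, n_frames - 1)
        h = fresh[0]
        p = params.motility_persistence
        for j in range(n_frames - 1):
            h = p * h + (1.0 - p) * fresh[j]
            h /= np.linalg.norm(h)
            headings[j] = h
        step_mean = np.where(
            in_event[1:],
            params.speed_base_um_min - params.speed_drop_during_event_um_min,
            params.speed_base_um_min,
        )
        step_speed = np.maximum(rng.normal(step_mean, params.speed_sd), 0.0)
        disp = headings * (step_speed * dt / 60.0)[:, None]
        xyz = np.vstack([[0.0, 0.0, 0.0], np.cumsum(disp, axis=0)])
        xyz += rng.uniform(0.0, 200.0, 3)  # random start in the field of view

        blocks.append(
            pd.DataFrame(
                {
                    "run_id": params.run_id,
                    "condition": params.condition,
                    "track_id": track_id,
                    "frame": frames,
                    "x_um": xyz[:, 0],
                    "y_um": xyz[:, 1],
                    "z_um": xyz[:, 2],
                    "ca_bound": bound,
                    "ca_unbound": unbound,
                }
            )
        )
    table = TrackTable(
        pd.concat(blocks, ignore_index=True),
        AcquisitionParams(frame_interval_s=dt),
    )
    return table, gt


# ---------------------------------------------------------------------------
# expression simulator


@dataclass(frozen=True)
class ExprSimParams:
    """Parameters for the expression-matrix simulator.

    Three populations (DN4, DP69neg, DP69pos) with ``n_replicates`` samples
    each. Planted signature genes have expected expression
    ``planted_base`` in DP69neg and ``planted_base / 2**planted_log2fc`` in
    both comparators; background genes share a per-gene baseline across
    populations. Multiplicative log-normal noise with sigma ``noise_sd``
    (natural log scale); 0 disables noise.
    """

    n_genes: int = 500
    n_replicates: int = 3
    planted_genes: tuple[str, ...] = ()
    planted_log2fc: float = 2.0
    planted_base: float = 3000.0
    baseline_log_mean: float = np.log(300.0)
    baseline_log_sd: float = 1.0
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_replicates < 2:
            raise ValueError("need n_genes >= 1 and n_replicates >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


POPULATIONS = ("DN4", "DP69neg", "DP69pos")


def simulate_expression(
    params: ExprSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Simulate a gene-by-sample expression matrix with a planted signature.

    Returns ``(values, samples, planted)``: the genes x samples matrix, a
    sample annotation table with ``sample_id, population, replicate``, and
    the planted gene list. Planted gene names not of the default
    ``G<number>`` form are appended to the gene universe.
    """
    rng = np.random.default_rng(params.rng_seed)
    genes = [f"G{i:04d}" for i in range(params.n_genes)]
    planted = list(params.planted_genes)
    for g in planted:
        if g not in genes:
            genes.append(g)

    sample_ids, pops, reps = [], [], []
    for pop in POPULATIONS:
        for r in range(1, params.n_replicates + 1):
            sample_ids.append(f"{pop}_r{r}")
            pops.append(pop)
            reps.append(r)
    samples = pd.DataFrame({"sample_id": sample_ids, "population": pops, "replicate": reps})

    base = np.exp(rng.normal(params.baseline_log_mean, params.baseline_log_sd, len(genes)))
    expected = np.tile(base[:, None], (1, len(sample_ids)))
    comparator = params.planted_base / 2.0**params.planted_log2fc
    pop_arr = np.asarray(pops)
    for g in planted:
        gi = genes.index(g)
        expected[gi, :] = np.where(pop_arr == "DP69neg", params.planted_base, comparator)

    if params.noise_sd > 0:
        noise = np.exp(rng.normal(0.0, params.noise_sd, expected.shape))
        values = expected * noise
    else:
        values = expected
    return pd.DataFrame(values, index=genes, columns=sample_ids), samples, planted
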