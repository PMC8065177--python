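"""Light-avoidance quantification from centroid tracking paths.

The arena is a 45 x 39 cm box split along its width into equally sized
light (300 lux) and dark compartments, connected by a small aperture on the
divider. A mouse is placed in the light compartment and tracked for 10
minutes; light avoidance is the percentage of total time spent in the dark
compartment, plus the latency to the first light-to-dark crossing.

The published crossing criterion (three paws across) is not computable from
a centroid track; compartment changes are instead registered when the
centroid penetrates a hysteresis band (2 cm by default) past the divider,
which suppresses chatter from divider-grazing paths. Occupancy heatmaps
average per-cell dwell time across animals, rendered with a 20 s cap while
the raw dwell values are kept.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig

__all__ = [
    "ArenaConfig",
    "TrackingSession",
    "assign_compartments",
    "time_in_dark",
    "latency_first_cross",
    "occupancy_heatmap",
    "behavior_summary",
]


@dataclass(frozen=True)
class ArenaConfig:
    """Two-compartment arena geometry, all lengths in cm.

    The divider runs parallel to the y axis at ``width_cm / 2``; x below the
    divider is the light compartment, x above it the dark one. The aperture
    spans ``aperture_span_cm`` centered on ``aperture_center_y_cm``.
    """

    width_cm: float = 45.0
    depth_cm: float = 39.0
    aperture_span_cm: float = 7.0
    aperture_center_y_cm: float = 19.5
    grid_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.width_cm <= 0 or self.depth_cm <= 0 or self.grid_cm <= 0:
            raise ValueError("arena dimensions must be positive")
        half = self.aperture_span_cm / 2
        if not 0 <= self.aperture_center_y_cm - half or not (
            self.aperture_center_y_cm + half <= self.depth_cm
        ):
            raise ValueError("aperture must lie on the divider inside the arena")

    @property
    def divider_x_cm(self) -> float:
        return self.width_cm / 2.0


@dataclass
class TrackingSession:
    """Timestamped centroid path of one animal."""

    t_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    group: str = "none"
    subject_id: str = "m0"

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_cm = np.asarray(self.x_cm, dtype=float)
        self.y_cm = np.asarray(self.y_cm, dtype=float)
        if not (len(self.t_s) == len(self.x_cm) == len(self.y_cm)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t_s) == 0:
            raise ValueError("no samples")
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0])


def _clamp_positions(session: TrackingSession, arena: ArenaConfig) -> tuple[np.ndarray, np.ndarray]:
    x, y = session.x_cm, session.y_cm
    out = (x < 0) | (x > arena.width_cm) | (y < 0) | (y > arena.depth_cm)
    if out.any():
        warnings.warn(f"{int(out.sum())} out-of-arena samples clamped to walls")
        x = np.clip(x, 0.0, arena.width_cm)
        y = np.clip(y, 0.0, arena.depth_cm)
    return x, y


def assign_compartments(
    session: TrackingSession,
    arena: ArenaConfig,
    hysteresis_cm: float = 2.0,
) -> np.ndarray:
    """Label each sample ``"light"`` or ``"dark"`` with divider hysteresis.

    A compartment change registers only when the centroid penetrates at
    least ``hysteresis_cm`` past the divider into the other side; samples
    inside the band keep the previous compartment. The first sample takes
    the side of the divider it lies on (light if exactly on it).
    """
    x, _ = _clamp_positions(session, arena)
    div = arena.divider_x_cm
    labels = np.empty(len(x), dtype=object)
    current = "light" if x[0] <= div else "dark"
    for i, xi in enumerate(x):
        if current == "light" and xi >= div + hysteresis_cm:
            current = "dark"
        elif current == "dark" and xi <= div - hysteresis_cm:
            current = "light"
        labels[i] = current
    return labels


def _sample_weights(t: np.ndarray) -> np.ndarray:
    """Midpoint-rule dwell time per sample; sums exactly to t[-1] - t[0].

    Robust to irregular frame rates: each sample owns the span between the
    midpoints of its neighboring intervals, with half-intervals at the ends.
    """
    if len(t) == 1:
        return np.zeros(1)
    mids = 0.5 * (t[:-1] + t[1:])
    bounds = np.concatenate([[t[0]], mids, [t[-1]]])
    return np.diff(bounds)


def time_in_dark(
    session: TrackingSession,
    arena: ArenaConfig,
    hysteresis_cm: float = 2.0,
) -> float:
    """Percentage of total trial time spent in the dark compartment.

    Time-weighted (not sample-counted); with the complementary light-side
    fraction it sums to exactly 100% of the trial.
    """
    if len(session.t_s) < 2:
        raise ValueError("need at least 2 samples")
    labels = assign_compartments(session, arena, hysteresis_cm)
    weights = _sample_weights(session.t_s)
    dark = float(weights[labels == "dark"].sum())
    return 100.0 * dark / session.duration_s


def latency_first_cross(
    session: TrackingSession,
    arena: ArenaConfig,
    hysteresis_cm: float = 2.0,
) -> float:
    """Minutes until the first qualifying light-to-dark crossing.

    The session must start in the light compartment (protocol). Returns NaN
    if the animal never crosses; report such sessions as censored at the
    trial duration.
    """
    labels = assign_compartments(session, arena, hysteresis_cm)
    if labels[0] != "light":
        raise ValueError("session starts in the dark compartment (protocol violation)")
    crossings = np.flatnonzero(labels == "dark")
    if crossings.size == 0:
        return math.nan
    t_cross = session.t_s[int(crossings[0])] - session.t_s[0]
    return t_cross / 60.0


def occupancy_heatmap(
    sessions: list[TrackingSession],
    arena: ArenaConfig,
    cap_s: float = 20.0,
) -> dict[str, np.ndarray]:
    """Mean per-cell dwell time across sessions, with a capped render copy.

    Returns ``{"raw": grid, "render": min(grid, cap), "x_edges", "y_edges"}``.
    The raw grid conserves time: each session's cell dwell sums to its trial
    duration before averaging. Grid resolution is ``arena.grid_cm``.
    """
    if not sessions:
        raise ValueError("need at least one session")
    nx = int(math.ceil(arena.width_cm / arena.grid_cm))
    ny = int(math.ceil(arena.depth_cm / arena.grid_cm))
    x_edges = np.linspace(0.0, arena.width_cm, nx + 1)
    y_edges = np.linspace(0.0, arena.depth_cm, ny + 1)
    total = np.zeros((nx, ny))
    for session in sessions:
        x, y = _clamp_positions(session, arena)
        weights = _sample_weights(session.t_s)
        grid, _, _ = np.histogram2d(
            x, y, bins=[x_edges, y_edges], weights=weights
        )
        total += grid
    raw = total / len(sessions)
    return {
        "raw": raw,
        "render": np.minimum(raw, cap_s),
        "x_edges": x_edges,
        "y_edges": y_edges,
    }


def behavior_summary(
    sessions: list[TrackingSession],
    arena: ArenaConfig,
    hysteresis_cm: float = 2.0,
    trial_duration_s: float = 600.0,
):
    """Per-animal summary rows: % time in dark and first-cross latency.

    Never-crossing sessions report latency censored at the trial duration
    with ``censored=True``.
    """
    import pandas as pd

    rows = []
    for s in sessions:
        latency = latency_first_cross(s, arena, hysteresis_cm)
        censored = math.isnan(latency)
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "pct_time_in_dark": time_in_dark(s, arena, hysteresis_cm),
                "latency_first_cross_min": (
                    trial_duration_s / 60.0 if censored else latency
                ),
                "censored": censored,
            }
        )
    return pd.DataFrame(rows)
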