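"""Rule-based classification of single units into 10 light-response classes.

A unit's trial-averaged PSTH is scanned in three analysis windows defined
relative to a flash of duration D: ON (0, D], OFF (D, 2D] and Sustained
(2D, 8D] (six stimulus durations past the OFF window). Within each window a
unit scores

* ``increase``  — rate > baseline mean + 3 SD for >= 100 ms contiguously,
* ``decrease``  — rate < baseline mean - 1 SD for >= 300 ms contiguously,
* ``none``      — neither criterion met,

and the triple of window states indexes a complete 27-entry lookup table
onto 10 response classes (ON, ON suppressed by dark, ON-OFF, slow
sustained, OFF, OFF suppressed by light, suppressed ON/OFF/ON-OFF, and
non-light-responsive). Triples not pinned down by the class definitions are
resolved by a fixed precedence (ON window > OFF window > Sustained window;
a sustained increase following an ON increase promotes to slow sustained).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig, StimulusProtocol
from .psth import PSTH, BaselineStats, compute_baseline, compute_psth, default_range
from .spikes import SpikeTrain, iter_units

__all__ = [
    "ResponseClass",
    "ResponseWindows",
    "WindowOutcome",
    "WindowState",
    "LOOKUP_TABLE",
    "define_windows",
    "detect_window_outcomes",
    "classify_unit",
    "classify_population",
]


class WindowState(str, enum.Enum):
    INCREASE = "increase"
    DECREASE = "decrease"
    NONE = "none"

    def __str__(self) -> str:  # keep table output compact
        return self.value


class ResponseClass(str, enum.Enum):
    ON = "ON"
    ON_SUPPRESSED_BY_DARK = "ON_SUPPRESSED_BY_DARK"
    ON_OFF = "ON_OFF"
    SLOW_SUSTAINED = "SLOW_SUSTAINED"
    OFF = "OFF"
    OFF_SUPPRESSED_BY_LIGHT = "OFF_SUPPRESSED_BY_LIGHT"
    SUPPRESSED_ON = "SUPPRESSED_ON"
    SUPPRESSED_OFF = "SUPPRESSED_OFF"
    SUPPRESSED_ON_OFF = "SUPPRESSED_ON_OFF"
    NON_LIGHT_RESPONSIVE = "NON_LIGHT_RESPONSIVE"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class ResponseWindows:
    """The three analysis windows, each as (start, end] in seconds."""

    on: tuple[float, float]
    off: tuple[float, float]
    sustained: tuple[float, float]

    @property
    def durations(self) -> tuple[float, float, float]:
        return (
            self.on[1] - self.on[0],
            self.off[1] - self.off[0],
            self.sustained[1] - self.sustained[0],
        )


@dataclass(frozen=True)
class WindowOutcome:
    """Threshold-crossing result inside one analysis window."""

    state: WindowState
    first_crossing_time_s: float | None = None
    crossing_run_length_s: float | None = None
    #: True when baseline SD was zero and the epsilon fallback threshold was used.
    degenerate_baseline: bool = False


def define_windows(protocol: StimulusProtocol, config: RunConfig | None = None) -> ResponseWindows:
    """ON / OFF / Sustained windows for a flash of duration D: lengths (D, D, 6D)."""
    config = config or RunConfig()
    d = protocol.stim_duration_s
    m = config.sustained_multiplier
    return ResponseWindows(
        on=(0.0, d),
        off=(d, 2.0 * d),
        sustained=(2.0 * d, (2.0 + m) * d),
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, length)."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i - start))
            start = None
    if start is not None:
        out.append((start, len(mask) - start))
    return out


def _scan_window(
    psth: PSTH,
    window: tuple[float, float],
    up_thresh: float,
    down_thresh: float,
    config: RunConfig,
    degenerate: bool,
) -> WindowOutcome:
    sl = psth.window_slice(*window)
    rates = psth.rate_hz[sl]
    lefts = psth.bin_edges_s[:-1][sl]
    bw = psth.bin_width_s
    n_up = max(1, int(round(config.up_duration_s / bw)))
    n_down = max(1, int(round(config.down_duration_s / bw)))

    def qualifying(mask: np.ndarray, need: int) -> tuple[float, float] | None:
        if config.contiguous_runs:
            for start, length in _runs(mask):
                if length >= need:
                    return float(lefts[start]), float(length * bw)
            return None
        total = int(mask.sum())
        if total >= need:
            first = int(np.flatnonzero(mask)[0])
            return float(lefts[first]), float(total * bw)
        return None

    up = qualifying(rates > up_thresh, n_up)
    down = qualifying(rates < down_thresh, n_down)
    if up is not None and down is not None:
        # both present: the earlier-starting qualifying run decides the state
        chosen = up if up[0] <= down[0] else down
        state = WindowState.INCREASE if chosen is up else WindowState.DECREASE
        return WindowOutcome(state, chosen[0], chosen[1], degenerate)
    if up is not None:
        return WindowOutcome(WindowState.INCREASE, up[0], up[1], degenerate)
    if down is not None:
        return WindowOutcome(WindowState.DECREASE, down[0], down[1], degenerate)
    return WindowOutcome(WindowState.NONE, None, None, degenerate)


def detect_window_outcomes(
    psth: PSTH,
    baseline: BaselineStats,
    windows: ResponseWindows,
    config: RunConfig | None = None,
) -> dict[str, WindowOutcome]:
    """Apply the amplitude+duration crossing rules in each analysis window.

    With a silent or perfectly regular baseline the SD is zero and the
    thresholds collapse onto the mean; they are then widened to
    mean +/- eps with eps = max(0.5 spikes/s, one spike per trial per
    window), so floating-point noise is never scored as a response. Such
    outcomes carry ``degenerate_baseline=True``.
    """
    config = config or RunConfig()
    if psth.bin_edges_s[-1] < windows.sustained[1] - 1e-9:
        raise ValueError("PSTH range does not cover the sustained window")
    out: dict[str, WindowOutcome] = {}
    for name in ("on", "off", "sustained"):
        window = getattr(windows, name)
        degenerate = baseline.sd_hz == 0.0
        if degenerate:
            duration = window[1] - window[0]
            eps = max(0.5, 1.0 / duration)
            up_thresh = baseline.mean_hz + eps
            down_thresh = baseline.mean_hz - eps
        else:
            up_thresh = baseline.mean_hz + config.up_threshold_sd * baseline.sd_hz
            down_thresh = baseline.mean_hz - config.down_threshold_sd * baseline.sd_hz
        out[name] = _scan_window(psth, window, up_thresh, down_thresh, config, degenerate)
    return out


I, D, N = WindowState.INCREASE, WindowState.DECREASE, WindowState.NONE
R = ResponseClass

#: Complete lookup: (on, off, sustained) window states -> response class.
#: Entries follow the prose class definitions; the remaining triples follow
#: the ON > OFF > Sustained precedence documented in the module docstring.
LOOKUP_TABLE: dict[tuple[WindowState, WindowState, WindowState], ResponseClass] = {
    # ON-window increase
    (I, N, N): R.ON,
    (I, N, D): R.ON,
    (I, N, I): R.SLOW_SUSTAINED,
    (I, I, N): R.ON_OFF,
    (I, I, D): R.ON_OFF,
    (I, I, I): R.SLOW_SUSTAINED,
    (I, D, N): R.ON_SUPPRESSED_BY_DARK,
    (I, D, I): R.ON_SUPPRESSED_BY_DARK,
    (I, D, D): R.ON_SUPPRESSED_BY_DARK,
    # ON-window decrease
    (D, N, N): R.SUPPRESSED_ON,
    (D, N, I): R.SUPPRESSED_ON,
    (D, N, D): R.SUPPRESSED_ON,
    (D, I, N): R.OFF_SUPPRESSED_BY_LIGHT,
    (D, I, I): R.OFF_SUPPRESSED_BY_LIGHT,
    (D, I, D): R.OFF_SUPPRESSED_BY_LIGHT,
    (D, D, N): R.SUPPRESSED_ON_OFF,
    (D, D, I): R.SUPPRESSED_ON_OFF,
    (D, D, D): R.SUPPRESSED_ON_OFF,
    # ON window quiet
    (N, I, N): R.OFF,
    (N, I, I): R.OFF,
    (N, I, D): R.OFF,
    (N, D, N): R.SUPPRESSED_OFF,
    (N, D, I): R.SUPPRESSED_OFF,
    (N, D, D): R.SUPPRESSED_OFF,
    (N, N, I): R.SLOW_SUSTAINED,
    (N, N, D): R.SUPPRESSED_OFF,
    (N, N, N): R.NON_LIGHT_RESPONSIVE,
}


def classify_unit(
    outcomes: dict[str, WindowOutcome] | tuple[WindowState, WindowState, WindowState],
) -> ResponseClass:
    """Map a triple of window states to its response class (total function)."""
    if isinstance(outcomes, dict):
        triple = (
            outcomes["on"].state,
            outcomes["off"].state,
            outcomes["sustained"].state,
        )
    else:
        triple = tuple(WindowState(s) for s in outcomes)
    return LOOKUP_TABLE[triple]


CLASSIFICATION_COLUMNS = (
    "retina_id", "channel", "unit_id", "condition", "response_class",
    "on_state", "off_state", "sustained_state",
    "baseline_mean_hz", "baseline_sd_hz", "degenerate_baseline", "n_spikes",
)


def classify_population(
    spikes: pd.DataFrame,
    protocol: StimulusProtocol,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Classify every unit in a spike table; one output row per unit.

    The table may mix conditions (pre-drug / blockade / washout); units are
    classified separately per condition since each condition is a separate
    recording block.
    """
    config = config or RunConfig()
    if spikes.empty:
        return pd.DataFrame(columns=list(CLASSIFICATION_COLUMNS))
    windows = define_windows(protocol, config)
    t_range = default_range(protocol, config)
    rows = []
    for condition, sub in spikes.groupby("condition", sort=True):
        for key, train in iter_units(sub, protocol.n_repeats):
            psth = compute_psth(train, protocol, config.bin_width_s, t_range)
            baseline = compute_baseline(train, protocol, config.bin_width_s)
            outcomes = detect_window_outcomes(psth, baseline, windows, config)
            cls = classify_unit(outcomes)
            rows.append(
                (
                    *key, str(condition), cls.value,
                    outcomes["on"].state.value,
                    outcomes["off"].state.value,
                    outcomes["sustained"].state.value,
                    baseline.mean_hz, baseline.sd_hz,
                    outcomes["on"].degenerate_baseline,
                    train.n_spikes,
                )
            )
    frame = pd.DataFrame(rows, columns=list(CLASSIFICATION_COLUMNS))
    return frame.sort_values(
        ["condition", "retina_id", "channel", "unit_id"], ignore_index=True
    )
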