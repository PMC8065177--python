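"""Response amplitude, latency-to-peak, and irradiance sensitivity.

Latency is measured on the smoothed 10-ms PSTH as the time from the
relevant stimulus edge (onset for ON components, offset for OFF components)
to the peak rate within the component's window; amplitude on the 100-ms
PSTH as the change in rate between the edge bin and the window peak. Only
peak-seeking classes receive component metrics: ON components for ON,
ON-suppressed-by-dark and ON-OFF units; OFF components for OFF,
OFF-suppressed-by-light and ON-OFF units.

Sensitivity curves report the change in rate over the first 400 ms of the
flash relative to that block's own pre-stimulus baseline, at each of six
irradiance levels. A unit enters the analysis only if its response at the
highest irradiance exceeds baseline mean + 3 SD; the lower levels are then
used regardless of significance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classification import ResponseClass, ResponseWindows, define_windows
from .config import RunConfig, StimulusProtocol
from .psth import (
    PSTH,
    BaselineStats,
    compute_baseline,
    compute_fine_psth,
    compute_psth,
    default_range,
)
from .spikes import SpikeTrain

__all__ = [
    "ComponentMetrics",
    "SensitivityCurve",
    "assign_components",
    "component_latency",
    "component_amplitude",
    "unit_metrics",
    "sensitivity_curve",
]

_ON_CLASSES = frozenset(
    {ResponseClass.ON, ResponseClass.ON_SUPPRESSED_BY_DARK, ResponseClass.ON_OFF}
)
_OFF_CLASSES = frozenset(
    {ResponseClass.OFF, ResponseClass.OFF_SUPPRESSED_BY_LIGHT, ResponseClass.ON_OFF}
)


@dataclass(frozen=True)
class ComponentMetrics:
    component: str  # "ON" | "OFF"
    amplitude_hz: float
    latency_s: float


@dataclass(frozen=True)
class SensitivityCurve:
    """Delta firing rate vs irradiance for one unit.

    ``included`` is decided solely at the highest irradiance level.
    """

    irradiance: tuple[float, ...]
    delta_rate_hz: tuple[float, ...]
    included: bool

    def __post_init__(self) -> None:
        if len(self.irradiance) != len(self.delta_rate_hz):
            raise ValueError("irradiance and delta_rate_hz lengths differ")


def assign_components(cls: ResponseClass) -> frozenset[str]:
    """Which components ("ON", "OFF") to measure for a response class."""
    cls = ResponseClass(cls)
    out = set()
    if cls in _ON_CLASSES:
        out.add("ON")
    if cls in _OFF_CLASSES:
        out.add("OFF")
    return frozenset(out)


def component_latency(
    fine_psth: PSTH,
    edge_time_s: float,
    window: tuple[float, float],
) -> float:
    """Time from a stimulus edge to the peak of the smoothed PSTH.

    Returns the argmax bin center within ``(window_start, window_end]``
    minus the edge time; ties break to the earliest bin. A flat window has
    no peak and returns NaN.
    """
    sl = fine_psth.window_slice(*window)
    rates = fine_psth.rate_hz[sl]
    if rates.size == 0:
        raise ValueError("fine PSTH does not cover the component window")
    if np.allclose(rates, rates[0]):
        return math.nan
    centers = fine_psth.bin_centers_s[sl]
    return float(centers[int(np.argmax(rates))] - edge_time_s)


def component_amplitude(
    psth: PSTH,
    baseline: BaselineStats,
    edge_time_s: float,
    window: tuple[float, float],
    reference: str = "edge",
) -> float:
    """Change in rate between the stimulus edge and the window peak (100-ms PSTH).

    ``reference="edge"`` subtracts the rate of the bin containing the edge;
    ``reference="baseline"`` subtracts the baseline mean instead. Clipped at
    zero: a window whose maximum sits at the edge has no excursion.
    """
    sl = psth.window_slice(*window)
    rates = psth.rate_hz[sl]
    if rates.size == 0:
        raise ValueError("PSTH does not cover the component window")
    if reference == "edge":
        edge_bin = int(np.floor((edge_time_s - psth.bin_edges_s[0]) / psth.bin_width_s))
        if not 0 <= edge_bin < len(psth.rate_hz):
            raise ValueError("edge time outside PSTH range")
        ref = float(psth.rate_hz[edge_bin])
    elif reference == "baseline":
        ref = baseline.mean_hz
    else:
        raise ValueError("reference must be 'edge' or 'baseline'")
    return max(0.0, float(rates.max()) - ref)


def unit_metrics(
    train: SpikeTrain,
    cls: ResponseClass,
    protocol: StimulusProtocol,
    config: RunConfig | None = None,
) -> list[ComponentMetrics]:
    """Latency and amplitude for every component the unit's class carries."""
    config = config or RunConfig()
    components = assign_components(cls)
    if not components:
        return []
    windows = define_windows(protocol, config)
    t_range = default_range(protocol, config)
    coarse = compute_psth(train, protocol, config.bin_width_s, t_range)
    fine = compute_fine_psth(train, protocol, config, t_range)
    baseline = compute_baseline(train, protocol, config.bin_width_s)
    d = protocol.stim_duration_s
    out = []
    for comp in sorted(components):
        if comp == "ON":
            edge, window = 0.0, windows.on
        else:
            edge, window = d, windows.off
        out.append(
            ComponentMetrics(
                component=comp,
                amplitude_hz=component_amplitude(
                    coarse, baseline, edge, window, config.amplitude_reference
                ),
                latency_s=component_latency(fine, edge, window),
            )
        )
    return out


def metrics_table(
    spikes: pd.DataFrame,
    classifications: pd.DataFrame,
    protocol: StimulusProtocol,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Per-(unit, component) metrics for a classified population.

    Emits one row per measured component; ON-OFF units contribute two rows.
    Pooling across units is left to reporting.
    """
    config = config or RunConfig()
    rows = []
    for _, rec in classifications.iterrows():
        cls = ResponseClass(rec["response_class"])
        if not assign_components(cls):
            continue
        mask = (
            (spikes["retina_id"].astype(str) == rec["retina_id"])
            & (spikes["channel"].astype(str) == rec["channel"])
            & (spikes["unit_id"].astype(str) == rec["unit_id"])
            & (spikes["condition"].astype(str) == rec["condition"])
        )
        train = SpikeTrain.from_frame(spikes[mask], protocol.n_repeats)
        for m in unit_metrics(train, cls, protocol, config):
            rows.append(
                (
                    rec["retina_id"], rec["channel"], rec["unit_id"],
                    rec["condition"], cls.value, m.component,
                    m.amplitude_hz, m.latency_s * 1e3,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "retina_id", "channel", "unit_id", "condition", "response_class",
            "component", "amplitude_hz", "latency_ms",
        ],
    )


def sensitivity_curve(
    trains_by_level: dict[float, SpikeTrain] | list[SpikeTrain],
    protocol: StimulusProtocol,
    config: RunConfig | None = None,
) -> SensitivityCurve:
    """Irradiance-response curve with the top-level inclusion filter.

    ``trains_by_level`` maps each irradiance in ``protocol.irradiance_levels``
    to that block's spike train (a list in level order is also accepted).
    Each block uses its own pre-stimulus baseline, which absorbs slow drift
    across the ~40-minute series.
    """
    config = config or RunConfig()
    levels = protocol.irradiance_levels
    if isinstance(trains_by_level, dict):
        missing = [lv for lv in levels if lv not in trains_by_level]
        if missing:
            raise ValueError(f"missing irradiance blocks: {missing}")
        trains = [trains_by_level[lv] for lv in levels]
    else:
        trains = list(trains_by_level)
        if len(trains) != len(levels):
            raise ValueError(
                f"got {len(trains)} blocks for {len(levels)} irradiance levels"
            )
    deltas = []
    included = False
    for i, (lv, train) in enumerate(zip(levels, trains)):
        baseline = compute_baseline(train, protocol, config.bin_width_s)
        psth = compute_psth(
            train, protocol, config.bin_width_s,
            t_range=(0.0, protocol.stim_duration_s),
        )
        sl = psth.window_slice(0.0, config.sensitivity_window_s)
        early_rate = float(psth.rate_hz[sl].mean())
        deltas.append(early_rate - baseline.mean_hz)
        if i == len(levels) - 1:
            included = early_rate > baseline.mean_hz + 3.0 * baseline.sd_hz
    return SensitivityCurve(
        irradiance=tuple(levels),
        delta_rate_hz=tuple(deltas),
        included=included,
    )
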