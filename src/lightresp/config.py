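"""Run configuration and stimulus protocol definitions.

All times are in seconds and all rates in spikes/s unless a field name says
otherwise. The stimulus convention throughout the package is trial-relative
time with light onset at t = 0, so the pre-stimulus baseline occupies
negative times.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np

__all__ = ["StimulusProtocol", "RunConfig", "DEFAULT_IRRADIANCE"]

#: Irradiance at the retinal surface for the single-intensity flash protocol,
#: in photons cm^-2 s^-1.
DEFAULT_IRRADIANCE = 4.21e15


@dataclass(frozen=True)
class StimulusProtocol:
    """Full-field flash protocol: 1-s steps from darkness, 20 s apart, x20.

    Parameters
    ----------
    stim_duration_s
        Duration of the light step (the ON period).
    isi_s
        Interstimulus interval; must cover the baseline window.
    n_repeats
        Number of stimulus repeats (trials) per block.
    irradiance_levels
        Ordered photon flux per block, photons cm^-2 s^-1. Length 1 for the
        plain flash protocol, 6 for the sensitivity series.
    baseline_window_s
        Span of pre-stimulus time used for the baseline estimate.
    """

    stim_duration_s: float = 1.0
    isi_s: float = 20.0
    n_repeats: int = 20
    irradiance_levels: tuple[float, ...] = (DEFAULT_IRRADIANCE,)
    baseline_window_s: float = 10.0

    def __post_init__(self) -> None:
        if not self.stim_duration_s > 0:
            raise ValueError("stim_duration_s must be > 0")
        if self.isi_s < self.baseline_window_s:
            raise ValueError(
                f"isi_s ({self.isi_s}) must be >= baseline_window_s "
                f"({self.baseline_window_s}): the baseline is carved out of "
                "the interstimulus interval"
            )
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        levels = tuple(float(v) for v in self.irradiance_levels)
        if len(levels) not in (1, 6):
            raise ValueError("irradiance_levels must have length 1 or 6")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("irradiance_levels must be strictly increasing")
        object.__setattr__(self, "irradiance_levels", levels)


@dataclass(frozen=True)
class RunConfig:
    """Analysis constants for PSTH construction, thresholding and behavior.

    Defaults implement the standard analysis: 100 ms PSTH bins, baseline
    over the 10 s preceding onset, response detection at baseline +3 SD
    sustained for >= 100 ms (increases) or baseline -1 SD for >= 300 ms
    (decreases), a sustained window six stimulus-durations long, a 400 ms
    integration window for irradiance sensitivity, and a 20 s rendering cap
    for occupancy heatmaps.
    """

    bin_width_s: float = 0.1
    fine_bin_width_s: float = 0.01
    up_threshold_sd: float = 3.0
    down_threshold_sd: float = 1.0
    up_duration_s: float = 0.1
    down_duration_s: float = 0.3
    sustained_multiplier: float = 6.0
    sensitivity_window_s: float = 0.4
    heatmap_cap_s: float = 20.0
    #: Gaussian smoothing sigma for the fine (10 ms) PSTH, seconds.
    smoothing_sigma_s: float = 0.02
    #: Reference for response amplitude: "edge" (rate in the bin containing
    #: the stimulus edge) or "baseline" (baseline mean rate).
    amplitude_reference: str = "edge"
    #: Require threshold crossings to be contiguous bins (True) or merely to
    #: accumulate enough total time above threshold within the window (False).
    contiguous_runs: bool = True
    #: Penetration depth past the divider required to register a compartment
    #: change in the light-avoidance arena, cm.
    hysteresis_cm: float = 2.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "bin_width_s", "fine_bin_width_s", "up_duration_s",
            "down_duration_s", "sensitivity_window_s", "heatmap_cap_s",
            "smoothing_sigma_s", "sustained_multiplier",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("up_threshold_sd", "down_threshold_sd"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.amplitude_reference not in ("edge", "baseline"):
            raise ValueError("amplitude_reference must be 'edge' or 'baseline'")

    def replace(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        """Build a config from a flat key/value mapping (e.g. a parsed file)."""
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for key, value in mapping.items():
            if key == "amplitude_reference":
                kwargs[key] = str(value)
            elif key == "contiguous_runs":
                kwargs[key] = _parse_bool(value)
            elif key == "rng_seed":
                kwargs[key] = None if value in (None, "", "none") else int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot parse boolean from {value!r}")
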