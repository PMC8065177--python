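"""Synthetic spike trains, sensitivity series, blockade blocks and tracks.

Every analysis stage in the package can be exercised without recorded data:
this module draws inhomogeneous-Poisson spike trains from archetypal rate
profiles matching the 10 light-response classes, builds the six-irradiance
sensitivity series, emulates pharmacological blockade (synaptic blockers
abolish photoreceptor-driven responses, sparing the slow melanopsin-style
intrinsic ones), and generates biased random-walk tracks through a
two-compartment arena.

Rate profiles are sums of a stationary baseline and class-shaped
modulations: fast transients (linear rise to a peak at the component
latency, exponential decay), plateaus spanning the light step, rectangular
suppressions of the baseline, and a slow melanopsin-style envelope (rise
over ~1 s, decay over ~10 s after offset). Spikes are drawn per trial from
a 1-ms discretization of the profile, which is exactly Poisson in every
analysis window at that resolution. All generators are deterministic given
their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .behavior import ArenaConfig, TrackingSession
from .classification import ResponseClass
from .config import RunConfig, StimulusProtocol
from .spikes import SPIKE_COLUMNS, SpikeTrain

__all__ = [
    "UnitArchetypeSpec",
    "PopulationSpec",
    "default_archetype",
    "rate_profile",
    "simulate_unit",
    "simulate_retina",
    "simulate_blockade_experiment",
    "simulate_sensitivity_series",
    "simulate_track",
]

#: Simulation grid step, seconds. 1 ms keeps the discretized profile
#: faithful for the fastest transients used here.
SIM_DT_S = 0.001

_SUPPRESSION_CLASSES = {
    ResponseClass.ON_SUPPRESSED_BY_DARK,
    ResponseClass.OFF_SUPPRESSED_BY_LIGHT,
    ResponseClass.SUPPRESSED_ON,
    ResponseClass.SUPPRESSED_OFF,
    ResponseClass.SUPPRESSED_ON_OFF,
}


@dataclass(frozen=True)
class UnitArchetypeSpec:
    """Generating parameters for one unit archetype.

    ``amplitude_hz`` is the peak rate excursion of excitatory components;
    ``suppression_depth`` the fraction of baseline removed during
    suppressive epochs. ``blockade_sensitive`` units lose all light-driven
    modulation under the blockade condition (photoreceptor-driven);
    insensitive units model intrinsically photosensitive ganglion cells.
    """

    label: ResponseClass
    baseline_hz: float = 5.0
    amplitude_hz: float = 15.0
    on_latency_s: float = 0.32
    off_latency_s: float = 0.35
    tau_s: float = 0.15
    rise_s: float = 0.1
    suppression_depth: float = 1.0
    suppression_duration_s: float = 0.6
    slow_rise_tau_s: float = 1.0
    slow_decay_tau_s: float = 10.0
    gain_profile: tuple[float, ...] | None = None
    blockade_sensitive: bool = True

    def __post_init__(self) -> None:
        if self.baseline_hz < 0 or self.amplitude_hz < 0:
            raise ValueError("rates must be >= 0")
        if not 0 <= self.suppression_depth <= 1:
            raise ValueError("suppression_depth must be in [0, 1]")


@dataclass(frozen=True)
class PopulationSpec:
    """Per-class unit counts plus the protocol and a mandatory seed."""

    counts: dict
    protocol: StimulusProtocol = StimulusProtocol()
    seed: int = 0
    retina_id: str = "r0"
    #: optional per-class archetype overrides
    archetypes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, n in self.counts.items():
            ResponseClass(label)
            if n < 0:
                raise ValueError("unit counts must be >= 0")


def default_archetype(label: ResponseClass | str, **overrides) -> UnitArchetypeSpec:
    """Archetype with field defaults tuned per class.

    Classes with suppressive components get a 20 Hz baseline (a decrease can
    only be seen against sustained firing); excitatory and silent classes
    use 5 Hz. The slow-sustained archetype carries melanopsin-style kinetics
    and survives synaptic blockade.
    """
    label = ResponseClass(label)
    kwargs: dict = {"label": label}
    if label in _SUPPRESSION_CLASSES:
        kwargs["baseline_hz"] = 20.0
    if label is ResponseClass.SLOW_SUSTAINED:
        kwargs["blockade_sensitive"] = False
    if label is ResponseClass.NON_LIGHT_RESPONSIVE:
        kwargs["amplitude_hz"] = 0.0
    kwargs.update(overrides)
    return UnitArchetypeSpec(**kwargs)


def _transient(t: np.ndarray, edge_s: float, latency_s: float, amp: float,
               tau_s: float, rise_s: float) -> np.ndarray:
    """Linear rise to ``amp`` at edge+latency, exponential decay after."""
    peak_t = edge_s + latency_s
    out = np.zeros_like(t)
    rising = (t > peak_t - rise_s) & (t <= peak_t)
    out[rising] = amp * (t[rising] - (peak_t - rise_s)) / rise_s
    decaying = t > peak_t
    out[decaying] = amp * np.exp(-(t[decaying] - peak_t) / tau_s)
    return out


def _plateau(t: np.ndarray, start_s: float, end_s: float, amp: float,
             rise_s: float) -> np.ndarray:
    """Quick rise at start, hold at ``amp``, hard stop at end."""
    out = np.zeros_like(t)
    rising = (t > start_s) & (t <= start_s + rise_s)
    out[rising] = amp * (t[rising] - start_s) / rise_s
    hold = (t > start_s + rise_s) & (t <= end_s)
    out[hold] = amp
    return out


def _suppression(t: np.ndarray, start_s: float, end_s: float,
                 baseline: float, depth: float) -> np.ndarray:
    out = np.zeros_like(t)
    out[(t > start_s) & (t <= end_s)] = -depth * baseline
    return out


def _slow_envelope(t: np.ndarray, d: float, amp: float,
                   rise_tau: float, decay_tau: float) -> np.ndarray:
    """Melanopsin-style: saturating rise during the step, slow decay after."""
    out = np.zeros_like(t)
    during = (t > 0) & (t <= d)
    out[during] = amp * (1.0 - np.exp(-t[during] / rise_tau))
    level_at_off = amp * (1.0 - np.exp(-d / rise_tau))
    after = t > d
    out[after] = level_at_off * np.exp(-(t[after] - d) / decay_tau)
    return out


def rate_profile(
    spec: UnitArchetypeSpec,
    protocol: StimulusProtocol,
    t: np.ndarray,
    amplitude_scale: float = 1.0,
) -> np.ndarray:
    """Generating rate lambda(t) in spikes/s on the given time grid.

    ``amplitude_scale`` scales all light-driven modulation (0 under
    blockade for sensitive units; the irradiance gain for sensitivity
    series). Negative rates are clipped at zero with a warning.
    """
    t = np.asarray(t, dtype=float)
    d = protocol.stim_duration_s
    b = spec.baseline_hz
    a = spec.amplitude_hz * amplitude_scale
    depth = spec.suppression_depth * amplitude_scale
    sup_d = spec.suppression_duration_s
    label = spec.label
    mod = np.zeros_like(t)
    if label is ResponseClass.ON:
        mod += _transient(t, 0.0, spec.on_latency_s, a, spec.tau_s, spec.rise_s)
    elif label is ResponseClass.ON_SUPPRESSED_BY_DARK:
        mod += _plateau(t, 0.0, d, a, spec.rise_s)
        mod += _suppression(t, d, d + sup_d, b, depth)
    elif label is ResponseClass.ON_OFF:
        mod += _transient(t, 0.0, spec.on_latency_s, a, spec.tau_s, spec.rise_s)
        mod += _transient(t, d, spec.off_latency_s, a, spec.tau_s, spec.rise_s)
    elif label is ResponseClass.SLOW_SUSTAINED:
        mod += _slow_envelope(t, d, a, spec.slow_rise_tau_s, spec.slow_decay_tau_s)
    elif label is ResponseClass.OFF:
        mod += _transient(t, d, spec.off_latency_s, a, spec.tau_s, spec.rise_s)
    elif label is ResponseClass.OFF_SUPPRESSED_BY_LIGHT:
        mod += _suppression(t, 0.0, d, b, depth)
        mod += _transient(t, d, spec.off_latency_s, a, spec.tau_s, spec.rise_s)
    elif label is ResponseClass.SUPPRESSED_ON:
        mod += _suppression(t, 0.0, sup_d, b, depth)
    elif label is ResponseClass.SUPPRESSED_OFF:
        mod += _suppression(t, d, d + sup_d, b, depth)
    elif label is ResponseClass.SUPPRESSED_ON_OFF:
        mod += _suppression(t, 0.0, sup_d, b, depth)
        mod += _suppression(t, d, d + sup_d, b, depth)
    elif label is ResponseClass.NON_LIGHT_RESPONSIVE:
        pass
    lam = b + mod
    if np.any(lam < -1e-9):
        warnings.warn("negative generating rate clipped at 0")
    return np.clip(lam, 0.0, None)


def simulate_unit(
    spec: UnitArchetypeSpec,
    protocol: StimulusProtocol,
    seed: int | np.random.Generator,
    t_range: tuple[float, float] = (-10.0, 8.0),
    amplitude_scale: float = 1.0,
    dt_s: float = SIM_DT_S,
) -> SpikeTrain:
    """Draw one unit's spikes: independent inhomogeneous-Poisson trials."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_start, t_end = t_range
    n_steps = int(round((t_end - t_start) / dt_s))
    centers = t_start + dt_s * (np.arange(n_steps) + 0.5)
    lam = rate_profile(spec, protocol, centers, amplitude_scale)
    counts = rng.poisson(lam * dt_s, size=(protocol.n_repeats, n_steps))
    trials = []
    for row in counts:
        idx = np.flatnonzero(row)
        if idx.size == 0:
            trials.append(np.empty(0))
            continue
        reps = row[idx]
        times = np.repeat(centers[idx], reps)
        times = times + rng.uniform(-dt_s / 2, dt_s / 2, size=times.size)
        trials.append(np.sort(times))
    return SpikeTrain(trials=trials)


def _units_frame(trains: list[SpikeTrain]) -> pd.DataFrame:
    frames = [t.to_frame() for t in trains if t.n_spikes > 0]
    if not frames:
        return pd.DataFrame(columns=list(SPIKE_COLUMNS))
    return pd.concat(frames, ignore_index=True)


def simulate_retina(
    pop: PopulationSpec,
    condition: str = "none",
    amplitude_scale: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a whole retina; returns (spike table, ground-truth table).

    The truth table has one row per unit with its generating class, for
    recovery tests downstream. Units are spread over mock channels, 4 per
    channel, purely as plausible identifiers.
    """
    rng = np.random.default_rng(pop.seed)
    trains: list[SpikeTrain] = []
    truth_rows = []
    unit_no = 0
    for label in sorted(pop.counts, key=lambda l: ResponseClass(l).value):
        n = pop.counts[label]
        spec = pop.archetypes.get(label) or default_archetype(label)
        for _ in range(n):
            train = simulate_unit(spec, pop.protocol, rng, amplitude_scale=amplitude_scale)
            train.retina_id = pop.retina_id
            train.channel = f"ch{unit_no // 4:03d}"
            train.unit_id = f"u{unit_no:04d}"
            train.condition = condition
            trains.append(train)
            truth_rows.append(
                (pop.retina_id, train.channel, train.unit_id, condition,
                 ResponseClass(label).value, spec.baseline_hz, spec.amplitude_hz)
            )
            unit_no += 1
    truth = pd.DataFrame(
        truth_rows,
        columns=["retina_id", "channel", "unit_id", "condition",
                 "true_class", "baseline_hz", "amplitude_hz"],
    )
    return _units_frame(trains), truth


def simulate_blockade_experiment(
    pop: PopulationSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pre-drug / blockade / washout recording blocks for one retina.

    Under blockade, units whose archetype is ``blockade_sensitive`` (the
    photoreceptor-driven classes) fall back to bare baseline firing; the
    melanopsin-style slow-sustained archetype keeps its response. Washout
    restores every response. Spikes are drawn independently per block.
    """
    frames = []
    truths = []
    for i, condition in enumerate(("pre_drug", "blockade", "washout")):
        sub = replace(pop, seed=pop.seed + i)
        specs = {
            label: (pop.archetypes.get(label) or default_archetype(label))
            for label in pop.counts
        }
        if condition == "blockade":
            scales = {
                label: (0.0 if spec.blockade_sensitive else 1.0)
                for label, spec in specs.items()
            }
            # per-class scaling needs separate draws; simulate class by class
            part_frames = []
            part_truths = []
            unit_offset = 0
            rng_seed = sub.seed
            for label in sorted(pop.counts, key=lambda l: ResponseClass(l).value):
                single = PopulationSpec(
                    counts={label: pop.counts[label]},
                    protocol=pop.protocol,
                    seed=rng_seed + unit_offset,
                    retina_id=pop.retina_id,
                    archetypes=pop.archetypes,
                )
                spikes, truth = simulate_retina(
                    single, condition, amplitude_scale=scales[label]
                )
                # renumber units to keep identities unique across classes
                mapping = {
                    u: f"u{unit_offset + k:04d}"
                    for k, u in enumerate(truth["unit_id"])
                }
                chmap = {
                    u: f"ch{(unit_offset + k) // 4:03d}"
                    for k, u in enumerate(truth["unit_id"])
                }
                if not spikes.empty:
                    spikes["channel"] = spikes["unit_id"].map(chmap)
                    spikes["unit_id"] = spikes["unit_id"].map(mapping)
                truth["channel"] = truth["unit_id"].map(chmap)
                truth["unit_id"] = truth["unit_id"].map(mapping)
                part_frames.append(spikes)
                part_truths.append(truth)
                unit_offset += pop.counts[label]
            frames.append(pd.concat(part_frames, ignore_index=True))
            truths.append(pd.concat(part_truths, ignore_index=True))
        else:
            spikes, truth = simulate_retina(sub, condition)
            frames.append(spikes)
            truths.append(truth)
    return (
        pd.concat(frames, ignore_index=True),
        pd.concat(truths, ignore_index=True),
    )


def simulate_sensitivity_series(
    spec: UnitArchetypeSpec,
    protocol: StimulusProtocol,
    seed: int,
) -> dict[float, SpikeTrain]:
    """One spike train per irradiance level, lowest level first.

    The light-driven modulation at level i is a rate step over the full
    light pulse of height ``gain_profile[i]`` (spikes/s); the archetype's
    waveform shape is bypassed so the generating delta-rate over the first
    400 ms equals the gain exactly. Each block has its own baseline epochs.
    """
    levels = protocol.irradiance_levels
    if len(levels) != 6:
        raise ValueError("sensitivity series needs a 6-level protocol")
    gains = spec.gain_profile
    if gains is None or len(gains) != 6:
        raise ValueError("archetype must define a 6-entry gain_profile")
    rng = np.random.default_rng(seed)
    d = protocol.stim_duration_s
    out = {}
    for level, gain in zip(levels, gains):
        step_spec = replace(
            spec,
            label=ResponseClass.ON_SUPPRESSED_BY_DARK,  # plateau shape
            amplitude_hz=float(gain),
            suppression_depth=0.0,
            rise_s=1e-6,
        )
        out[level] = simulate_unit(
            step_spec, protocol, rng, t_range=(-protocol.baseline_window_s, 2.0 * d)
        )
    return out


def simulate_track(
    dark_preference: float,
    arena: ArenaConfig | None = None,
    duration_s: float = 600.0,
    seed: int = 0,
    dt_s: float = 0.1,
    speed_cm_s: float = 8.0,
    goal_dwell_s: float = 5.0,
) -> tuple[TrackingSession, dict]:
    """Biased random walk in the two-compartment arena.

    The walker pursues a goal point resampled every ``goal_dwell_s``; the
    goal lands in the dark compartment with probability ``dark_preference``.
    Divider crossings are only possible through the aperture; elsewhere the
    divider is a wall. Starts in the light compartment near the aperture
    (the test protocol's starting placement). Returns the session plus a
    truth dict with the realized dark-side occupancy fraction.
    """
    if not 0.0 <= dark_preference <= 1.0:
        raise ValueError("dark_preference must be in [0, 1]")
    arena = arena or ArenaConfig()
    rng = np.random.default_rng(seed)
    n = int(round(duration_s / dt_s)) + 1
    div = arena.divider_x_cm
    ap_lo = arena.aperture_center_y_cm - arena.aperture_span_cm / 2
    ap_hi = arena.aperture_center_y_cm + arena.aperture_span_cm / 2

    def sample_goal() -> np.ndarray:
        if rng.random() < dark_preference:
            x = rng.uniform(div + 4.0, arena.width_cm - 3.0)
        else:
            x = rng.uniform(3.0, div - 4.0)
        return np.array([x, rng.uniform(3.0, arena.depth_cm - 3.0)])

    pos = np.array([div - 4.0, arena.aperture_center_y_cm])
    goal = sample_goal()
    resample_every = max(1, int(round(goal_dwell_s / dt_s)))
    xs = np.empty(n)
    ys = np.empty(n)
    step = speed_cm_s * dt_s
    for i in range(n):
        xs[i], ys[i] = pos
        if i % resample_every == 0 and i > 0:
            goal = sample_goal()
        direction = goal - pos
        dist = np.hypot(*direction)
        if dist < 1.0:
            goal = sample_goal()
            direction = goal - pos
            dist = np.hypot(*direction)
        drift = direction / max(dist, 1e-9)
        proposal = pos + step * drift + rng.normal(0.0, 0.6 * step, size=2)
        # the divider is a wall except at the aperture: a proposal that
        # changes side must pass through the aperture's span
        if (pos[0] - div) * (proposal[0] - div) < 0:
            frac = (div - pos[0]) / (proposal[0] - pos[0])
            y_at_div = pos[1] + frac * (proposal[1] - pos[1])
            if not (ap_lo <= y_at_div <= ap_hi):
                side = -1.0 if pos[0] < div else 1.0
                proposal[0] = div + side * 0.5
        proposal[0] = np.clip(proposal[0], 0.2, arena.width_cm - 0.2)
        proposal[1] = np.clip(proposal[1], 0.2, arena.depth_cm - 0.2)
        pos = proposal
    t = dt_s * np.arange(n)
    session = TrackingSession(t_s=t, x_cm=xs, y_cm=ys)
    # realized occupancy truth: midpoint-weighted time on the dark side of
    # the divider, without hysteresis
    mids = 0.5 * (t[:-1] + t[1:])
    bounds = np.concatenate([[t[0]], mids, [t[-1]]])
    weights = np.diff(bounds)
    dark_frac = float(weights[xs > div].sum() / (t[-1] - t[0]))
    return session, {"realized_dark_fraction": dark_frac}
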