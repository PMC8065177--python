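"""Figure helpers: PSTHs, class distributions, tracking plots, heatmaps.

Thin matplotlib wrappers; every function takes/returns an Axes so figures
compose. Heatmap rendering applies the 20 s occupancy cap; the underlying
grids keep raw values.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .behavior import ArenaConfig, TrackingSession
from .psth import PSTH

__all__ = ["plot_psth", "plot_class_distribution", "plot_track", "plot_heatmap"]


def plot_psth(psth: PSTH, ax=None, stim_duration_s: float = 1.0, **kwargs):
    """Step plot of a PSTH with SEM shading and the light step marked."""
    ax = ax or plt.gca()
    centers = psth.bin_centers_s
    ax.fill_between(
        centers,
        psth.rate_hz - psth.rate_sem_hz,
        psth.rate_hz + psth.rate_sem_hz,
        alpha=0.3,
        linewidth=0,
    )
    ax.plot(centers, psth.rate_hz, drawstyle="steps-mid", **kwargs)
    ax.axvspan(0.0, stim_duration_s, color="gold", alpha=0.2)
    ax.set_xlabel("time from light onset (s)")
    ax.set_ylabel("firing rate (spikes/s)")
    return ax


def plot_class_distribution(summary_row, ax=None, as_pct_of_responsive: bool = False):
    """Bar chart of per-class unit percentages from one retina summary row."""
    ax = ax or plt.gca()
    pct_cols = [c for c in summary_row.index if c.startswith("pct_") and c != "pct_light_responsive"]
    labels = [c[4:] for c in pct_cols]
    values = np.array([summary_row[c] for c in pct_cols], dtype=float)
    if as_pct_of_responsive:
        keep = [i for i, l in enumerate(labels) if l != "NON_LIGHT_RESPONSIVE"]
        labels = [labels[i] for i in keep]
        values = values[keep]
        total = values.sum()
        if total > 0:
            values = 100.0 * values / total
    ax.bar(range(len(values)), values)
    ax.set_xticks(range(len(values)))
    ax.set_xticklabels(labels, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("% of units")
    return ax


def plot_track(session: TrackingSession, arena: ArenaConfig, ax=None):
    """Path plot with start (blue) and end (red) markers and the divider."""
    ax = ax or plt.gca()
    ax.plot(session.x_cm, session.y_cm, lw=0.5, color="gray")
    ax.plot(session.x_cm[0], session.y_cm[0], "o", color="blue", label="start")
    ax.plot(session.x_cm[-1], session.y_cm[-1], "o", color="red", label="end")
    ax.axvline(arena.divider_x_cm, color="black", lw=1)
    ax.set_xlim(0, arena.width_cm)
    ax.set_ylim(0, arena.depth_cm)
    ax.set_aspect("equal")
    return ax


def plot_heatmap(heatmap: dict, ax=None, cap_s: float = 20.0):
    """Render the occupancy grid, saturating at the configured cap."""
    ax = ax or plt.gca()
    render = np.minimum(heatmap["raw"], cap_s)
    im = ax.pcolormesh(
        heatmap["x_edges"], heatmap["y_edges"], render.T,
        cmap="jet", vmin=0.0, vmax=cap_s,
    )
    ax.set_aspect("equal")
    return im
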