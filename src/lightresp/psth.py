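"""Peristimulus time histograms and baseline statistics.

The PSTH is the trial-averaged firing rate: rate in bin b equals the total
spike count in b across trials divided by (n_trials x bin_width). Bins are
half-open ``[left, right)``, so a spike exactly at stimulus onset (t = 0)
falls in the first ON bin. The default analysis range is [-10 s, +8 s],
covering the 10 s baseline and the ON/OFF/Sustained windows of a 1-s flash.

The baseline is the mean rate over the 10 s preceding onset; its SD is
taken across the baseline-window bins of the trial-averaged PSTH, because
the response thresholds are applied to that same trial-averaged object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .config import RunConfig, StimulusProtocol
from .spikes import SpikeTrain

__all__ = [
    "PSTH",
    "BaselineStats",
    "default_range",
    "compute_psth",
    "compute_baseline",
    "compute_fine_psth",
    "trial_average_waveform",
]


@dataclass(frozen=True)
class PSTH:
    """Trial-averaged firing-rate histogram.

    ``rate_hz[b]`` is the mean rate in ``[bin_edges_s[b], bin_edges_s[b+1])``
    across trials; ``rate_sem_hz`` the across-trial SEM of the same bin.
    """

    bin_edges_s: np.ndarray
    rate_hz: np.ndarray
    rate_sem_hz: np.ndarray
    n_trials: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_edges_s", np.asarray(self.bin_edges_s, dtype=float))
        object.__setattr__(self, "rate_hz", np.asarray(self.rate_hz, dtype=float))
        object.__setattr__(self, "rate_sem_hz", np.asarray(self.rate_sem_hz, dtype=float))
        if len(self.rate_hz) != len(self.bin_edges_s) - 1:
            raise ValueError("rate_hz length must be len(bin_edges_s) - 1")
        if np.any(self.rate_hz < -1e-12):
            raise ValueError("negative firing rate in PSTH")

    @property
    def bin_width_s(self) -> float:
        return float(self.bin_edges_s[1] - self.bin_edges_s[0])

    @property
    def bin_centers_s(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_s[:-1] + self.bin_edges_s[1:])

    def window_slice(self, t_start: float, t_end: float) -> slice:
        """Bins whose left edge lies in [t_start, t_end).

        With half-open bins this selects exactly the bins tiling the window
        ``(t_start, t_end]`` under the onset-in-first-bin convention.
        """
        left = self.bin_edges_s[:-1]
        idx = np.flatnonzero((left >= t_start - 1e-9) & (left < t_end - 1e-9))
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def total_spikes(self) -> float:
        """Spike count implied by the histogram (exact by construction)."""
        return float(np.sum(self.rate_hz) * self.bin_width_s * self.n_trials)


@dataclass(frozen=True)
class BaselineStats:
    """Pre-stimulus firing statistics of one unit.

    ``mean_hz`` is the average rate over the baseline window; ``sd_hz`` the
    SD across the 100-ms bins of the trial-averaged PSTH within that window.
    """

    mean_hz: float
    sd_hz: float
    window_s: float

    def __post_init__(self) -> None:
        if self.sd_hz < 0:
            raise ValueError("sd_hz must be >= 0")


def default_range(protocol: StimulusProtocol, config: RunConfig) -> tuple[float, float]:
    """Analysis range covering baseline, ON, OFF and Sustained windows."""
    d = protocol.stim_duration_s
    t_end = d * (2.0 + config.sustained_multiplier)
    return (-protocol.baseline_window_s, t_end)


def compute_psth(
    train: SpikeTrain,
    protocol: StimulusProtocol,
    bin_width_s: float = 0.1,
    t_range: tuple[float, float] | None = None,
) -> PSTH:
    """Histogram a unit's spikes into a trial-averaged rate.

    Spikes outside ``t_range`` are excluded from the histogram (they remain
    in the input). Raises on a unit with zero trials.
    """
    if bin_width_s <= 0:
        raise ValueError("bin_width_s must be > 0")
    if train.n_trials == 0:
        raise ValueError("unit has zero trials")
    if t_range is None:
        t_range = default_range(protocol, RunConfig())
    t_start, t_end = t_range
    n_bins = int(round((t_end - t_start) / bin_width_s))
    if n_bins < 1:
        raise ValueError("t_range shorter than one bin")
    edges = t_start + bin_width_s * np.arange(n_bins + 1)
    counts = np.zeros((train.n_trials, n_bins))
    for i, times in enumerate(train.trials):
        if times.size:
            # right-open bins: searchsorted 'right' on left edges - epsilon is
            # equivalent to floor((t - t_start)/width); clip out-of-range
            idx = np.floor((times - t_start) / bin_width_s).astype(int)
            ok = (idx >= 0) & (idx < n_bins) & (times < t_end)
            if ok.any():
                np.add.at(counts[i], idx[ok], 1.0)
    rates = counts / bin_width_s
    mean = rates.mean(axis=0)
    if train.n_trials > 1:
        sem = rates.std(axis=0, ddof=1) / np.sqrt(train.n_trials)
    else:
        sem = np.zeros(n_bins)
    return PSTH(bin_edges_s=edges, rate_hz=mean, rate_sem_hz=sem, n_trials=train.n_trials)


def compute_baseline(
    train: SpikeTrain,
    protocol: StimulusProtocol,
    bin_width_s: float = 0.1,
) -> BaselineStats:
    """Baseline mean and bin-to-bin SD from the pre-stimulus window."""
    window = protocol.baseline_window_s
    if window < 1.0:
        raise ValueError(
            f"baseline window of {window} s is too short; need >= 1 s"
        )
    psth = compute_psth(train, protocol, bin_width_s, t_range=(-window, 0.0))
    mean = float(psth.rate_hz.mean())
    sd = float(psth.rate_hz.std(ddof=0))
    return BaselineStats(mean_hz=mean, sd_hz=sd, window_s=window)


def compute_fine_psth(
    train: SpikeTrain,
    protocol: StimulusProtocol,
    config: RunConfig | None = None,
    t_range: tuple[float, float] | None = None,
) -> PSTH:
    """10-ms-binned PSTH smoothed with a normalized Gaussian kernel.

    The kernel (sigma 20 ms by default, truncated at +/-3 sigma, edges
    padded by replication) is symmetric, so it preserves the argmax of a
    unimodal peak — the property latency extraction relies on. Output length
    equals the unsmoothed histogram's length.
    """
    config = config or RunConfig()
    psth = compute_psth(train, protocol, config.fine_bin_width_s, t_range)
    sigma_bins = config.smoothing_sigma_s / config.fine_bin_width_s
    smooth = gaussian_filter1d(psth.rate_hz, sigma_bins, mode="nearest", truncate=3.0)
    smooth = np.clip(smooth, 0.0, None)
    return PSTH(
        bin_edges_s=psth.bin_edges_s,
        rate_hz=smooth,
        rate_sem_hz=psth.rate_sem_hz,
        n_trials=psth.n_trials,
    )


def trial_average_waveform(traces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and SD of time-aligned per-trial waveforms.

    ``traces`` is (n_trials, n_samples); ragged input raises.
    """
    arr = np.asarray(traces, dtype=float)
    if arr.ndim != 2:
        raise ValueError("traces must be a 2-D (n_trials, n_samples) array")
    return arr.mean(axis=0), arr.std(axis=0, ddof=0)
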