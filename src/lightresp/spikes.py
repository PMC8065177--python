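"""Spike-train containers and the tabular spike schema.

A *spike table* is a pandas DataFrame with one row per spike:

    retina_id, channel, unit_id, trial_index, time_s, condition

``time_s`` is trial-relative with stimulus onset at t = 0 (baseline spikes
sit at negative times). ``(retina_id, channel, unit_id)`` jointly identify a
sorted single unit. ``condition`` is a pharmacology label and is metadata
only: {pre_drug, blockade, washout, none}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SPIKE_COLUMNS",
    "CONDITIONS",
    "SpikeTrain",
    "validate_spike_table",
    "iter_units",
    "unit_key",
]

SPIKE_COLUMNS = ("retina_id", "channel", "unit_id", "trial_index", "time_s", "condition")
CONDITIONS = ("pre_drug", "blockade", "washout", "none")


@dataclass
class SpikeTrain:
    """One unit's spikes organized by trial.

    ``trials`` holds one float array of trial-relative spike times per
    repeat; empty trials are empty arrays, so ``len(trials)`` always equals
    the protocol's repeat count.
    """

    trials: list[np.ndarray]
    retina_id: str = "r0"
    channel: str = "ch0"
    unit_id: str = "u0"
    condition: str = "none"

    def __post_init__(self) -> None:
        self.trials = [np.asarray(t, dtype=float) for t in self.trials]
        for i, t in enumerate(self.trials):
            if t.size and not np.all(np.isfinite(t)):
                raise ValueError(f"non-finite spike time in trial {i}")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.trials))

    def all_times(self) -> np.ndarray:
        if not self.trials:
            return np.empty(0)
        return np.concatenate(self.trials)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to spike-table rows."""
        rows = []
        for i, times in enumerate(self.trials):
            for t in times:
                rows.append((self.retina_id, self.channel, self.unit_id, i, t, self.condition))
        return pd.DataFrame(rows, columns=list(SPIKE_COLUMNS))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, n_trials: int) -> "SpikeTrain":
        """Collect one unit's rows back into per-trial arrays.

        ``frame`` must contain rows of a single unit; ``n_trials`` fixes the
        trial count so silent trials are preserved as empty arrays.
        """
        if frame.empty:
            return cls(trials=[np.empty(0)] * n_trials)
        ids = frame[["retina_id", "channel", "unit_id"]].drop_duplicates()
        if len(ids) != 1:
            raise ValueError("from_frame expects rows of exactly one unit")
        retina_id, channel, unit_id = ids.iloc[0]
        condition = frame["condition"].iloc[0]
        trials = [np.empty(0)] * n_trials
        for idx, sub in frame.groupby("trial_index"):
            if idx >= n_trials:
                raise ValueError(
                    f"trial_index {idx} >= declared trial count {n_trials}"
                )
            trials[int(idx)] = np.sort(sub["time_s"].to_numpy(dtype=float))
        return cls(
            trials=trials,
            retina_id=str(retina_id),
            channel=str(channel),
            unit_id=str(unit_id),
            condition=str(condition),
        )


def unit_key(train_or_row) -> tuple[str, str, str]:
    """The (retina_id, channel, unit_id) identity triple."""
    return (
        str(train_or_row.retina_id),
        str(train_or_row.channel),
        str(train_or_row.unit_id),
    )


def validate_spike_table(table: pd.DataFrame, n_repeats: int | None = None) -> pd.DataFrame:
    """Check schema and invariants of a spike table; returns the table.

    Raises ``ValueError`` naming the first offending row (0-based, in table
    order) on a malformed entry. Never drops rows.
    """
    missing = [c for c in SPIKE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"spike table missing columns: {missing}")
    times = pd.to_numeric(table["time_s"], errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(times)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(f"row {row}: non-finite time_s {table['time_s'].iloc[row]!r}")
    trials = pd.to_numeric(table["trial_index"], errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(trials) | (trials != np.floor(trials)) | (trials < 0)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"row {row}: trial_index must be a non-negative integer, got "
            f"{table['trial_index'].iloc[row]!r}"
        )
    if n_repeats is not None and len(trials) and trials.max() >= n_repeats:
        row = int(np.flatnonzero(trials >= n_repeats)[0])
        raise ValueError(
            f"row {row}: trial_index {int(trials[row])} >= protocol repeat "
            f"count {n_repeats}"
        )
    bad_cond = ~table["condition"].astype(str).isin(CONDITIONS)
    if bad_cond.any():
        row = int(np.flatnonzero(bad_cond.to_numpy())[0])
        raise ValueError(
            f"row {row}: unknown condition {table['condition'].iloc[row]!r} "
            f"(expected one of {CONDITIONS})"
        )
    out = table.copy()
    out["time_s"] = times
    out["trial_index"] = trials.astype(int)
    out["condition"] = out["condition"].astype(str)
    return out


def iter_units(
    table: pd.DataFrame, n_trials: int
) -> Iterator[tuple[tuple[str, str, str], SpikeTrain]]:
    """Yield ((retina_id, channel, unit_id), SpikeTrain) per unit, sorted by key."""
    if table.empty:
        return
    for key, sub in table.groupby(["retina_id", "channel", "unit_id"], sort=True):
        yield tuple(map(str, key)), SpikeTrain.from_frame(sub, n_trials)
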