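"""Readers and writers for the package's tabular text formats.

All on-disk formats are tab-separated text with fixed headers, or flat
``key: value`` files for protocols, run configuration and arena geometry.
Vendor MEA formats are out of scope: conversion from proprietary
spike-sorter output happens upstream. Readers validate and never silently
drop rows; record counts go to the module logger.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import ArenaConfig, TrackingSession
from .config import RunConfig, StimulusProtocol
from .spikes import SPIKE_COLUMNS, validate_spike_table

logger = logging.getLogger("lightresp")

__all__ = [
    "read_spike_table",
    "write_spike_table",
    "read_stimulus_log",
    "write_stimulus_log",
    "read_tracking",
    "write_tracking",
    "read_run_config",
    "write_run_config",
    "read_arena",
    "write_arena",
    "write_results",
]


def _read_kv(path) -> dict:
    out = {}
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValueError(f"{path}: line {i + 1}: expected 'key: value'")
        key, value = line.split(":", 1)
        out[key.strip()] = value.strip()
    return out


def _write_kv(mapping: dict, path) -> None:
    lines = [f"{k}: {v}" for k, v in mapping.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_spike_table(path, n_repeats: int | None = None) -> pd.DataFrame:
    """Read and validate a spike table (TSV, one row per spike)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    table = validate_spike_table(raw, n_repeats)
    per_unit = table.groupby(["retina_id", "channel", "unit_id"]).size()
    logger.info(
        "read %d spikes / %d units from %s", len(table), len(per_unit), path
    )
    return table


def write_spike_table(table: pd.DataFrame, path) -> None:
    table = table[list(SPIKE_COLUMNS)]
    table.to_csv(path, sep="\t", index=False)
    logger.info("wrote %d spikes to %s", len(table), path)


def read_stimulus_log(path) -> StimulusProtocol:
    """Parse a flat key:value stimulus log into a protocol."""
    kv = _read_kv(path)
    kwargs = {}
    if "stim_duration_s" in kv:
        kwargs["stim_duration_s"] = float(kv["stim_duration_s"])
    if "isi_s" in kv:
        kwargs["isi_s"] = float(kv["isi_s"])
    if "n_repeats" in kv:
        kwargs["n_repeats"] = int(kv["n_repeats"])
    if "baseline_window_s" in kv:
        kwargs["baseline_window_s"] = float(kv["baseline_window_s"])
    if "irradiance_levels" in kv:
        kwargs["irradiance_levels"] = tuple(
            float(v) for v in kv["irradiance_levels"].split(",") if v.strip()
        )
    return StimulusProtocol(**kwargs)


def write_stimulus_log(protocol: StimulusProtocol, path) -> None:
    _write_kv(
        {
            "stim_duration_s": protocol.stim_duration_s,
            "isi_s": protocol.isi_s,
            "n_repeats": protocol.n_repeats,
            "baseline_window_s": protocol.baseline_window_s,
            "irradiance_levels": ",".join(
                repr(v) for v in protocol.irradiance_levels
            ),
        },
        path,
    )


def read_tracking(path, group: str = "none", subject_id: str | None = None) -> TrackingSession:
    """Read a tracking path (TSV: t_s, x_cm, y_cm)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    for col in ("t_s", "x_cm", "y_cm"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if frame.empty:
        raise ValueError(f"{path}: no samples")
    session = TrackingSession(
        t_s=frame["t_s"].to_numpy(dtype=float),
        x_cm=frame["x_cm"].to_numpy(dtype=float),
        y_cm=frame["y_cm"].to_numpy(dtype=float),
        group=group,
        subject_id=subject_id or path.stem,
    )
    logger.info("read %d tracking samples from %s", len(session.t_s), path)
    return session


def write_tracking(session: TrackingSession, path) -> None:
    pd.DataFrame(
        {"t_s": session.t_s, "x_cm": session.x_cm, "y_cm": session.y_cm}
    ).to_csv(path, sep="\t", index=False)


def read_run_config(path) -> RunConfig:
    return RunConfig.from_mapping(_read_kv(path))


def write_run_config(config: RunConfig, path) -> None:
    from dataclasses import asdict

    _write_kv({k: v for k, v in asdict(config).items() if v is not None}, path)


def read_arena(path) -> ArenaConfig:
    kv = _read_kv(path)
    return ArenaConfig(**{k: float(v) for k, v in kv.items()})


def write_arena(arena: ArenaConfig, path) -> None:
    from dataclasses import asdict

    _write_kv(asdict(arena), path)


def write_results(tables: dict[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write each result table as ``<name>.tsv`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        path = out_dir / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False)
        logger.info("wrote %d rows to %s", len(table), path)
        written.append(path)
    return written
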