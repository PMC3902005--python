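"""Readers and writers for the package's plain-text file formats.

All files are UTF-8, comma-delimited CSV with a header row and '.' decimal
separator, so every artifact is diff-friendly and round-trips exactly at the
written precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .data import PULSE_COLUMNS, SPIKE_COLUMNS, ResponseMatrix, SpikeEventSet
from .layout import ElectrodeMap

__all__ = [
    "ParseError",
    "read_electrode_map",
    "write_electrode_map",
    "read_spike_events",
    "write_spike_events",
    "read_matrix",
    "write_matrix",
    "read_metrics",
    "write_metrics",
]

METRIC_COLUMNS = ["culture_id", "batch_id", "day_in_vitro", "window_ms", "metric_name", "value"]


class ParseError(ValueError):
    """Raised when an input file violates the documented layout."""


def write_electrode_map(emap: ElectrodeMap, path) -> None:
    emap.table.to_csv(path, index=False)


def read_electrode_map(path) -> ElectrodeMap:
    table = pd.read_csv(path, dtype={"electrode_id": str})
    required = {"electrode_id", "x_um", "y_um", "ground_flag"}
    missing = required - set(table.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    table["ground_flag"] = table["ground_flag"].astype(bool)
    return ElectrodeMap(table)


def write_spike_events(events: SpikeEventSet, spikes_path, pulses_path=None) -> None:
    """Write spikes (and the pulse table, if present) as CSV."""
    df = events.spikes.copy()
    df["time_s"] = df["time_s"].map(lambda v: format(float(v), ".6f"))
    df.to_csv(spikes_path, index=False, columns=SPIKE_COLUMNS)
    if events.pulses is not None and pulses_path is not None:
        pf = events.pulses.copy()
        pf["pulse_time_s"] = pf["pulse_time_s"].map(lambda v: format(float(v), ".6f"))
        pf.to_csv(pulses_path, index=False, columns=PULSE_COLUMNS)


def read_spike_events(
    spikes_path,
    pulses_path=None,
    electrode_map: Optional[ElectrodeMap] = None,
    n_trials: int = 50,
) -> SpikeEventSet:
    """Read a spike-event file (plus optional pulse file) with validation.

    Errors name the offending record so a malformed line can be located.
    """
    spikes = pd.read_csv(
        spikes_path, dtype={"electrode_id": str, "session_id": str, "culture_id": str, "batch_id": str}
    )
    missing = set(SPIKE_COLUMNS) - set(spikes.columns)
    if missing:
        raise ParseError(f"{spikes_path}: missing columns {sorted(missing)}")
    pulses = None
    if pulses_path is not None:
        pulses = pd.read_csv(pulses_path, dtype={"stim_electrode_id": str, "session_id": str})
        missing = set(PULSE_COLUMNS) - set(pulses.columns)
        if missing:
            raise ParseError(f"{pulses_path}: missing columns {sorted(missing)}")
    events = SpikeEventSet(spikes=spikes, pulses=pulses)
    try:
        events.validate(electrode_map=electrode_map, n_trials=n_trials)
    except ValueError as exc:  # re-raise with file context
        raise ParseError(f"{spikes_path}: {exc}") from exc
    return events


def write_matrix(rm: ResponseMatrix, path) -> None:
    """Write a response matrix as CSV (electrode ids as header row/column)
    plus a ``<path>.meta.json`` sidecar with window and provenance fields."""
    path = Path(path)
    df = pd.DataFrame(rm.z, index=rm.electrode_ids, columns=rm.electrode_ids)
    df.to_csv(path, index_label="electrode_id", float_format="%.10g")
    meta = {
        "window_ms": rm.window_ms,
        "day_in_vitro": rm.day_in_vitro,
        "culture_id": rm.culture_id,
        "batch_id": rm.batch_id,
        "diagonal_policy": rm.diagonal_policy,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_matrix(path, electrode_map: Optional[ElectrodeMap] = None) -> ResponseMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if df.shape[0] != df.shape[1]:
        raise ParseError(f"{path}: matrix is not square ({df.shape[0]}x{df.shape[1]})")
    if list(df.index) != list(df.columns):
        raise ParseError(f"{path}: row and column electrode ids differ")
    if electrode_map is not None and list(df.index) != electrode_map.analysis_ids:
        raise ParseError(f"{path}: electrode ids do not match the electrode map")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return ResponseMatrix(
        z=df.to_numpy(dtype=float),
        electrode_ids=list(df.index),
        window_ms=float(meta.get("window_ms", 100.0)),
        day_in_vitro=meta.get("day_in_vitro"),
        culture_id=meta.get("culture_id"),
        batch_id=meta.get("batch_id"),
        diagonal_policy=meta.get("diagonal_policy", "zero"),
    )


def write_metrics(metrics: pd.DataFrame, path) -> None:
    missing = set(METRIC_COLUMNS) - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table missing columns: {sorted(missing)}")
    metrics.to_csv(path, index=False, columns=METRIC_COLUMNS, float_format="%.10g")


def read_metrics(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"culture_id": str, "batch_id": str, "metric_name": str})
    missing = set(METRIC_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df
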