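"""Core data containers shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SPIKE_COLUMNS",
    "PULSE_COLUMNS",
    "SpikeEventSet",
    "ResponseMatrix",
    "StudyManifest",
    "DailyMetrics",
    "PLATING_TABLE",
]

SPIKE_COLUMNS = [
    "electrode_id",
    "time_s",
    "session_id",
    "session_kind",
    "day_in_vitro",
    "culture_id",
    "batch_id",
]
PULSE_COLUMNS = ["stim_electrode_id", "pulse_time_s", "trial_index", "session_id"]

#: Plating configuration per density class: volume (µL), suspension density
#: (cells/µL); the nominal plated-cell count is their product.
PLATING_TABLE = {
    "dense": {"plating_volume_ul": 20.0, "suspension_density_cells_per_ul": 2500.0},
    "small": {"plating_volume_ul": 5.0, "suspension_density_cells_per_ul": 2500.0},
    "sparse": {"plating_volume_ul": 20.0, "suspension_density_cells_per_ul": 625.0},
}


def nominal_plated_cells(density_class: str) -> float:
    row = PLATING_TABLE[density_class]
    return row["plating_volume_ul"] * row["suspension_density_cells_per_ul"]


@dataclass
class SpikeEventSet:
    """Timestamped spikes from one or more recording sessions.

    ``spikes`` has columns :data:`SPIKE_COLUMNS`; ``pulses`` (stimulation
    sessions only) has columns :data:`PULSE_COLUMNS` with ``trial_index`` in
    ``0..n_trials-1`` for each stimulated electrode.  Times are seconds from
    session start.  ``duration_s`` optionally records the session length; when
    absent it is inferred from the last event.
    """

    spikes: pd.DataFrame
    pulses: Optional[pd.DataFrame] = None
    duration_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.spikes is None or len(self.spikes) == 0:
            self.spikes = pd.DataFrame(columns=SPIKE_COLUMNS)
        missing = set(SPIKE_COLUMNS) - set(self.spikes.columns)
        if missing:
            raise ValueError(f"spike table missing columns: {sorted(missing)}")
        if self.pulses is not None and len(self.pulses):
            missing = set(PULSE_COLUMNS) - set(self.pulses.columns)
            if missing:
                raise ValueError(f"pulse table missing columns: {sorted(missing)}")

    def validate(self, electrode_map=None, n_trials: int = 50) -> None:
        """Check invariants; raise ``ValueError`` on the first violation."""
        t = self.spikes["time_s"].to_numpy(dtype=float)
        if len(t) and (not np.isfinite(t).all() or (t < 0).any()):
            bad = int(np.flatnonzero(~np.isfinite(t) | (t < 0))[0])
            raise ValueError(f"spike record {bad}: time must be finite and non-negative")
        for sid, grp in self.spikes.groupby("session_id", sort=False):
            tt = grp["time_s"].to_numpy(dtype=float)
            if len(tt) > 1 and (np.diff(tt) < 0).any():
                bad = int(grp.index[np.flatnonzero(np.diff(tt) < 0)[0] + 1])
                raise ValueError(f"spike record {bad}: times unsorted within session {sid!r}")
        kinds = set(self.spikes["session_kind"].unique())
        if not kinds <= {"spontaneous", "stimulation"}:
            raise ValueError(f"unknown session kinds: {sorted(kinds - {'spontaneous', 'stimulation'})}")
        if self.pulses is not None and len(self.pulses):
            ti = self.pulses["trial_index"].to_numpy()
            if ((ti < 0) | (ti >= n_trials)).any():
                bad = int(np.flatnonzero((ti < 0) | (ti >= n_trials))[0])
                raise ValueError(
                    f"pulse record {bad}: trial_index {ti[bad]} outside [0, {n_trials - 1}]"
                )
        if electrode_map is not None:
            valid = set(electrode_map.analysis_ids)
            ids = set(self.spikes["electrode_id"].unique())
            if self.pulses is not None and len(self.pulses):
                stim = set(self.pulses["stim_electrode_id"].unique())
                if not stim <= valid:
                    raise ValueError(f"unknown stimulated electrodes: {sorted(stim - valid)}")
            unknown = ids - valid
            if unknown:
                raise ValueError(f"unknown recording electrodes: {sorted(unknown)}")

    def session_duration(self) -> float:
        if self.duration_s is not None:
            return float(self.duration_s)
        times = []
        if len(self.spikes):
            times.append(self.spikes["time_s"].max())
        if self.pulses is not None and len(self.pulses):
            times.append(self.pulses["pulse_time_s"].max())
        if not times:
            raise ValueError("empty event set with no recorded duration")
        return float(max(times))


@dataclass
class ResponseMatrix:
    """Normalized stimulus-response matrix Z for one culture-day.

    ``z[k, j]`` is the trial-averaged evoked spike count at recording
    electrode ``j`` after stimulating electrode ``k``, minus the spontaneous
    per-window baseline of ``j`` (units: spikes per window).  Negative values
    are legal.  ``diagonal_policy`` is ``"zero"`` (default: the k = j channel
    is artifact-dominated, set to 0 and excluded from testing) or
    ``"include"``.
    """

    z: np.ndarray
    electrode_ids: list[str]
    window_ms: float
    day_in_vitro: Optional[int] = None
    culture_id: Optional[str] = None
    batch_id: Optional[str] = None
    diagonal_policy: str = "zero"

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2 or self.z.shape[0] != self.z.shape[1]:
            raise ValueError("Z must be a square matrix")
        if self.z.shape[0] != len(self.electrode_ids):
            raise ValueError("Z dimensions must match electrode id count")
        if not np.isfinite(self.z).all():
            raise ValueError("Z contains non-finite entries")
        if self.window_ms <= 0:
            raise ValueError("window_ms must be positive")
        if self.diagonal_policy not in {"zero", "include"}:
            raise ValueError(f"unknown diagonal_policy {self.diagonal_policy!r}")

    @property
    def tested_mask(self) -> np.ndarray:
        """Boolean mask of entries that enter the significance test."""
        mask = np.ones_like(self.z, dtype=bool)
        if self.diagonal_policy == "zero":
            np.fill_diagonal(mask, False)
        return mask


@dataclass
class StudyManifest:
    """Cultures of a longitudinal study, grouped into tissue batches.

    ``cultures`` has columns ``culture_id``, ``batch_id``, ``density_class``
    (dense/small/sparse) and ``days`` (list of recorded days in vitro).
    """

    cultures: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"culture_id", "batch_id", "density_class", "days"}
        missing = required - set(self.cultures.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        if self.cultures["culture_id"].duplicated().any():
            raise ValueError("duplicate culture ids (a culture belongs to exactly one batch)")
        bad = set(self.cultures["density_class"]) - set(PLATING_TABLE)
        if bad:
            raise ValueError(f"unknown density classes: {sorted(bad)}")

    def plating_metadata(self) -> pd.DataFrame:
        """Per-culture plating volume, suspension density and nominal cells."""
        rows = []
        for _, c in self.cultures.iterrows():
            meta = PLATING_TABLE[c["density_class"]]
            rows.append(
                {
                    "culture_id": c["culture_id"],
                    "batch_id": c["batch_id"],
                    "density_class": c["density_class"],
                    **meta,
                    "nominal_plated_cells": meta["plating_volume_ul"]
                    * meta["suspension_density_cells_per_ul"],
                }
            )
        return pd.DataFrame(rows)


@dataclass
class DailyMetrics:
    """Connectivity metrics for one culture on one day in vitro."""

    culture_id: str
    day_in_vitro: int
    window_ms: float
    n_edges: int
    mean_connection_length_um: float  # NaN when the graph is empty
    n_incoming_supernodes: int
    n_outgoing_supernodes: int
    batch_id: Optional[str] = None

    def to_rows(self) -> list[dict]:
        """Tidy long-format rows (one per metric) for the metrics table."""
        base = {
            "culture_id": self.culture_id,
            "batch_id": self.batch_id,
            "day_in_vitro": self.day_in_vitro,
            "window_ms": self.window_ms,
        }
        return [
            {**base, "metric_name": "mean_connection_length_um", "value": self.mean_connection_length_um},
            {**base, "metric_name": "n_edges", "value": float(self.n_edges)},
            {**base, "metric_name": "n_incoming_supernodes", "value": float(self.n_incoming_supernodes)},
            {**base, "metric_name": "n_outgoing_supernodes", "value": float(self.n_outgoing_supernodes)},
        ]
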