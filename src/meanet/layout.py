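"""Electrode layouts for micro-electrode array (MEA) dishes.

The standard commercial 60-electrode MEA is an 8x8 grid with the four
corner positions absent.  One electrode serves as ground/reference and is
excluded from analysis, leaving 59 analysis electrodes -- the configuration
assumed throughout this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ElectrodeMap", "standard_mea_layout"]

_CORNERS = {(1, 1), (1, 8), (8, 1), (8, 8)}


@dataclass(frozen=True)
class ElectrodeMap:
    """Physical electrode positions on an MEA dish.

    ``table`` has one row per electrode with columns ``electrode_id`` (str),
    ``x_um``, ``y_um`` (micrometers) and ``ground_flag`` (bool).  Electrodes
    flagged as ground are excluded from every analysis.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"electrode_id", "x_um", "y_um", "ground_flag"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"electrode map missing columns: {sorted(missing)}")
        ana = self.table[~self.table["ground_flag"]]
        if ana["electrode_id"].duplicated().any():
            raise ValueError("duplicate analysis electrode ids")
        if ana.duplicated(subset=["x_um", "y_um"]).any():
            raise ValueError("duplicate analysis electrode coordinates")
        if (self.table[["x_um", "y_um"]].to_numpy() < 0).any():
            raise ValueError("electrode coordinates must be non-negative")

    @property
    def analysis_ids(self) -> list[str]:
        """Ids of non-ground electrodes, in layout order."""
        return list(self.table.loc[~self.table["ground_flag"], "electrode_id"])

    @property
    def n_analysis(self) -> int:
        return len(self.analysis_ids)

    def coords(self) -> np.ndarray:
        """(n_analysis, 2) array of x/y positions in micrometers."""
        ana = self.table[~self.table["ground_flag"]]
        return ana[["x_um", "y_um"]].to_numpy(dtype=float)

    def index_of(self, electrode_id: str) -> int:
        try:
            return self.analysis_ids.index(electrode_id)
        except ValueError:
            raise KeyError(f"unknown analysis electrode {electrode_id!r}") from None

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean distances (µm) between analysis electrodes."""
        xy = self.coords()
        diff = xy[:, None, :] - xy[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))


def standard_mea_layout(pitch_um: float = 200.0, ground_electrode: str = "15") -> ElectrodeMap:
    """Build the conventional 8x8-minus-corners MEA layout.

    Parameters
    ----------
    pitch_um
        Center-to-center electrode spacing in micrometers.
    ground_electrode
        Label (``"<col><row>"``, 1-based) of the position used as ground;
        it is flagged and excluded from analysis, leaving 59 electrodes.
    """
    if pitch_um <= 0:
        raise ValueError("pitch_um must be positive")
    rows = []
    labels = set()
    for col in range(1, 9):
        for row in range(1, 9):
            if (col, row) in _CORNERS:
                continue
            label = f"{col}{row}"
            labels.add(label)
            rows.append(
                {
                    "electrode_id": label,
                    "x_um": col * pitch_um,
                    "y_um": row * pitch_um,
                    "ground_flag": False,
                }
            )
    if ground_electrode not in labels:
        raise ValueError(
            f"ground electrode {ground_electrode!r} is not a valid grid position"
        )
    table = pd.DataFrame(rows)
    table.loc[table["electrode_id"] == ground_electrode, "ground_flag"] = True
    return ElectrodeMap(table)
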