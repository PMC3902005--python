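"""From spike events to the normalized stimulus-response matrix Z.

For each stimulated electrode k, recording electrode j and trial t, spikes
at j falling in the observation window after the pulse are counted; trial
averages are normalized by subtracting the per-electrode mean spontaneous
spike count over the same window length, recorded the same day from the
same network.  The result is the square Z matrix (stimulated x recording)
in units of spikes per window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import ResponseMatrix, SpikeEventSet
from .layout import ElectrodeMap

__all__ = ["WindowSpec", "count_evoked", "spontaneous_baseline", "build_z", "response_matrix_for_day"]


@dataclass(frozen=True)
class WindowSpec:
    """Observation window after stimulus onset.

    ``window_ms`` is typically 50, 100 or 150 ms: the three windows capture,
    respectively, direct responses (0-20 ms), early post-synaptic spikes and
    late culture-wide barrages (>100 ms).  Spikes within ``artifact_blank_ms``
    of the pulse are ignored (stimulus-artifact blanking; default 0).
    """

    window_ms: float = 100.0
    artifact_blank_ms: float = 0.0

    def __post_init__(self) -> None:
        if not (self.window_ms > self.artifact_blank_ms >= 0.0):
            raise ValueError("require window_ms > artifact_blank_ms >= 0")


def count_evoked(
    events: SpikeEventSet,
    window: WindowSpec,
    emap: ElectrodeMap,
    n_trials: int = 50,
) -> np.ndarray:
    """Count evoked spikes per (stimulated, recording, trial).

    Returns an ``(n, n, n_trials)`` integer array where entry ``(k, j, t)``
    is the number of spikes at electrode j in the half-open interval
    ``(pulse + blank, pulse + window]`` for trial t of stimulation at k.
    Raises if any (electrode, trial) pulse is missing; warns when the window
    exceeds the inter-pulse interval (responses then overlap the next pulse).
    """
    if events.pulses is None or len(events.pulses) == 0:
        raise ValueError("stimulation events lack a pulse table")
    ids = emap.analysis_ids
    n = len(ids)
    idx = {eid: i for i, eid in enumerate(ids)}

    pulses = events.pulses
    missing = []
    for eid in ids:
        trials = set(pulses.loc[pulses["stim_electrode_id"] == eid, "trial_index"])
        missing.extend((eid, t) for t in range(n_trials) if t not in trials)
    if missing:
        raise ValueError(f"missing trials: {missing[:10]}{'...' if len(missing) > 10 else ''}")

    p_times = pulses["pulse_time_s"].to_numpy(dtype=float)
    if len(p_times) > 1:
        ipi = np.diff(np.sort(p_times))
        ipi = ipi[ipi > 0]
        if len(ipi) and window.window_ms / 1000.0 > ipi.min() + 1e-12:
            warnings.warn(
                f"window {window.window_ms} ms exceeds the {ipi.min() * 1000:.0f} ms "
                "inter-pulse interval; counting windows overlap the next pulse",
                stacklevel=2,
            )

    k_idx = pulses["stim_electrode_id"].map(idx).to_numpy()
    t_idx = pulses["trial_index"].to_numpy(dtype=int)
    lo = p_times + window.artifact_blank_ms / 1000.0
    hi = p_times + window.window_ms / 1000.0

    counts = np.zeros((n, n, n_trials), dtype=np.int64)
    spikes = events.spikes
    for eid, grp in spikes.groupby("electrode_id", sort=False):
        j = idx.get(eid)
        if j is None:
            continue
        st = np.sort(grp["time_s"].to_numpy(dtype=float))
        c = np.searchsorted(st, hi, side="right") - np.searchsorted(st, lo, side="right")
        counts[k_idx, j, t_idx] = c
    return counts


def spontaneous_baseline(
    events: SpikeEventSet,
    window: WindowSpec,
    emap: ElectrodeMap,
    n_windows: int | None = None,
    placement: str = "tile",
    seed: int | None = None,
) -> np.ndarray:
    """Mean spontaneous spike count per electrode per window (length-n).

    Default placement tiles the whole recording with contiguous windows (the
    lowest-variance deterministic estimate); ``placement="random"`` instead
    draws ``n_windows`` uniformly placed windows using ``seed``.
    """
    w = window.window_ms / 1000.0
    duration = events.session_duration() if len(events.spikes) else (events.duration_s or 0.0)
    if duration < w:
        raise ValueError("spontaneous recording shorter than one window")
    if placement == "tile":
        m = int(duration / w) if n_windows is None else min(n_windows, int(duration / w))
        starts = np.arange(m) * w
    elif placement == "random":
        if n_windows is None:
            raise ValueError("random placement requires n_windows")
        m = n_windows
        starts = np.random.default_rng(seed).uniform(0.0, duration - w, size=m)
    else:
        raise ValueError(f"unknown placement {placement!r}")
    if m == 0:
        raise ValueError("no counting windows fit in the recording")

    ids = emap.analysis_ids
    baseline = np.zeros(len(ids))
    idx = {eid: i for i, eid in enumerate(ids)}
    for eid, grp in events.spikes.groupby("electrode_id", sort=False):
        j = idx.get(eid)
        if j is None:
            continue
        st = np.sort(grp["time_s"].to_numpy(dtype=float))
        c = np.searchsorted(st, starts + w, side="right") - np.searchsorted(st, starts, side="right")
        baseline[j] = c.sum() / m
    return baseline


def build_z(
    counts: np.ndarray,
    baseline: np.ndarray,
    emap: ElectrodeMap,
    window: WindowSpec,
    diagonal_policy: str = "zero",
    day_in_vitro: int | None = None,
    culture_id: str | None = None,
    batch_id: str | None = None,
) -> ResponseMatrix:
    """Average counts across trials and subtract the spontaneous baseline.

    ``Z[k, j] = mean_t counts[k, j, t] - baseline[j]``.  Under the default
    ``diagonal_policy="zero"`` the stimulated electrode's own channel is set
    to 0 and excluded from downstream testing; ``"include"`` keeps it.
    """
    counts = np.asarray(counts)
    baseline = np.asarray(baseline, dtype=float)
    if counts.ndim != 3 or counts.shape[0] != counts.shape[1]:
        raise ValueError("counts must be (n, n, n_trials)")
    if counts.shape[0] != len(baseline) or counts.shape[0] != emap.n_analysis:
        raise ValueError("counts/baseline dimensions do not match the electrode map")
    if not (np.isfinite(counts).all() and np.isfinite(baseline).all()):
        raise ValueError("NaN or infinite values in counts or baseline")
    z = counts.mean(axis=2) - baseline[None, :]
    if diagonal_policy == "zero":
        np.fill_diagonal(z, 0.0)
    return ResponseMatrix(
        z=z,
        electrode_ids=emap.analysis_ids,
        window_ms=window.window_ms,
        day_in_vitro=day_in_vitro,
        culture_id=culture_id,
        batch_id=batch_id,
        diagonal_policy=diagonal_policy,
    )


def response_matrix_for_day(
    stim_events: SpikeEventSet,
    spont_events: SpikeEventSet,
    window: WindowSpec,
    emap: ElectrodeMap,
    n_trials: int = 50,
    diagonal_policy: str = "zero",
) -> ResponseMatrix:
    """Convenience composition: counts, baseline and Z for one culture-day."""
    counts = count_evoked(stim_events, window, emap, n_trials=n_trials)
    baseline = spontaneous_baseline(spont_events, window, emap)
    first = stim_events.spikes.iloc[0] if len(stim_events.spikes) else None
    return build_z(
        counts,
        baseline,
        emap,
        window,
        diagonal_policy=diagonal_policy,
        day_in_vitro=None if first is None else int(first["day_in_vitro"]),
        culture_id=None if first is None else str(first["culture_id"]),
        batch_id=None if first is None else str(first["batch_id"]),
    )
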