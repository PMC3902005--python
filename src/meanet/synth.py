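"""Synthetic longitudinal MEA studies.

Generates data with the statistical structure the analysis pipeline assumes:

* a latent directed connectivity graph per culture that grows over ~40 days
  in vitro in two phases (a quiescent phase of about five days, then rapid
  growth over 10-15 days, then a plateau), with hub nodes that accumulate
  degree >= 4 so that supernode metrics have something to find;
* spontaneous sessions: per-electrode Poisson background firing plus
  network-wide burst epochs, the characteristic activity of dissociated
  cortical cultures;
* stimulation sessions: 50 pulses per electrode delivered sequentially once
  every 300 ms, each pulse evoking spikes across latent edges with
  edge-specific probabilities and response latencies (direct 0-20 ms, early
  post-synaptic within the observation window, late culture-wide barrages);
* plain two-group mixture Z matrices for fast significance-testing checks.

Every generator is a pure function of its parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .data import (
    PLATING_TABLE,
    PULSE_COLUMNS,
    SPIKE_COLUMNS,
    ResponseMatrix,
    SpikeEventSet,
    StudyManifest,
    nominal_plated_cells,
)
from .layout import ElectrodeMap
from . import io as mio

__all__ = [
    "GrowthSchedule",
    "LatentNetwork",
    "FiringParams",
    "StimProtocol",
    "MixtureSpec",
    "generate_latent_trajectory",
    "simulate_spontaneous",
    "simulate_stimulation_session",
    "generate_study",
    "generate_z_mixture",
    "default_manifest",
    "session_seed",
]

LATENCY_CLASSES = ("direct", "early", "barrage")


@dataclass(frozen=True)
class GrowthSchedule:
    """Two-phase developmental schedule of the latent connectivity graph.

    Edge count is ~0 for ``quiescent_days``, then climbs linearly over
    ``growth_days`` to ``plateau_density`` (fraction of ordered electrode
    pairs), then stays flat.  Edges are drawn with an exponential distance
    preference whose length scale widens from ``length_scale_start_um`` to
    ``length_scale_end_um`` across the growth phase, so mean connection
    length also rises and plateaus.  A fraction of nodes are designated
    hubs and attract edges preferentially, producing supernodes
    (degree >= 4) by plateau.  ``density_class`` scales the plateau density
    by sqrt(nominal plated cells / dense nominal cells).

    Functional connectivity in cultures is not static day to day: only part
    of the network is expressed in any one session.  ``core_fraction`` of
    each day's edges form a stable backbone that accumulates through
    development and persists; the remainder are transient edges redrawn
    fresh every day from the same distance/hub preference, so the expressed
    edge set fluctuates between sessions while its statistics follow the
    growth schedule.
    """

    quiescent_days: int = 5
    growth_days: int = 12
    n_days: int = 40
    plateau_density: float = 0.05
    length_scale_start_um: float = 150.0
    length_scale_end_um: float = 350.0
    hub_fraction: float = 0.2
    hub_bias: float = 4.0
    core_fraction: float = 0.3
    density_class: str = "dense"
    weight_range: tuple[float, float] = (0.3, 0.9)
    latency_fractions: tuple[float, float, float] = (0.5, 0.35, 0.15)
    direct_band_ms: tuple[float, float] = (0.0, 20.0)
    early_band_ms: tuple[float, float] = (5.0, 100.0)
    barrage_band_ms: tuple[float, float] = (100.0, 250.0)

    def __post_init__(self) -> None:
        if self.quiescent_days <= 0 or self.growth_days <= 0:
            raise ValueError("phase durations must be positive")
        if not (0.0 <= self.plateau_density <= 1.0):
            raise ValueError("plateau_density must lie in [0, 1]")
        if self.quiescent_days + self.growth_days > self.n_days:
            raise ValueError("schedule phases exceed the simulated horizon")
        if self.density_class not in PLATING_TABLE:
            raise ValueError(f"unknown density class {self.density_class!r}")
        if abs(sum(self.latency_fractions) - 1.0) > 1e-9:
            raise ValueError("latency_fractions must sum to 1")

    @property
    def density_scale(self) -> float:
        return float(
            np.sqrt(nominal_plated_cells(self.density_class) / nominal_plated_cells("dense"))
        )

    def target_edge_count(self, day: int, n_electrodes: int) -> int:
        """Expected latent edge count on a given day in vitro."""
        n_pairs = n_electrodes * (n_electrodes - 1)
        plateau = self.plateau_density * self.density_scale * n_pairs
        if day <= self.quiescent_days:
            frac = 0.0
        else:
            frac = min(1.0, (day - self.quiescent_days) / self.growth_days)
        return int(round(plateau * frac))

    def length_scale(self, day: int) -> float:
        frac = min(1.0, max(0.0, (day - self.quiescent_days) / self.growth_days))
        return self.length_scale_start_um + frac * (
            self.length_scale_end_um - self.length_scale_start_um
        )

    def latency_band_ms(self, latency_class: str) -> tuple[float, float]:
        return {
            "direct": self.direct_band_ms,
            "early": self.early_band_ms,
            "barrage": self.barrage_band_ms,
        }[latency_class]


@dataclass
class LatentNetwork:
    """Per-day snapshot of the latent directed connectivity graph.

    ``edges`` has columns ``src``, ``dst`` (analysis electrode ids),
    ``weight`` (probability that one pulse at src evokes an extra spike at
    dst), ``latency_class`` and ``length_um``.
    """

    day: int
    electrode_ids: list[str]
    edges: pd.DataFrame
    schedule: GrowthSchedule

    def __post_init__(self) -> None:
        if len(self.edges):
            w = self.edges["weight"].to_numpy(dtype=float)
            if ((w < 0) | (w > 1)).any():
                raise ValueError("edge weights must lie in [0, 1]")
            if (self.edges["src"] == self.edges["dst"]).any():
                raise ValueError("self-edges are not allowed")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def mean_edge_length(self) -> float:
        if not len(self.edges):
            return float("nan")
        return float(self.edges["length_um"].mean())


def _draw_edges(
    rng: np.random.Generator,
    n_draw: int,
    pref: np.ndarray,
    blocked: np.ndarray,
    ids: list[str],
    dist: np.ndarray,
    schedule: GrowthSchedule,
) -> list[dict]:
    """Sample ``n_draw`` distinct ordered pairs (excluding ``blocked``) with
    probability proportional to ``pref``, attaching weight/latency/length."""
    n = len(ids)
    p = pref.copy()
    p[blocked] = 0.0
    total = p.sum()
    if total <= 0 or n_draw <= 0:
        return []
    n_draw = min(n_draw, int((p > 0).sum()))
    flat = rng.choice(n * n, size=n_draw, replace=False, p=(p / total).ravel())
    rows = []
    for f in np.sort(flat):
        k, j = divmod(int(f), n)
        rows.append(
            {
                "src": ids[k],
                "dst": ids[j],
                "weight": rng.uniform(*schedule.weight_range),
                "latency_class": LATENCY_CLASSES[rng.choice(3, p=schedule.latency_fractions)],
                "length_um": dist[k, j],
            }
        )
    return rows


def generate_latent_trajectory(
    emap: ElectrodeMap, schedule: GrowthSchedule, seed: int
) -> list[LatentNetwork]:
    """Simulate the latent functional network for days 1..n_days.

    The stable core accumulates (core edges never disappear): its count is
    near zero through the quiescent phase, rises through the growth phase
    and is flat at plateau.  On each day the expressed network is the core
    plus freshly drawn transient edges (see :class:`GrowthSchedule`), so
    total expressed edge count follows the schedule while the expressed set
    fluctuates between days.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    ids = emap.analysis_ids
    n = len(ids)
    dist = emap.distance_matrix()

    n_hubs = int(round(schedule.hub_fraction * n))
    in_hubs = set(rng.choice(n, size=n_hubs, replace=False)) if n_hubs else set()
    out_hubs = set(rng.choice(n, size=n_hubs, replace=False)) if n_hubs else set()
    hub_in = np.array([schedule.hub_bias if j in in_hubs else 1.0 for j in range(n)])
    hub_out = np.array([schedule.hub_bias if k in out_hubs else 1.0 for k in range(n)])

    core_present = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(core_present, True)  # block self-edges from sampling
    core_rows: list[dict] = []
    snapshots: list[LatentNetwork] = []
    idx = {eid: i for i, eid in enumerate(ids)}
    for day in range(1, schedule.n_days + 1):
        target = schedule.target_edge_count(day, n)
        core_target = int(round(schedule.core_fraction * target))
        lam = schedule.length_scale(day)
        pref = np.exp(-dist / lam) * hub_out[:, None] * hub_in[None, :]
        new_core = _draw_edges(
            rng, core_target - len(core_rows), pref, core_present, ids, dist, schedule
        )
        for e in new_core:
            core_present[idx[e["src"]], idx[e["dst"]]] = True
        core_rows.extend(new_core)
        transient = _draw_edges(
            rng, target - len(core_rows), pref, core_present, ids, dist, schedule
        )
        edges = pd.DataFrame(
            core_rows + transient,
            columns=["src", "dst", "weight", "latency_class", "length_um"],
        )
        snapshots.append(
            LatentNetwork(day=day, electrode_ids=list(ids), edges=edges, schedule=schedule)
        )
    return snapshots


@dataclass(frozen=True)
class FiringParams:
    """Spontaneous firing model: baseline Poisson rate per electrode plus
    network-wide burst epochs during which the rate is multiplied."""

    baseline_hz: float = 0.5
    burst_rate_hz: float = 0.1  # Poisson rate of burst onsets
    burst_duration_s: float = 0.3
    burst_multiplier: float = 20.0

    def __post_init__(self) -> None:
        if min(self.baseline_hz, self.burst_rate_hz, self.burst_duration_s) < 0:
            raise ValueError("rates and durations must be non-negative")
        if self.burst_multiplier < 1.0:
            raise ValueError("burst_multiplier must be >= 1")


def _spontaneous_spike_times(
    rng: np.random.Generator, params: FiringParams, duration_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Burst onsets shared network-wide; returns (burst_starts, burst_ends)."""
    n_bursts = rng.poisson(params.burst_rate_hz * duration_s)
    starts = np.sort(rng.uniform(0.0, duration_s, size=n_bursts))
    ends = np.minimum(starts + params.burst_duration_s, duration_s)
    return starts, ends


def simulate_spontaneous(
    emap: ElectrodeMap,
    day: int,
    firing_params: FiringParams,
    duration_s: float,
    seed: int,
    culture_id: str = "c1",
    batch_id: str = "b1",
    session_id: Optional[str] = None,
) -> SpikeEventSet:
    """Simulate one spontaneous (no-stimulation) recording session."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    session_id = session_id or f"{culture_id}-d{day:02d}-spont"
    starts, ends = _spontaneous_spike_times(rng, firing_params, duration_s)
    rows_e: list[str] = []
    rows_t: list[np.ndarray] = []
    for eid in emap.analysis_ids:
        n_base = rng.poisson(firing_params.baseline_hz * duration_s)
        times = [rng.uniform(0.0, duration_s, size=n_base)]
        extra_rate = firing_params.baseline_hz * (firing_params.burst_multiplier - 1.0)
        for s, e in zip(starts, ends):
            n_extra = rng.poisson(extra_rate * (e - s))
            times.append(rng.uniform(s, e, size=n_extra))
        t = np.concatenate(times)
        rows_e.extend([eid] * len(t))
        rows_t.append(t)
    times_all = np.concatenate(rows_t) if rows_t else np.empty(0)
    spikes = pd.DataFrame(
        {
            "electrode_id": rows_e,
            "time_s": times_all,
            "session_id": session_id,
            "session_kind": "spontaneous",
            "day_in_vitro": day,
            "culture_id": culture_id,
            "batch_id": batch_id,
        }
    ).sort_values(["time_s", "electrode_id"], kind="stable", ignore_index=True)
    return SpikeEventSet(spikes=spikes[SPIKE_COLUMNS], duration_s=duration_s)


@dataclass(frozen=True)
class StimProtocol:
    """Stimulation protocol: ``n_pulses`` pulses per electrode delivered
    sequentially (electrode by electrode) once every ``inter_pulse_s``."""

    n_pulses: int = 50
    inter_pulse_s: float = 0.3

    def __post_init__(self) -> None:
        if self.n_pulses <= 0 or self.inter_pulse_s <= 0:
            raise ValueError("protocol parameters must be positive")


def simulate_stimulation_session(
    emap: ElectrodeMap,
    network: LatentNetwork,
    protocol: StimProtocol = StimProtocol(),
    background: Optional[FiringParams] = FiringParams(),
    seed: int = 0,
    culture_id: str = "c1",
    batch_id: str = "b1",
    session_id: Optional[str] = None,
) -> SpikeEventSet:
    """Simulate one stimulation session over the latent network.

    Each pulse at electrode k evokes, independently per outgoing latent edge
    (k -> j), one extra spike at j with the edge's probability, at the pulse
    time plus a latency drawn uniformly from the edge's latency-class band.
    Evoked spikes are superimposed on the spontaneous background and always
    follow their pulse.
    """
    if set(network.electrode_ids) != set(emap.analysis_ids):
        raise ValueError("latent network electrodes do not match the electrode map")
    rng = np.random.default_rng(seed)
    ids = emap.analysis_ids
    day = network.day
    session_id = session_id or f"{culture_id}-d{day:02d}-stim"

    # pulse table: electrodes stimulated in layout order, n_pulses each
    pulse_rows = []
    t = 0.0
    for eid in ids:
        for trial in range(protocol.n_pulses):
            pulse_rows.append(
                {
                    "stim_electrode_id": eid,
                    "pulse_time_s": t,
                    "trial_index": trial,
                    "session_id": session_id,
                }
            )
            t += protocol.inter_pulse_s
    pulses = pd.DataFrame(pulse_rows, columns=PULSE_COLUMNS)
    duration = t

    rows_e: list[str] = []
    rows_t: list[np.ndarray] = []
    edges_by_src = dict(tuple(network.edges.groupby("src", sort=False))) if network.n_edges else {}
    for eid in ids:
        sub = edges_by_src.get(eid)
        if sub is None:
            continue
        p_times = pulses.loc[pulses["stim_electrode_id"] == eid, "pulse_time_s"].to_numpy()
        for _, edge in sub.iterrows():
            hit = rng.random(len(p_times)) < edge["weight"]
            if not hit.any():
                continue
            lo, hi = network.schedule.latency_band_ms(edge["latency_class"])
            lat = rng.uniform(lo, hi, size=int(hit.sum())) / 1000.0
            evoked = p_times[hit] + lat
            rows_e.extend([edge["dst"]] * len(evoked))
            rows_t.append(evoked)

    if background is not None and background.baseline_hz > 0:
        bg = simulate_spontaneous(
            emap,
            day,
            background,
            duration,
            seed=int(rng.integers(0, 2**31 - 1)),
            culture_id=culture_id,
            batch_id=batch_id,
            session_id=session_id,
        )
        rows_e.extend(bg.spikes["electrode_id"].tolist())
        rows_t.append(bg.spikes["time_s"].to_numpy())

    times_all = np.concatenate(rows_t) if rows_t else np.empty(0)
    spikes = pd.DataFrame(
        {
            "electrode_id": rows_e,
            "time_s": times_all,
            "session_id": session_id,
            "session_kind": "stimulation",
            "day_in_vitro": day,
            "culture_id": culture_id,
            "batch_id": batch_id,
        }
    ).sort_values(["time_s", "electrode_id"], kind="stable", ignore_index=True)
    return SpikeEventSet(spikes=spikes[SPIKE_COLUMNS], pulses=pulses, duration_s=duration)


def default_manifest() -> StudyManifest:
    """A compact default study: 2 batches x 3 dense cultures, recorded every
    other day over 40 days in vitro."""
    days = list(range(1, 41, 2))
    rows = []
    for b in (1, 2):
        for c in range(1, 4):
            rows.append(
                {
                    "culture_id": f"{b}-{c}",
                    "batch_id": f"batch{b}",
                    "density_class": "dense",
                    "days": days,
                }
            )
    return StudyManifest(cultures=pd.DataFrame(rows))


def session_seed(master_seed: int, culture_index: int, day: int, kind: str) -> int:
    """Documented counter scheme deriving per-session seeds from one study
    seed, so any single session can be regenerated in isolation."""
    kind_code = {"latent": 0, "spontaneous": 1, "stimulation": 2}[kind]
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(culture_index, day, kind_code))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def batch_adjusted_schedule(
    schedule: GrowthSchedule,
    manifest: StudyManifest,
    culture_index: int,
    master_seed: int,
    batch_sd: float = 0.5,
    culture_sd: float = 0.02,
    density_class: Optional[str] = None,
) -> GrowthSchedule:
    """Schedule for one culture: batch-level lognormal offsets on plateau
    density and length scale (shared by all cultures of the batch) plus a
    small culture-level jitter.  This is the designed batch structure that
    makes trajectories more similar within batches than across them."""
    row = manifest.cultures.iloc[culture_index]
    batch_ids = list(dict.fromkeys(manifest.cultures["batch_id"]))
    b_idx = batch_ids.index(row["batch_id"])
    b_rng = np.random.default_rng(np.random.SeedSequence(entropy=master_seed, spawn_key=(10_000 + b_idx,)))
    c_rng = np.random.default_rng(np.random.SeedSequence(entropy=master_seed, spawn_key=(20_000 + culture_index,)))
    dens_mult = float(b_rng.lognormal(0.0, batch_sd) * c_rng.lognormal(0.0, culture_sd))
    len_mult = float(b_rng.lognormal(0.0, batch_sd) * c_rng.lognormal(0.0, culture_sd))
    return replace(
        schedule,
        plateau_density=min(1.0, schedule.plateau_density * dens_mult),
        length_scale_end_um=schedule.length_scale_end_um * len_mult,
        density_class=density_class or row["density_class"],
    )


def generate_study(
    manifest: StudyManifest,
    schedule: GrowthSchedule,
    seed: int,
    out_dir,
    protocol: StimProtocol = StimProtocol(),
    firing_params: FiringParams = FiringParams(),
    spontaneous_duration_s: float = 60.0,
    batch_sd: float = 0.5,
    culture_sd: float = 0.02,
) -> pd.DataFrame:
    """Generate and write a full longitudinal study to ``out_dir``.

    For each culture and recorded day, writes one stimulation session (spike
    + pulse CSVs), one spontaneous session (spike CSV) and the ground-truth
    latent edge list for validation.  Returns an index table of the files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    emap_path = out_dir / "electrode_map.csv"
    from .layout import standard_mea_layout

    emap = standard_mea_layout()
    mio.write_electrode_map(emap, emap_path)
    manifest.plating_metadata().to_csv(out_dir / "plating_metadata.csv", index=False)

    index_rows = []
    for ci, row in manifest.cultures.reset_index(drop=True).iterrows():
        cid, bid = row["culture_id"], row["batch_id"]
        csched = batch_adjusted_schedule(schedule, manifest, ci, seed, batch_sd, culture_sd)
        traj = generate_latent_trajectory(emap, csched, session_seed(seed, ci, 0, "latent"))
        for day in row["days"]:
            net = traj[day - 1]
            truth_path = out_dir / f"{cid}_d{day:02d}_truth_edges.csv"
            net.edges.to_csv(truth_path, index=False, float_format="%.6g")
            spont = simulate_spontaneous(
                emap, day, firing_params, spontaneous_duration_s,
                seed=session_seed(seed, ci, day, "spontaneous"),
                culture_id=cid, batch_id=bid,
            )
            sp_path = out_dir / f"{cid}_d{day:02d}_spont_spikes.csv"
            mio.write_spike_events(spont, sp_path)
            stim = simulate_stimulation_session(
                emap, net, protocol, firing_params,
                seed=session_seed(seed, ci, day, "stimulation"),
                culture_id=cid, batch_id=bid,
            )
            st_path = out_dir / f"{cid}_d{day:02d}_stim_spikes.csv"
            pu_path = out_dir / f"{cid}_d{day:02d}_stim_pulses.csv"
            mio.write_spike_events(stim, st_path, pu_path)
            index_rows.append(
                {
                    "culture_id": cid,
                    "batch_id": bid,
                    "day_in_vitro": day,
                    "spont_spikes": sp_path.name,
                    "spont_duration_s": spontaneous_duration_s,
                    "stim_spikes": st_path.name,
                    "stim_pulses": pu_path.name,
                    "truth_edges": truth_path.name,
                }
            )
    index = pd.DataFrame(index_rows)
    index.to_csv(out_dir / "sessions.csv", index=False)
    return index


@dataclass(frozen=True)
class MixtureSpec:
    """Two-group mixture for Z entries: null N(0, sigma^2) with probability
    1 - epsilon, else the non-null distribution f1 (normal by default)."""

    epsilon: float = 0.05
    sigma: float = 1.0
    f1_loc: float = 4.0
    f1_scale: float = 1.0
    f1_sampler: Optional[Callable[[np.random.Generator, int], np.ndarray]] = None
    dims: tuple[int, int] = (59, 59)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon <= 1.0):
            raise ValueError("epsilon must lie in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def generate_z_mixture(spec: MixtureSpec) -> tuple[ResponseMatrix, np.ndarray]:
    """Draw a Z matrix from the two-group mixture; returns (matrix, truth).

    ``truth`` is the boolean non-null mask for validating false-discovery
    control and parameter recovery.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.dims
    truth = rng.random((n, m)) < spec.epsilon
    z = rng.normal(0.0, spec.sigma, size=(n, m))
    k = int(truth.sum())
    if k:
        if spec.f1_sampler is not None:
            z[truth] = spec.f1_sampler(rng, k)
        else:
            z[truth] = rng.normal(spec.f1_loc, spec.f1_scale, size=k)
    ids = [f"e{i}" for i in range(max(n, m))][:n]
    rm = ResponseMatrix(
        z=z, electrode_ids=ids, window_ms=100.0, diagonal_policy="include"
    ) if n == m else None
    if rm is None:
        raise ValueError("mixture dims must be square to form a ResponseMatrix")
    return rm, truth
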