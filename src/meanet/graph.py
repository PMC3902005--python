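"""Connectivity graphs and the two summary metrics.

The significant stimulus-response pairs form a directed graph (stimulated
electrode -> recording electrode).  Two metrics summarize it per day:

* mean connection length — the average Euclidean distance (µm) between the
  stimulated and recording electrodes of significant pairs, a proxy for how
  far evoked activity propagates across the dish;
* supernode counts — the number of electrodes with at least four significant
  connections in a given direction (incoming or outgoing), i.e. functional
  hubs.  The threshold is applied per direction by default; a total-degree
  variant is available.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

from .data import DailyMetrics
from .fdr import LocalFdrResult
from .layout import ElectrodeMap

__all__ = [
    "build_graph",
    "mean_connection_length",
    "supernode_counts",
    "metrics_for_day",
    "edge_table",
]


def build_graph(mask: np.ndarray, emap: ElectrodeMap) -> nx.DiGraph:
    """Directed graph with one edge per true mask entry.

    Nodes are all analysis electrodes (isolated ones included); each edge
    carries its Euclidean length in micrometers as ``length_um``.
    """
    mask = np.asarray(mask, dtype=bool)
    ids = emap.analysis_ids
    if mask.shape != (len(ids), len(ids)):
        raise ValueError("mask dimensions do not match the electrode map")
    dist = emap.distance_matrix()
    g = nx.DiGraph()
    g.add_nodes_from(ids)
    for k, j in zip(*np.nonzero(mask)):
        g.add_edge(ids[k], ids[j], length_um=float(dist[k, j]))
    return g


def mean_connection_length(g: nx.DiGraph) -> float:
    """Arithmetic mean edge length in µm; NaN for an empty graph."""
    lengths = [d["length_um"] for _, _, d in g.edges(data=True)]
    return float(np.mean(lengths)) if lengths else float("nan")


def supernode_counts(
    g: nx.DiGraph, threshold: int = 4, mode: str = "per-direction"
) -> tuple[int, int]:
    """Count hub electrodes with at least ``threshold`` connections.

    ``"per-direction"`` (default) counts nodes with in-degree >= threshold
    and, separately, nodes with out-degree >= threshold (a node can count in
    both).  ``"total"`` applies the threshold to in+out degree and reports
    the same count twice.
    """
    if mode == "per-direction":
        n_in = sum(1 for _, d in g.in_degree() if d >= threshold)
        n_out = sum(1 for _, d in g.out_degree() if d >= threshold)
    elif mode == "total":
        n_tot = sum(1 for n in g.nodes if g.in_degree(n) + g.out_degree(n) >= threshold)
        n_in = n_out = n_tot
    else:
        raise ValueError(f"unknown supernode mode {mode!r}")
    return n_in, n_out


def metrics_for_day(
    fdr_result: LocalFdrResult,
    emap: ElectrodeMap,
    culture_id: str,
    day_in_vitro: int,
    window_ms: float,
    batch_id: str | None = None,
    supernode_threshold: int = 4,
    supernode_mode: str = "per-direction",
) -> DailyMetrics:
    """Compose graph construction and both metrics for one culture-day."""
    g = build_graph(fdr_result.significant_mask, emap)
    n_in, n_out = supernode_counts(g, threshold=supernode_threshold, mode=supernode_mode)
    return DailyMetrics(
        culture_id=culture_id,
        batch_id=batch_id,
        day_in_vitro=day_in_vitro,
        window_ms=window_ms,
        n_edges=g.number_of_edges(),
        mean_connection_length_um=mean_connection_length(g),
        n_incoming_supernodes=n_in,
        n_outgoing_supernodes=n_out,
    )


def edge_table(fdr_result: LocalFdrResult, z: np.ndarray, emap: ElectrodeMap) -> pd.DataFrame:
    """Significant-pair edge list: stim/rec electrode, Z and T per edge."""
    ids = emap.analysis_ids
    ks, js = np.nonzero(fdr_result.significant_mask)
    return pd.DataFrame(
        {
            "stim_electrode_id": [ids[k] for k in ks],
            "rec_electrode_id": [ids[j] for j in js],
            "z": np.asarray(z)[ks, js],
            "t": fdr_result.t[ks, js],
        }
    )
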