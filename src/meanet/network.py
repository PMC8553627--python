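"""Thresholded functional-connectivity graph and per-electrode metrics.

An undirected edge joins electrodes i and j iff their STTC is defined and
strictly exceeds the edge threshold (default 0.6); the STTC value is kept
as the edge weight.  Node degree is the binary degree of this thresholded
graph; each node also carries its firing rate (spikes per second) and spike
count.  Electrodes with undefined STTC (empty trains) stay in the graph
with degree 0 and are flagged, so the node count always equals the array
size.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import SpikeMatrix, SpikeTrain
from .errors import ValidationError
from .sttc import STTCMatrix

__all__ = [
    "firing_rate",
    "build_graph",
    "degree_distribution",
    "ConnectivityGraph",
    "NetworkBuilder",
]


def firing_rate(train: SpikeTrain) -> float:
    """Mean firing rate: spike count divided by the recording duration."""
    return train.firing_rate_hz


@dataclass(frozen=True)
class ConnectivityGraph:
    """Binary thresholded graph with STTC edge weights and node metrics."""

    graph: nx.Graph
    electrode_ids: tuple[int, ...]
    threshold: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def adjacency(self) -> np.ndarray:
        """Binary symmetric adjacency with zero diagonal, in electrode order."""
        a = nx.to_numpy_array(self.graph, nodelist=list(self.electrode_ids),
                              weight=None)
        return a.astype(np.int8)

    @property
    def degrees(self) -> np.ndarray:
        return np.array([self.graph.degree[i] for i in self.electrode_ids],
                        dtype=np.int64)

    @property
    def mean_degree(self) -> float:
        return float(self.degrees.mean())

    @property
    def edge_density(self) -> float:
        return float(nx.density(self.graph))

    def nodes_table(self) -> pd.DataFrame:
        rows = [
            {
                "electrode_id": i,
                "degree": self.graph.degree[i],
                "firing_rate_hz": self.graph.nodes[i]["firing_rate_hz"],
                "n_spikes": self.graph.nodes[i]["n_spikes"],
                "sttc_defined": self.graph.nodes[i]["sttc_defined"],
            }
            for i in self.electrode_ids
        ]
        return pd.DataFrame(rows)

    def to_graphml(self, path) -> None:
        """Export for external graph/visualization tools."""
        nx.write_graphml(self.graph, path)

    def edges_table(self) -> pd.DataFrame:
        rows = [{"source": u, "target": v, "sttc": d["weight"]}
                for u, v, d in self.graph.edges(data=True)]
        df = pd.DataFrame(rows, columns=["source", "target", "sttc"])
        return df.sort_values(["source", "target"]).reset_index(drop=True)


def build_graph(sttc: STTCMatrix, spike_matrix: SpikeMatrix | None = None,
                edge_threshold: float = 0.6) -> ConnectivityGraph:
    """Threshold the STTC matrix into a connectivity graph.

    The inequality is strict (an entry exactly at the threshold yields no
    edge) and NaN entries never create edges.
    """
    if spike_matrix is None:
        spike_matrix = sttc.spike_matrix
    if spike_matrix is None:
        raise ValidationError("a spike matrix is required to attach node metrics")
    if tuple(spike_matrix.electrode_ids) != tuple(sttc.electrode_ids):
        raise ValidationError("STTC matrix and spike matrix cover different electrodes")

    g = nx.Graph()
    for eid, train in zip(sttc.electrode_ids, spike_matrix):
        g.add_node(eid, firing_rate_hz=train.firing_rate_hz,
                   n_spikes=train.n_spikes,
                   sttc_defined=bool(train.n_spikes > 0))
    v = sttc.values
    n = sttc.n_electrodes
    for i in range(n):
        for j in range(i + 1, n):
            w = v[i, j]
            if np.isfinite(w) and w > edge_threshold:
                g.add_edge(sttc.electrode_ids[i], sttc.electrode_ids[j], weight=float(w))
    return ConnectivityGraph(g, sttc.electrode_ids, float(edge_threshold))


def degree_distribution(graph: ConnectivityGraph) -> np.ndarray:
    """Histogram of node degrees over the support ``0 .. N-1``; sums to N."""
    n = graph.n_nodes
    counts = np.bincount(graph.degrees, minlength=n)
    return counts[:n]


class NetworkBuilder(TransformerMixin, BaseEstimator):
    """Transformer thresholding an :class:`~meanet.sttc.STTCMatrix` into a graph.

    Parameters
    ----------
    edge_threshold : float, default=0.6
        Strict lower bound on STTC for an edge to exist.
    """

    def __init__(self, edge_threshold: float = 0.6):
        self.edge_threshold = edge_threshold

    def fit(self, X: STTCMatrix, y=None) -> "NetworkBuilder":
        if not 0.0 <= self.edge_threshold <= 1.0:
            raise ValidationError("edge_threshold must be in [0, 1]")
        self.electrode_ids_ = X.electrode_ids
        return self

    def transform(self, X: STTCMatrix) -> ConnectivityGraph:
        if not hasattr(self, "electrode_ids_"):
            self.fit(X)
        return build_graph(X, edge_threshold=self.edge_threshold)
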