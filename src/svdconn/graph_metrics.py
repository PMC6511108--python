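"""Whole-brain weighted network measures: density, global and local efficiency.

Connection weights are converted to lengths as 1/w (stronger connections are
"shorter"), and efficiencies average the inverse weighted shortest-path
distance, so disconnected node pairs contribute 0 rather than breaking the
average — disconnected pairs are common in small-vessel-disease networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .connectome import Connectome

__all__ = [
    "NetworkMetrics",
    "density",
    "global_efficiency",
    "local_efficiency",
    "compute_metrics",
]


@dataclass
class NetworkMetrics:
    density: float
    global_efficiency: float
    local_efficiency: float


def _weights(conn: Union[Connectome, np.ndarray]) -> np.ndarray:
    w = conn.weights if isinstance(conn, Connectome) else np.asarray(conn, dtype=float)
    if np.any(w < 0):
        raise ValueError("negative edge weight")
    return w


def density(conn: Union[Connectome, np.ndarray]) -> float:
    """Ratio of observed to possible edges, 2|E| / (n(n-1))."""
    w = _weights(conn)
    n = w.shape[0]
    if n < 2:
        raise ValueError("density needs at least 2 nodes")
    n_edges = int(np.count_nonzero(np.triu(w, k=1)))
    return n_edges / (n * (n - 1) / 2)

def _inverse_distance_sum(w: np.ndarray) -> float:
    """Sum over ordered pairs i != j of 1/d_ij with lengths 1/w; disconnected -> 0."""
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    d = shortest_path(lengths, method="D", directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0  # disconnected pairs and the diagonal
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum())


def global_efficiency(conn: Union[Connectome, np.ndarray]) -> float:
    """Average inverse weighted shortest-path length over all node pairs."""
    w = _weights(conn)
    n = w.shape[0]
    if n < 2:
        return 0.0
    return _inverse_distance_sum(w) / (n * (n - 1))


def local_efficiency(conn: Union[Connectome, np.ndarray]) -> float:
    """Mean over nodes of the global efficiency of the neighbor-induced subgraph.

    Neighbors are nodes joined by nonzero weight; the induced subgraph keeps
    the original weights. Nodes with fewer than 2 neighbors contribute 0.
    """
    w = _weights(conn)
    n = w.shape[0]
    if n < 2:
        raise ValueError("local efficiency needs at least 2 nodes")
    total = 0.0
    for i in range(n):
        nbrs = np.nonzero(w[i])[0]
        if len(nbrs) < 2:
            continue
        total += global_efficiency(w[np.ix_(nbrs, nbrs)])
    return total / n


def compute_metrics(conn: Union[Connectome, np.ndarray]) -> NetworkMetrics:
    return NetworkMetrics(density(conn), global_efficiency(conn), local_efficiency(conn))
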