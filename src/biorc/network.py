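"""Surrogate-validated functional connectivity and graph metrics.

Connectivity between two neurons is declared when the Pearson correlation of
their event-derived calcium curves exceeds the chosen percentile (default
99th, strict inequality) of a null distribution built by redrawing one
train's event times uniformly over the recording while preserving the event
count.  The resulting binary adjacency matrix is symmetrised by logical OR.

Graph summaries are global efficiency (mean inverse shortest-path length,
with 1/d = 0 for disconnected pairs), Louvain modularity with its partition,
the mean local clustering coefficient (zero for nodes of degree < 2), and
network density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from networkx.algorithms.community import louvain_communities, modularity

from . import kernels
from .imaging import EventTrain

__all__ = [
    "Adjacency",
    "NetworkMetrics",
    "DirectedGraph",
    "functional_connectivity",
    "correlation_matrix",
    "graph_metrics",
    "importance_graph",
]


@dataclass
class Adjacency:
    """Binary, symmetric, zero-diagonal functional-connectivity matrix."""

    matrix: np.ndarray
    node_ids: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.matrix)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have a zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be binary")
        self.matrix = a.astype(np.uint8)
        self.node_ids = np.asarray(self.node_ids)

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def to_networkx(self) -> nx.Graph:
        g = nx.from_numpy_array(self.matrix)
        return nx.relabel_nodes(g, dict(enumerate(self.node_ids.tolist())))


@dataclass
class NetworkMetrics:
    global_efficiency: float
    modularity: float
    partition: dict  # node -> community index
    clustering_coef: float
    density: float


@dataclass
class DirectedGraph:
    """Top-p importance digraph: i -> j for each of i's p best partners."""

    edges: np.ndarray  # (m, 2) ordered pairs
    in_degree: np.ndarray
    p: int

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.in_degree.size))
        g.add_edges_from(map(tuple, self.edges))
        return g


# --------------------------------------------------------------------------- #
# functional connectivity
# --------------------------------------------------------------------------- #


def _standardize(curves: np.ndarray) -> tuple:
    mu = curves.mean(axis=1, keepdims=True)
    dev = curves - mu
    sd = dev.std(axis=1)
    ok = sd > 1e-12
    z = np.zeros_like(curves)
    z[ok] = dev[ok] / (sd[ok, None] * np.sqrt(curves.shape[1]))
    return z, ok


def correlation_matrix(
    events: Sequence[EventTrain],
    duration: float,
    sample_rate: float = 10.0,
    rise_tau: float = 0.05,
    decay_tau: float = 0.6,
) -> np.ndarray:
    """Pairwise Pearson correlations of event-derived calcium curves."""
    n_samp = int(round(duration * sample_rate))
    times = np.arange(n_samp) / sample_rate
    curves = kernels.superpose_batch(
        [e.times for e in events], times, rise_tau, decay_tau
    )
    z, _ = _standardize(curves)
    cc = z @ z.T
    np.fill_diagonal(cc, 1.0)
    return cc


def functional_connectivity(
    events: Sequence[EventTrain],
    duration: float,
    sample_rate: float = 10.0,
    rise_tau: float = 0.05,
    decay_tau: float = 0.6,
    n_surrogates: int = 500,
    percentile: float = 99.0,
    seed: int = 0,
) -> Adjacency:
    """Build the binary functional-connectivity graph from event trains.

    For each ordered pair (i, j) the observed correlation is compared with
    the ``percentile``-th percentile of correlations between train i and
    ``n_surrogates`` uniform-redraw surrogates of train j (event counts
    preserved); the edge is set iff the observed value strictly exceeds that
    threshold, and the matrix is symmetrised by OR.  Trains with no events
    produce all-zero rows/columns with a warning.
    """
    n = len(events)
    if n < 2:
        raise ValueError("need at least two event trains")
    if n_surrogates < 100:
        raise ValueError("n_surrogates must be at least 100")

    n_samp = int(round(duration * sample_rate))
    times = np.arange(n_samp) / sample_rate
    curves = kernels.superpose_batch(
        [e.times for e in events], times, rise_tau, decay_tau
    )
    z, ok = _standardize(curves)
    if not ok.all():
        warnings.warn(
            "event trains with no events produce zero connectivity rows",
            RuntimeWarning,
        )
    cc = z @ z.T

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    a_dir = np.zeros((n, n), dtype=bool)
    for j in range(n):
        k = len(events[j])
        if k == 0 or not ok[j]:
            continue
        surr_times = np.sort(rng.uniform(0.0, duration, size=(n_surrogates, k)), axis=1)
        surr = kernels.superpose_batch(list(surr_times), times, rise_tau, decay_tau)
        zs, _ = _standardize(surr)
        null = z @ zs.T  # (n, n_surrogates): corr of each i with surrogates of j
        thresh = np.percentile(null, percentile, axis=1)
        a_dir[:, j] = cc[:, j] > thresh
    a = (a_dir | a_dir.T).astype(np.uint8)
    np.fill_diagonal(a, 0)
    a[~ok, :] = 0
    a[:, ~ok] = 0
    return Adjacency(matrix=a, node_ids=np.arange(n))


# --------------------------------------------------------------------------- #
# graph metrics
# --------------------------------------------------------------------------- #


def graph_metrics(
    adj, seed: int = 0, n_louvain_restarts: int = 8
) -> NetworkMetrics:
    """Global efficiency, Louvain modularity, mean clustering, density.

    Modularity is maximised with several seeded Louvain restarts and the
    best-Q partition is reported, which makes the result deterministic per
    seed and reliably optimal on small graphs.
    """
    if isinstance(adj, Adjacency):
        a = adj.matrix
    else:
        a = np.asarray(adj)
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency matrix must be symmetric")
        adj = Adjacency(matrix=a, node_ids=np.arange(a.shape[0]))
        a = adj.matrix
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least two nodes")

    g = nx.from_numpy_array(a)
    ge = nx.global_efficiency(g)
    density = nx.density(g)
    clustering = float(np.mean(list(nx.clustering(g).values())))

    if g.number_of_edges() == 0:
        partition = {v: i for i, v in enumerate(g.nodes())}
        q = 0.0
    else:
        seeds = np.random.SeedSequence(seed).generate_state(n_louvain_restarts)
        best = None
        for s in seeds:
            comms = louvain_communities(g, seed=int(s % (2**31)))
            qv = modularity(g, comms)
            if best is None or qv > best[0] + 1e-12:
                best = (qv, comms)
        q, comms = best
        partition = {}
        for ci, comm in enumerate(sorted(comms, key=min)):
            for v in comm:
                partition[v] = ci
    return NetworkMetrics(
        global_efficiency=float(ge),
        modularity=float(q),
        partition=partition,
        clustering_coef=clustering,
        density=float(density),
    )


def importance_graph(cc_matrix: np.ndarray, p: int) -> DirectedGraph:
    """Directed edges from each node to its p most-correlated partners.

    Ties are broken toward the lower node index.  In-degree (incoming edge
    count) serves as the node-importance proxy.
    """
    cc = np.asarray(cc_matrix, dtype=float)
    if cc.ndim != 2 or cc.shape[0] != cc.shape[1]:
        raise ValueError("cc_matrix must be square")
    if not np.allclose(cc, cc.T, atol=1e-10):
        raise ValueError("cc_matrix must be symmetric")
    n = cc.shape[0]
    if not (1 <= p < n):
        raise ValueError("require 1 <= p < n")

    edges = []
    idx = np.arange(n)
    for i in range(n):
        row = cc[i].copy()
        row[i] = -np.inf
        order = np.lexsort((idx, -row))  # descending correlation, then low index
        for j in order[:p]:
            edges.append((i, int(j)))
    edges = np.asarray(edges, dtype=int)
    in_degree = np.bincount(edges[:, 1], minlength=n)
    return DirectedGraph(edges=edges, in_degree=in_degree, p=p)
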