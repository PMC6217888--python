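"""Weighted, undirected network-architecture metrics.

Four whole-graph summaries, following Brain Connectivity Toolbox conventions
for weighted undirected matrices:

- clustering coefficient (segregation): mean over nodes of the Onnela
  geometric-mean triangle intensity, weights normalised by the graph maximum;
- modularity (segregation): Newman modularity Q of the partition found by
  deterministic leading-eigenvector splitting with Kernighan-Lin refinement;
- characteristic path length (integration): mean shortest-path distance on
  reciprocal-weight edge lengths over reachable ordered pairs;
- global efficiency (integration): mean inverse shortest-path distance, with
  1/inf = 0 for unreachable pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "WeightedGraph",
    "NetworkMetrics",
    "weight_to_length",
    "clustering_coefficient",
    "modularity",
    "modularity_partition",
    "modularity_value",
    "characteristic_path_length",
    "global_efficiency",
    "subject_metrics",
]


@dataclass
class WeightedGraph:
    """Symmetric nonnegative weight matrix with exactly-zero diagonal."""

    weights: np.ndarray
    node_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.isfinite(w).all():
            raise ValueError("weights must be finite")
        if np.abs(w - w.T).max(initial=0.0) > 1e-12:
            raise ValueError("weights must be symmetric to 1e-12")
        if np.diagonal(w).any():
            raise ValueError("diagonal must be exactly zero")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        self.weights = (w + w.T) / 2.0
        np.fill_diagonal(self.weights, 0.0)
        if self.node_ids is None:
            self.node_ids = tuple(f"n{i:03d}" for i in range(w.shape[0]))
        else:
            self.node_ids = tuple(str(t) for t in self.node_ids)
            if len(self.node_ids) != w.shape[0]:
                raise ValueError("node_ids length must match the matrix size")

    @classmethod
    def from_connectivity(cls, cm) -> "WeightedGraph":
        return cls(weights=cm.weights, node_ids=cm.node_ids)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class NetworkMetrics:
    """The four per-subject architecture summaries plus a connectedness flag."""

    clustering_coefficient: float
    modularity: float
    path_length: float
    global_efficiency: float
    connected: bool

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.clustering_coefficient,
                self.modularity,
                self.path_length,
                self.global_efficiency,
            ]
        )


#: Feature order used throughout prediction and reporting.
METRIC_NAMES = (
    "clustering_coefficient",
    "modularity",
    "path_length",
    "global_efficiency",
)


def weight_to_length(g: WeightedGraph) -> np.ndarray:
    """Map weights to edge lengths: 1/w for w > 0, +inf for absent edges, 0 on the diagonal."""
    w = g.weights
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    return lengths


def clustering_coefficient(g: WeightedGraph) -> float:
    """Mean weighted clustering coefficient (Onnela geometric-mean form).

    Weights are normalised by the graph-wide maximum, so the value is
    invariant to uniform rescaling; nodes with degree < 2 contribute 0.
    """
    if g.n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    w = g.weights
    mx = w.max()
    if mx == 0.0:
        warnings.warn("all-zero graph: clustering coefficient is 0", stacklevel=2)
        return 0.0
    cw = np.cbrt(w / mx)
    cyc3 = np.einsum("ij,jk,ki->i", cw, cw, cw)
    deg = (w > 0).sum(axis=1)
    denom = deg * (deg - 1)
    per_node = np.where(denom > 0, cyc3 / np.where(denom > 0, denom, 1), 0.0)
    return float(per_node.mean())


def modularity_value(weights: np.ndarray, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Newman modularity Q of a given partition (direct evaluation)."""
    w = np.asarray(weights, dtype=np.float64)
    s_tot = w.sum()
    if s_tot <= 0:
        raise ValueError("modularity undefined for a graph with no weight")
    k = w.sum(axis=1)
    b = w - gamma * np.outer(k, k) / s_tot
    q = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        q += b[np.ix_(idx, idx)].sum()
    return float(q / s_tot)


def _refine_split(bg: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, float]:
    """Kernighan-Lin style fine-tuning of a two-way split.

    Maximises s^T Bg s by greedy single-node moves (each node moved at most
    once per pass, best prefix kept); deterministic given the input vector.
    """
    n = s.size
    diag = np.diagonal(bg).copy()
    best_s = s.copy()
    best_obj = float(best_s @ bg @ best_s)
    improved = True
    while improved:
        improved = False
        s_work = best_s.copy()
        obj = best_obj
        moved = np.zeros(n, dtype=bool)
        trail_obj = np.empty(n)
        trail_s = np.empty((n, n))
        for step in range(n):
            gains = -4.0 * s_work * (bg @ s_work) + 4.0 * diag
            gains[moved] = -np.inf
            i = int(np.argmax(gains))
            obj += gains[i]
            s_work[i] = -s_work[i]
            moved[i] = True
            trail_obj[step] = obj
            trail_s[step] = s_work
        j = int(np.argmax(trail_obj))
        if trail_obj[j] > best_obj + 1e-12:
            best_obj = float(trail_obj[j])
            best_s = trail_s[j].copy()
            improved = True
    return best_s, best_obj


def modularity_partition(
    g: WeightedGraph, gamma: float = 1.0
) -> tuple[np.ndarray, float]:
    """Community labels and modularity Q by recursive spectral bisection.

    Leading-eigenvector splitting of the (generalised) modularity matrix with
    Kernighan-Lin refinement; entirely deterministic.  The trivial
    one-community partition has Q = 0, so Q >= 0 always.
    """
    w = g.weights
    s_tot = w.sum()
    if s_tot <= 0:
        raise ValueError("modularity undefined for a graph with no weight")
    n = g.n_nodes
    k = w.sum(axis=1)
    b = w - gamma * np.outer(k, k) / s_tot

    labels = np.zeros(n, dtype=np.int64)
    next_label = 1
    queue = [np.arange(n)]
    while queue:
        idx = queue.pop()
        if idx.size < 2:
            continue
        bg = b[np.ix_(idx, idx)].copy()
        rs = bg.sum(axis=1)
        bg[np.diag_indices_from(bg)] -= rs
        vals, vecs = scipy.linalg.eigh(bg)
        if vals[-1] <= 1e-12:
            continue  # indivisible subgraph
        lead = vecs[:, -1]
        s = np.where(lead >= 0, 1.0, -1.0)
        s, obj = _refine_split(bg, s)
        if obj <= 1e-12 or np.all(s == s[0]):
            continue
        neg = idx[s < 0]
        labels[neg] = next_label
        next_label += 1
        queue.append(idx[s > 0])
        queue.append(neg)
    return labels, modularity_value(w, labels, gamma)


def modularity(g: WeightedGraph, gamma: float = 1.0) -> float:
    """Modularity Q of the partition found by :func:`modularity_partition`."""
    return modularity_partition(g, gamma)[1]


def _pair_distances(g: WeightedGraph) -> np.ndarray:
    lengths = weight_to_length(g)
    # csgraph dense convention: 0 = no edge; true lengths are strictly positive
    dense = np.where(np.isinf(lengths), 0.0, lengths)
    return shortest_path(dense, method="D", directed=False)


def characteristic_path_length(g: WeightedGraph) -> float:
    """Mean shortest-path distance over reachable ordered pairs (self-pairs excluded)."""
    if g.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    d = _pair_distances(g)
    off = d[~np.eye(g.n_nodes, dtype=bool)]
    finite = off[np.isfinite(off)]
    if finite.size == 0:
        raise ValueError("no finite pair distances (empty graph)")
    return float(finite.mean())


def global_efficiency(g: WeightedGraph) -> float:
    """Mean inverse shortest-path distance over ordered pairs, with 1/inf = 0."""
    if g.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    d = _pair_distances(g)
    off = d[~np.eye(g.n_nodes, dtype=bool)]
    with np.errstate(divide="ignore"):
        inv = np.where(off > 0, 1.0 / off, np.inf)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def subject_metrics(g: WeightedGraph) -> NetworkMetrics:
    """Bundle the four architecture metrics plus the connectedness flag."""
    d = _pair_distances(g)
    off = d[~np.eye(g.n_nodes, dtype=bool)]
    connected = bool(np.isfinite(off).all())
    return NetworkMetrics(
        clustering_coefficient=clustering_coefficient(g),
        modularity=modularity(g),
        path_length=characteristic_path_length(g),
        global_efficiency=global_efficiency(g),
        connected=connected,
    )
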