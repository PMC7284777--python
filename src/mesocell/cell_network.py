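"""Spatial cell-network construction and small-world statistics.

Detected cell nodes are wired with the Waxman rule, in which the probability
of a link between nodes u and v decays exponentially with their Euclidean
distance d::

    P(u, v) = alpha * exp(-d / (beta * L))

with L the largest possible distance between two nodes of the grid.  A link
is kept whenever ``P(u, v) - R >= 0`` for a fixed acceptance constant R,
which makes the rule deterministic and equivalent to thresholding the
distance at::

    d* = beta * L * ln(alpha / R)

From the resulting undirected graph we compute the clustering coefficient
(Cc, Watts-Strogatz local coefficient averaged over nodes), the
characteristic path length (Cpl, mean shortest hop distance over reachable
pairs), and the small-world-ness

    SW = (Cc / Cc_rand) / (Cpl / Cpl_rand)

where the *_rand references are ensemble means over Erdos-Renyi G(n, m)
graphs with the same number of nodes and edges.  SW > 1 indicates
small-world organization: high local clustering at short path lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field
from typing import Any

import networkx as nx
import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import squareform, pdist

from .errors import ParameterError
from .nuclei_graph import ImageGrid, NodeSet, SegmentationParams, detect_nodes_from_image

__all__ = [
    "WaxmanParams",
    "CellGraph",
    "NullMetrics",
    "GraphMetrics",
    "field_diagonal",
    "waxman_cutoff",
    "build_graph",
    "clustering_coefficient",
    "characteristic_path_length",
    "er_null_metrics",
    "small_world_ness",
    "analyze_graph",
    "analyze_positions",
    "analyze_image",
]


@dataclass(frozen=True)
class WaxmanParams:
    """Waxman link-rule parameters.

    alpha, beta in (0, 1] control link density (small values, fewer links);
    R in (0, alpha) is the acceptance constant; L (um) is the largest
    possible Euclidean distance between two grid nodes, normally the
    diagonal of the imaged field.
    """

    alpha: float = 1.0
    beta: float = 0.025
    R: float = 0.1
    L: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ParameterError(f"alpha must be in (0, 1], got {self.alpha}")
        if not (0 < self.beta <= 1):
            raise ParameterError(f"beta must be in (0, 1], got {self.beta}")
        if not (0 < self.R < 1):
            raise ParameterError(f"R must be in (0, 1), got {self.R}")
        if self.R >= self.alpha:
            raise ParameterError(
                f"R must be < alpha for the cutoff to exist, got R={self.R}, alpha={self.alpha}"
            )
        if self.L <= 0:
            raise ParameterError(f"L must be > 0, got {self.L}")


@dataclass
class CellGraph:
    """Undirected spatial graph: node positions plus binary adjacency."""

    positions_um: np.ndarray      # (N, 2)
    adjacency: np.ndarray         # (N, N) bool, symmetric, zero diagonal
    params: WaxmanParams
    nodes: NodeSet | None = None  # provenance, if built from an image

    @property
    def n(self) -> int:
        return int(self.adjacency.shape[0])

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def distances_um(self) -> np.ndarray:
        return squareform(pdist(self.positions_um)) if self.n > 1 else np.zeros((self.n, self.n))

    def to_networkx(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency.astype(np.int8))
        g.remove_edges_from(nx.selfloop_edges(g))
        return g


@dataclass(frozen=True)
class NullMetrics:
    """Ensemble mean +/- sd of Cc and Cpl over G(n, m) random graphs."""

    cc_mean: float
    cc_sd: float
    cpl_mean: float
    cpl_sd: float
    reps: int


@dataclass
class GraphMetrics:
    """Full topological summary of one cell network."""

    n: int
    n_edges: int
    cc: float
    cpl: float
    cc_rand: float
    cc_rand_sd: float
    cpl_rand: float
    cpl_rand_sd: float
    sw: float
    null_reps: int
    seed: int
    params: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def field_diagonal(width_um: float, height_um: float) -> float:
    """Largest possible Euclidean distance in a rectangular field."""
    if width_um <= 0 or height_um <= 0:
        raise ParameterError("field dimensions must be positive")
    return math.hypot(width_um, height_um)


def waxman_cutoff(params: WaxmanParams) -> float:
    """Distance d* (um) below which the Waxman rule accepts a link.

    Solving alpha*exp(-d/(beta*L)) - R >= 0 for d gives
    d* = beta*L*ln(alpha/R); the rule holds iff d <= d*.
    """
    return params.beta * params.L * math.log(params.alpha / params.R)


def build_graph(nodes: NodeSet | np.ndarray, params: WaxmanParams) -> CellGraph:
    """Deterministic Waxman graph: link node pairs closer than the cutoff."""
    if isinstance(nodes, NodeSet):
        positions = nodes.positions_um
        node_set = nodes
    else:
        positions = np.asarray(nodes, dtype=float)
        node_set = None
    n = positions.shape[0]
    adj = np.zeros((n, n), dtype=bool)
    if n > 1:
        d = squareform(pdist(positions))
        adj = d <= waxman_cutoff(params)
        np.fill_diagonal(adj, False)
    return CellGraph(positions_um=positions, adjacency=adj, params=params, nodes=node_set)


def clustering_coefficient(graph: CellGraph | np.ndarray) -> float:
    """Average Watts-Strogatz local clustering coefficient.

    Per node: realized links among its neighbours over deg*(deg-1)/2
    possible ones; nodes of degree < 2 contribute 0.  Empty graph -> 0.
    """
    adj = graph.adjacency if isinstance(graph, CellGraph) else np.asarray(graph)
    if adj.shape[0] == 0:
        return 0.0
    g = nx.from_numpy_array(adj.astype(np.int8))
    return float(nx.average_clustering(g, count_zeros=True))


def characteristic_path_length(graph: CellGraph | np.ndarray) -> float:
    """Mean shortest hop distance over reachable node pairs.

    Self pairs are excluded; unreachable pairs (disconnected graphs) are
    excluded rather than counted as infinite, so fragmented layouts still
    yield a finite Cpl.  A graph with no edges has no reachable pairs and
    returns NaN.
    """
    adj = graph.adjacency if isinstance(graph, CellGraph) else np.asarray(graph)
    n = adj.shape[0]
    if n < 2 or not adj.any():
        return float("nan")
    hops = shortest_path(csr_array(adj.astype(np.int8)), method="D", unweighted=True)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(hops) & off
    if not finite.any():
        return float("nan")
    return float(hops[finite].mean())


def er_null_metrics(n: int, m: int, reps: int = 20, seed: int = 0) -> NullMetrics:
    """Cc and Cpl references from uniform G(n, m) Erdos-Renyi graphs.

    Each realization has exactly the node and edge count of the graph under
    study; Cpl is averaged over reachable pairs per realization.
    """
    if reps < 1:
        raise ParameterError(f"reps must be >= 1, got {reps}")
    max_m = n * (n - 1) // 2
    if not (0 <= m <= max_m):
        raise ParameterError(f"m must be in [0, {max_m}] for n={n}, got {m}")
    rng = np.random.default_rng(seed)
    ccs, cpls = [], []
    for _ in range(reps):
        g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
        ccs.append(nx.average_clustering(g, count_zeros=True) if n else 0.0)
        adj = nx.to_numpy_array(g, dtype=np.int8)
        cpls.append(characteristic_path_length(adj))
    ccs = np.asarray(ccs)
    cpls = np.asarray(cpls)
    cpl_ok = np.isfinite(cpls)
    return NullMetrics(
        cc_mean=float(ccs.mean()),
        cc_sd=float(ccs.std(ddof=1)) if reps > 1 else 0.0,
        cpl_mean=float(cpls[cpl_ok].mean()) if cpl_ok.any() else float("nan"),
        cpl_sd=float(cpls[cpl_ok].std(ddof=1)) if cpl_ok.sum() > 1 else 0.0,
        reps=reps,
    )


def small_world_ness(cc: float, cc_rand: float, cpl: float, cpl_rand: float) -> float:
    """SW = (Cc/Cc_rand) / (Cpl/Cpl_rand); NaN if any input is not positive."""
    vals = (cc, cc_rand, cpl, cpl_rand)
    if any((not np.isfinite(v)) or v <= 0 for v in vals):
        return float("nan")
    return (cc / cc_rand) / (cpl / cpl_rand)


def analyze_graph(graph: CellGraph, reps: int = 20, seed: int = 0) -> GraphMetrics:
    """Metrics of a built graph against its own-size ER null ensemble."""
    cc = clustering_coefficient(graph)
    cpl = characteristic_path_length(graph)
    if graph.n > 0 and graph.n_edges > 0:
        null = er_null_metrics(graph.n, graph.n_edges, reps=reps, seed=seed)
    else:
        null = NullMetrics(float("nan"), float("nan"), float("nan"), float("nan"), reps)
    sw = small_world_ness(cc, null.cc_mean, cpl, null.cpl_mean)
    return GraphMetrics(
        n=graph.n,
        n_edges=graph.n_edges,
        cc=cc,
        cpl=cpl,
        cc_rand=null.cc_mean,
        cc_rand_sd=null.cc_sd,
        cpl_rand=null.cpl_mean,
        cpl_rand_sd=null.cpl_sd,
        sw=sw,
        null_reps=reps,
        seed=seed,
        params=asdict(graph.params),
    )


def analyze_positions(
    positions_um: np.ndarray,
    field_size_um: tuple[float, float],
    waxman: WaxmanParams | None = None,
    reps: int = 20,
    seed: int = 0,
) -> GraphMetrics:
    """Build and analyze the Waxman network of a set of cell positions."""
    if waxman is None:
        waxman = WaxmanParams(L=field_diagonal(*field_size_um))
    graph = build_graph(np.asarray(positions_um, dtype=float), waxman)
    return analyze_graph(graph, reps=reps, seed=seed)


def analyze_image(
    img: ImageGrid,
    seg_params: SegmentationParams | None = None,
    waxman: WaxmanParams | None = None,
    reps: int = 20,
    seed: int = 0,
) -> GraphMetrics:
    """Full pipeline: segment -> occupancy -> nodes -> graph -> metrics.

    ``L`` defaults to the diagonal of the imaged field (largest possible
    node-to-node distance), computed from the field extent rather than from
    the realized nodes so that sparse detections do not shrink the cutoff.
    """
    if seg_params is None:
        seg_params = SegmentationParams()
    nodes = detect_nodes_from_image(img, seg_params)
    if waxman is None:
        waxman = WaxmanParams(L=field_diagonal(*img.field_size_um))
    graph = build_graph(nodes, waxman)
    metrics = analyze_graph(graph, reps=reps, seed=seed)
    metrics.params.update(
        {
            "k": seg_params.k,
            "t": seg_params.t,
            "r": seg_params.r,
            "p_thresh": seg_params.p_thresh,
            "invert": seg_params.invert,
        }
    )
    return metrics
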