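"""District spatial graphs and the neighbor-averaged design operator.

Districts are nodes; an undirected edge means two districts share a border or
a direct road/bridge. Hop distances on the binary graph induce exponentially
decaying weights ``w_ij = exp(-(d_ij - 1))`` so that immediate neighbors have
weight 1 and remote districts are discounted. The neighbor-design operator
replaces each district's covariates with the (weighted) mean over its
neighbors; it is the spatial term of the SP and WSP regression models.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

#: Edge list for an 18-district Hong Kong-like road network. Reconstructed
#: from public district geography (borders, tunnels and bridges); a fixture,
#: not authoritative ground truth.
HK_DISTRICTS = [
    "Islands", "Kwai Tsing", "North", "Sai Kung", "Sha Tin", "Tai Po",
    "Tsuen Wan", "Tuen Mun", "Yuen Long", "Kowloon City", "Kwun Tong",
    "Sham Shui Po", "Wong Tai Sin", "Yau Tsim Mong", "Central & Western",
    "Eastern", "Southern", "Wan Chai",
]

HK_EDGES = [
    ("Islands", "Kwai Tsing"), ("Islands", "Tsuen Wan"),
    ("Kwai Tsing", "Tsuen Wan"), ("Kwai Tsing", "Sham Shui Po"),
    ("Tsuen Wan", "Tuen Mun"), ("Tsuen Wan", "Sha Tin"),
    ("Tsuen Wan", "Yuen Long"), ("Tuen Mun", "Yuen Long"),
    ("Yuen Long", "North"), ("North", "Tai Po"), ("Tai Po", "Sha Tin"),
    ("Sha Tin", "Sai Kung"), ("Sha Tin", "Wong Tai Sin"),
    ("Sha Tin", "Kowloon City"), ("Sai Kung", "Kwun Tong"),
    ("Wong Tai Sin", "Kowloon City"), ("Wong Tai Sin", "Kwun Tong"),
    ("Kowloon City", "Kwun Tong"), ("Kowloon City", "Yau Tsim Mong"),
    ("Kowloon City", "Sham Shui Po"), ("Kowloon City", "Wan Chai"),
    ("Sham Shui Po", "Yau Tsim Mong"),
    ("Yau Tsim Mong", "Central & Western"),
    ("Central & Western", "Wan Chai"), ("Central & Western", "Southern"),
    ("Wan Chai", "Eastern"), ("Wan Chai", "Southern"),
    ("Eastern", "Southern"), ("Eastern", "Kwun Tong"),
]


class GraphError(ValueError):
    pass


def edge_weight(d) -> float:
    """Exponential distance decay ``exp(-(d - 1))`` for hop distance d >= 1."""
    d = float(d)
    if np.isinf(d):
        return 0.0
    if d < 1:
        raise GraphError(f"hop distance must be >= 1, got {d}")
    return float(np.exp(-(d - 1.0)))


@dataclass
class SpatialGraph:
    labels: list
    A: np.ndarray  # binary adjacency with unit diagonal
    D: np.ndarray  # hop distances (np.inf for unreachable)
    W: np.ndarray  # exponential weights, zero diagonal
    ego: object = None  # set on ego-network subgraphs

    @property
    def n(self) -> int:
        return len(self.labels)

    def neighbors(self, label) -> list:
        i = self.index(label)
        return [self.labels[j] for j in range(self.n)
                if self.A[i, j] and j != i]

    def index(self, label) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise GraphError(f"unknown district {label!r}") from None

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.labels)
        n = self.n
        for i in range(n):
            for j in range(i + 1, n):
                if self.A[i, j]:
                    g.add_edge(self.labels[i], self.labels[j])
        return g


def build_graph(edges, labels) -> SpatialGraph:
    """Build a district graph from an undirected edge list.

    Self-edges are ignored and duplicate edges collapse; every node must end
    up with at least one neighbor.
    """
    labels = list(labels)
    if len(set(labels)) != len(labels):
        raise GraphError("duplicate node labels")
    if len(labels) < 2:
        raise GraphError("need at least 2 nodes")
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    A = np.eye(n)
    for a, b in edges:
        if a not in index or b not in index:
            missing = a if a not in index else b
            raise GraphError(f"edge endpoint {missing!r} is not a known district")
        if a == b:
            continue
        A[index[a], index[b]] = A[index[b], index[a]] = 1.0
    degree = A.sum(axis=1) - 1
    if np.any(degree == 0):
        i = int(np.argwhere(degree == 0)[0][0])
        raise GraphError(f"district {labels[i]!r} has no neighbors")

    g = nx.from_numpy_array(A - np.eye(n))
    D = np.full((n, n), np.inf)
    for i, dists in nx.all_pairs_shortest_path_length(g):
        for j, d in dists.items():
            D[i, j] = d
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(D[i, j]):
                W[i, j] = edge_weight(D[i, j])
    return SpatialGraph(labels, A, D, W)


def hk_graph() -> SpatialGraph:
    """The bundled 18-district Hong Kong-like fixture graph."""
    return build_graph(HK_EDGES, HK_DISTRICTS)


def read_edge_list(path, labels=None) -> SpatialGraph:
    df = pd.read_csv(path)
    if not {"source", "target"} <= set(df.columns):
        raise GraphError("edge list CSV needs 'source' and 'target' columns")
    edges = list(zip(df["source"], df["target"]))
    if labels is None:
        labels = list(dict.fromkeys([x for pair in edges for x in pair]))
    return build_graph(edges, labels)


def write_edge_list(graph: SpatialGraph, path) -> None:
    rows = []
    n = graph.n
    for i in range(n):
        for j in range(i + 1, n):
            if graph.A[i, j]:
                rows.append({"source": graph.labels[i], "target": graph.labels[j]})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_graphml(path, labels=None) -> SpatialGraph:
    g = nx.read_graphml(path)
    if labels is None:
        labels = list(g.nodes)
    return build_graph(list(g.edges), labels)


def write_graphml(graph: SpatialGraph, path) -> None:
    nx.write_graphml(graph.to_networkx(), path)


def neighbor_design(X_t: np.ndarray, graph: SpatialGraph, mode: str = "sp") -> np.ndarray:
    """Neighbor-average of the non-intercept predictors of a design matrix.

    ``sp`` averages over immediate neighbors with equal weight; ``wsp`` is a
    row-normalized weighted mean over all reachable districts using the
    exponential distance-decay weights. The intercept column is dropped: the
    spatial term of the model carries no intercept.
    """
    X_t = np.asarray(X_t, dtype=float)
    if X_t.shape[0] != graph.n:
        raise GraphError(f"design has {X_t.shape[0]} rows, graph has {graph.n} nodes")
    if not np.allclose(X_t[:, 0], 1.0):
        raise GraphError("first design column must be the intercept (all ones)")
    Z = X_t[:, 1:]
    if mode == "sp":
        Wm = graph.A - np.eye(graph.n)
    elif mode == "wsp":
        Wm = graph.W.copy()
    else:
        raise GraphError(f"unknown mode {mode!r}; expected 'sp' or 'wsp'")
    rowsum = Wm.sum(axis=1)
    if np.any(rowsum <= 0):
        i = int(np.argwhere(rowsum <= 0)[0][0])
        raise GraphError(f"district {graph.labels[i]!r} has zero total neighbor weight")
    return (Wm / rowsum[:, None]) @ Z


def average_clustering(graph: SpatialGraph) -> float:
    """Mean local clustering coefficient of the binary graph."""
    return float(nx.average_clustering(graph.to_networkx()))


def ego_network(graph: SpatialGraph, node) -> SpatialGraph:
    """Induced subgraph on a node and its immediate neighbors."""
    i = graph.index(node)
    keep = [j for j in range(graph.n) if graph.A[i, j] == 1.0]
    labels = [graph.labels[j] for j in keep]
    edges = []
    for a in range(len(keep)):
        for b in range(a + 1, len(keep)):
            if graph.A[keep[a], keep[b]]:
                edges.append((labels[a], labels[b]))
    sub = build_graph(edges, labels)
    sub.ego = node
    return sub
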