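"""Spanning-tree backbone extraction and tree topology metrics.

The analysis backbone of a PLI network is its maximum-weight spanning tree:
the acyclic connected subgraph that keeps the strongest couplings (for
distance-like weights this is the classical minimum spanning tree; PLI is a
similarity, so the maximum-weight tree is the same object). On N nodes the
tree always has M = N - 1 edges, which removes the arbitrary threshold step
of conventional network analysis and makes trees comparable across subjects
and conditions.

Metric conventions, for a tree with N nodes and M = N - 1 edges:

* degree_max = max_i k_i / M, with k_i the raw degree;
* leaf fraction Lf = L / M, with L the number of degree-1 nodes;
* betweenness centrality BC_i = (1 / ((N-1)(N-2))) * sum over ordered pairs
  (h, j), h != i != j, of the fraction of shortest h-j paths through i; in a
  tree each pair has a unique path, so BC_i counts separated pairs. bc_max is
  its maximum;
* diameter D = d / M with d the largest pairwise distance, eccentricity the
  per-node largest distance, averaged over nodes and divided by M;
* tree hierarchy Th = L / (2 * M * bc_max), which is 0.5 for a perfect star
  and captures the trade-off between integration (many leaves) and hub
  overload (high bc_max).

Two distance conventions are supported for diameter/eccentricity: ``hop``
(every edge has length 1) and ``weighted`` (edge length 1 - PLI, so strong
couplings are short). The weighted convention is the default; see the
methods note for why.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix

__all__ = [
    "TreeMetrics",
    "METRIC_NAMES",
    "kruskal_max_tree",
    "max_spanning_tree",
    "node_betweenness",
    "tree_metrics",
    "validate_tree",
    "write_tree_csv",
    "read_tree_csv",
]

#: Column order of the long-format metric table.
METRIC_NAMES: tuple[str, ...] = (
    "mpli",
    "degree_max",
    "bc_max",
    "leaf_fraction",
    "diameter",
    "eccentricity",
    "tree_hierarchy",
)


@dataclass(frozen=True)
class TreeMetrics:
    """The per-tree summary statistics (normalized as documented above)."""

    mpli: float | None
    degree_max: float
    bc_max: float
    leaf_fraction: float
    diameter: float
    eccentricity: float
    tree_hierarchy: float | None
    distance_convention: str = "weighted"

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


# ---------------------------------------------------------------------------
# Kruskal
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1
        return True


def kruskal_max_tree(
    weights: np.ndarray, node_labels: Sequence[str] | None = None
) -> nx.Graph:
    """Maximum-weight spanning tree of a symmetric weight matrix (Kruskal).

    Edges are ranked from highest to lowest weight and added whenever they
    join two components, until all nodes are connected without a cycle.
    Equal-weight edges are broken by lexicographic (i, j) node-index order,
    which makes the result deterministic.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"weight matrix must be square, got {w.shape}")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    n = w.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    labels = list(node_labels) if node_labels is not None else list(range(n))
    if len(labels) != n:
        raise ValueError("node label count does not match matrix size")

    iu, ju = np.triu_indices(n, k=1)
    order = sorted(range(len(iu)), key=lambda k: (-w[iu[k], ju[k]], iu[k], ju[k]))
    uf = _UnionFind(n)
    tree = nx.Graph()
    tree.add_nodes_from(labels)
    added = 0
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        if uf.union(i, j):
            tree.add_edge(labels[i], labels[j], weight=float(w[i, j]))
            added += 1
            if added == n - 1:
                break
    return tree


def max_spanning_tree(matrix: ConnectivityMatrix | np.ndarray,
                      node_labels: Sequence[str] | None = None) -> nx.Graph:
    """Maximum-PLI spanning tree of a connectivity matrix."""
    if isinstance(matrix, ConnectivityMatrix):
        return kruskal_max_tree(matrix.values, list(matrix.channel_names))
    return kruskal_max_tree(np.asarray(matrix), node_labels)


def validate_tree(tree: nx.Graph) -> None:
    """Assert the spanning-tree invariants: connected, acyclic, M = N - 1."""
    n = tree.number_of_nodes()
    if tree.number_of_edges() != n - 1:
        raise ValueError(
            f"tree has {tree.number_of_edges()} edges for {n} nodes; expected {n - 1}"
        )
    if not nx.is_connected(tree):
        raise ValueError("tree is not connected")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def node_betweenness(tree: nx.Graph) -> dict:
    """Normalized betweenness centrality per node.

    Path counting is topological (a tree's paths are unique whatever the edge
    weights); networkx's normalization is 2 / ((N-1)(N-2)) over unordered
    pairs, identical to 1 / ((N-1)(N-2)) over ordered pairs.
    """
    return nx.betweenness_centrality(tree, normalized=True, weight=None)


def _distances(tree: nx.Graph, convention: str) -> dict:
    if convention == "hop":
        return dict(nx.all_pairs_shortest_path_length(tree))
    if convention == "weighted":
        for _, _, d in tree.edges(data=True):
            if "weight" not in d:
                raise ValueError("weighted distances need 'weight' edge attributes")
        g = tree.copy()
        for _, _, d in g.edges(data=True):
            d["length"] = 1.0 - d["weight"]
        return dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    raise ValueError(f"unknown distance convention {convention!r}")


def tree_metrics(
    tree: nx.Graph,
    mpli: float | None = None,
    distance_convention: str = "weighted",
) -> TreeMetrics:
    """All tree summary metrics; ``mpli`` is carried through if supplied.

    With fewer than 3 nodes bc_max is 0 and the tree hierarchy is undefined
    (reported as None).
    """
    validate_tree(tree)
    n = tree.number_of_nodes()
    m = n - 1
    degrees = dict(tree.degree())
    degree_max = max(degrees.values()) / m
    leaves = sum(1 for k in degrees.values() if k == 1)
    leaf_fraction = leaves / m

    bc = node_betweenness(tree)
    bc_max = max(bc.values())

    dist = _distances(tree, distance_convention)
    ecc = {u: max(dist[u].values()) for u in tree.nodes}
    d = max(ecc.values())
    diameter = d / m
    eccentricity = float(np.mean(list(ecc.values()))) / m

    tree_hierarchy = leaves / (2.0 * m * bc_max) if bc_max > 0 else None

    return TreeMetrics(
        mpli=mpli,
        degree_max=degree_max,
        bc_max=bc_max,
        leaf_fraction=leaf_fraction,
        diameter=diameter,
        eccentricity=eccentricity,
        tree_hierarchy=tree_hierarchy,
        distance_convention=distance_convention,
    )


# ---------------------------------------------------------------------------
# Edge-list CSV round-trip
# ---------------------------------------------------------------------------

def write_tree_csv(tree: nx.Graph, path: str | Path,
                   weight_column: str = "pli") -> Path:
    path = Path(path)
    rows = [
        {"node_a": u, "node_b": v, weight_column: d.get("weight", np.nan)}
        for u, v, d in sorted(tree.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", weight_column]).to_csv(
        path, index=False, float_format="%.10g"
    )
    return path


def read_tree_csv(path: str | Path, weight_column: str = "pli") -> nx.Graph:
    df = pd.read_csv(path)
    g = nx.Graph()
    for r in df.itertuples():
        g.add_edge(r.node_a, r.node_b, weight=float(getattr(r, weight_column)))
    return g
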