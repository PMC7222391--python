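"""Cross-subject aggregation: edge-overlap graphs, average spanning trees, hubs.

For one condition and band, the per-subject spanning trees are overlaid on
the shared node set: each edge of the overlap graph carries an integer count,
the number of subjects whose tree contains it. The "average" spanning tree of
the condition is then the maximum-weight spanning tree of the overlap graph
(same Kruskal procedure and tie-break as for individual trees), i.e. the tree
built from the most-shared edges. Nodes of high degree in the average tree
are reported as hubs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .tree import kruskal_max_tree, validate_tree

__all__ = ["overlap_graph", "average_mst", "hub_table", "write_overlap_csv"]


def overlap_graph(trees: Iterable[nx.Graph]) -> nx.Graph:
    """Union of subject trees with per-edge subject counts.

    All trees must share the same node set; the result's edges carry a
    ``count`` attribute in [1, n_subjects].
    """
    trees = list(trees)
    if not trees:
        raise ValueError("need at least one subject tree")
    nodes = set(trees[0].nodes)
    overlap = nx.Graph()
    overlap.add_nodes_from(trees[0].nodes)
    for t in trees:
        if set(t.nodes) != nodes:
            raise ValueError("subject trees have mismatched node sets")
        for u, v in t.edges:
            if overlap.has_edge(u, v):
                overlap[u][v]["count"] += 1
            else:
                overlap.add_edge(u, v, count=1)
    return overlap


def average_mst(overlap: nx.Graph, node_order: Sequence | None = None) -> nx.Graph:
    """Maximum-count spanning tree of an overlap graph.

    ``node_order`` fixes the node-index order used by the deterministic
    tie-break (defaults to the overlap graph's node insertion order). Edges
    absent from the overlap graph count 0 and are only used if the graph is
    otherwise disconnected — which cannot happen when the input trees were
    valid spanning trees.
    """
    if overlap.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes")
    if not nx.is_connected(overlap):
        raise ValueError("overlap graph is disconnected; inputs were not spanning trees")
    labels = list(node_order) if node_order is not None else list(overlap.nodes)
    index = {u: k for k, u in enumerate(labels)}
    n = len(labels)
    w = np.zeros((n, n))
    for u, v, d in overlap.edges(data=True):
        w[index[u], index[v]] = w[index[v], index[u]] = d["count"]
    tree = kruskal_max_tree(w, labels)
    validate_tree(tree)
    return tree


def hub_table(avg_tree: nx.Graph, min_degree: int = 3) -> pd.DataFrame:
    """Nodes of the average tree with raw degree >= ``min_degree``.

    Sorted by degree descending, then channel name. The ``degree_class``
    column distinguishes strong hubs (degree >= 4) from marginal ones
    (degree == 3), matching the two-tier hub display convention.
    """
    rows = [
        {
            "channel": u,
            "degree": k,
            "degree_class": "major" if k >= 4 else ("minor" if k == 3 else "none"),
        }
        for u, k in avg_tree.degree()
        if k >= min_degree
    ]
    rows.sort(key=lambda r: (-r["degree"], str(r["channel"])))
    return pd.DataFrame(rows, columns=["channel", "degree", "degree_class"])


def write_overlap_csv(overlap: nx.Graph, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"node_a": u, "node_b": v, "count": d["count"]}
        for u, v, d in overlap.edges(data=True)
    ]
    rows.sort(key=lambda r: (str(r["node_a"]), str(r["node_b"])))
    pd.DataFrame(rows, columns=["node_a", "node_b", "count"]).to_csv(path, index=False)
    return path
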