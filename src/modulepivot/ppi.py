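"""Protein-protein interaction graph: hubs and network clusters.

The graph is built from a score-filtered edge table (strict threshold,
matching the usual "score > 950" convention of curated PPI databases on
their 0-1000 confidence scale), optionally restricted to a node subset such
as a drug's differential proteins.  Node degree ranks hubs — the higher the
degree, the more central the protein — and "network clusters" are the
connected components above a minimum size.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .data_io import PPIEdgeTable

DEFAULT_MIN_SCORE = 950.0
DEFAULT_MIN_CLUSTER_SIZE = 3


def build_graph(
    edge_table: PPIEdgeTable,
    node_subset: set[str] | None = None,
    min_score: float = DEFAULT_MIN_SCORE,
) -> nx.Graph:
    """Score-filter the edges and build an undirected graph.

    Edges need ``score > min_score`` (strict) and, when ``node_subset`` is
    given, both endpoints inside it; subset nodes without surviving edges
    are retained as isolated (degree-0) nodes.
    """
    g = nx.Graph()
    if node_subset is not None:
        g.add_nodes_from(sorted(node_subset))
    frame = edge_table.frame
    kept = frame[frame["score"] > min_score]
    for a, b, s in kept[["protein_a", "protein_b", "score"]].itertuples(index=False):
        if node_subset is not None and (a not in node_subset or b not in node_subset):
            continue
        g.add_edge(a, b, score=float(s))
    return g


def hub_ranking(graph: nx.Graph, top_n: int | None = None) -> pd.DataFrame:
    """Nodes by degree, descending; ties broken by node ID ascending."""
    rows = sorted(graph.degree(), key=lambda nd: (-nd[1], nd[0]))
    if top_n is not None:
        rows = rows[: int(top_n)]
    return pd.DataFrame(rows, columns=["node", "degree"])


def connected_clusters(
    graph: nx.Graph, min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE
) -> list[frozenset[str]]:
    """Connected components of size >= ``min_cluster_size``, largest first.

    Ties in size are ordered by the smallest member ID so the output is
    deterministic regardless of edge insertion order.
    """
    comps = [frozenset(c) for c in nx.connected_components(graph)]
    comps = [c for c in comps if len(c) >= min_cluster_size]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def clusters_to_frame(clusters: list[frozenset[str]]) -> pd.DataFrame:
    rows = [
        {"cluster": i, "size": len(c), "members": ",".join(sorted(c))}
        for i, c in enumerate(clusters, start=1)
    ]
    return pd.DataFrame(rows, columns=["cluster", "size", "members"])
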