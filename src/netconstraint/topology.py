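"""Per-node topology statistics that partition a PPI network.

Three metrics locate a node within the network architecture:

* **ASPL** — average shortest path length, the mean hop distance from a
  node to every other node; largest at the periphery.
* **BC** — betweenness centrality, the fraction of all-pairs shortest
  paths running through a node, normalized by (n-1)(n-2)/2 for
  undirected graphs so values lie in [0, 1]; largest at hubs.
* **NC** — neighborhood connectivity, the mean degree of a node's
  neighbors; largest at intermediate nodes that attach to hubs.

Edges are treated as unweighted for all three metrics: confidence scores
gate which edges exist but are never used as path lengths.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

__all__ = ["aspl", "betweenness", "neighborhood_connectivity", "node_metrics"]


def _require_connected(g: nx.Graph, min_nodes: int) -> None:
    if g.number_of_nodes() < min_nodes:
        raise ValueError(f"need >= {min_nodes} nodes, got {g.number_of_nodes()}")
    if not nx.is_connected(g):
        raise ValueError(
            "network is disconnected; extract the analysis graph with "
            "network.largest_connected_component first")


def aspl(g: nx.Graph) -> dict[str, float]:
    """Average shortest path length per node, in hops.

    ``aspl(v)`` is the mean of d(v, u) over all u != v; the zero
    self-distance is excluded.  Requires a connected graph with at least
    two nodes.
    """
    _require_connected(g, 2)
    n = g.number_of_nodes()
    out = {}
    for v in g:
        dist = nx.single_source_shortest_path_length(g, v)
        out[v] = sum(dist.values()) / (n - 1)
    return out


def betweenness(g: nx.Graph, normalized: bool = True) -> dict[str, float]:
    """Freeman betweenness centrality, endpoints excluded.

    With ``normalized=True`` (default, the Cytoscape convention) values
    are divided by (n-1)(n-2)/2 and lie in [0, 1].  Requires a connected
    graph with at least three nodes (the normalization is undefined
    below that).
    """
    _require_connected(g, 3)
    return nx.betweenness_centrality(g, normalized=normalized)


def neighborhood_connectivity(g: nx.Graph) -> dict[str, float]:
    """Mean degree of each node's neighbors."""
    isolated = [v for v in g if g.degree(v) == 0]
    if isolated:
        raise ValueError(f"isolated nodes have no neighborhood: {isolated[:5]}")
    return {v: sum(g.degree(u) for u in g[v]) / g.degree(v) for v in g}


def node_metrics(g: nx.Graph, normalized_bc: bool = True) -> pd.DataFrame:
    """All three metrics plus degree as a DataFrame indexed by node id.

    Columns: ``degree``, ``aspl``, ``bc``, ``nc``.  Requires the
    connected analysis graph.
    """
    a = aspl(g)
    b = betweenness(g, normalized=normalized_bc)
    c = neighborhood_connectivity(g)
    nodes = sorted(g.nodes)
    return pd.DataFrame(
        {
            "degree": [g.degree(v) for v in nodes],
            "aspl": [a[v] for v in nodes],
            "bc": [b[v] for v in nodes],
            "nc": [c[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
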