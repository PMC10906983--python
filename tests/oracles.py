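"""Independent brute-force oracles for the topology metrics.

These deliberately avoid the implementation's code paths: ASPL comes
from a hand-written breadth-first search, betweenness from explicit
enumeration of all shortest paths (feasible on graphs with <= 10
nodes), and neighborhood connectivity from direct adjacency-row
summation.
"""

from collections import deque
from itertools import combinations

import networkx as nx


def bfs_distances(g: nx.Graph, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for u in g[v]:
            if u not in dist:
                dist[u] = dist[v] + 1
                queue.append(u)
    return dist


def aspl_oracle(g: nx.Graph) -> dict:
    n = g.number_of_nodes()
    return {v: sum(bfs_distances(g, v).values()) / (n - 1) for v in g}


def betweenness_oracle(g: nx.Graph, normalized: bool = True) -> dict:
    """Freeman betweenness by enumerating every shortest path per pair."""
    score = {v: 0.0 for v in g}
    for s, t in combinations(g.nodes, 2):
        paths = list(nx.all_shortest_paths(g, s, t))
        for path in paths:
            for v in path[1:-1]:  # endpoints excluded
                score[v] += 1.0 / len(paths)
    if normalized:
        n = g.number_of_nodes()
        norm = (n - 1) * (n - 2) / 2.0
        score = {v: s / norm for v, s in score.items()}
    return score


def nc_oracle(g: nx.Graph) -> dict:
    adj = nx.to_numpy_array(g)
    degrees = adj.sum(axis=1)
    nodes = list(g.nodes)
    return {
        v: float((adj[i] * degrees).sum() / degrees[i])
        for i, v in enumerate(nodes)
    }
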