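import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netconstraint import synthetic, topology


def graph_with_confidence(edges) -> nx.Graph:
    g = nx.Graph()
    for u, v in edges:
        g.add_edge(u, v, confidence=0.9)
    return g


@pytest.fixture
def path3():
    return graph_with_confidence([("A", "B"), ("B", "C")])


@pytest.fixture
def star5():
    return graph_with_confidence([("c", f"l{i}") for i in range(4)])


@pytest.fixture(scope="session")
def oracle_graph_suite():
    """Connected graphs with <= 10 nodes for exact metric verification."""
    suite = [
        nx.path_graph(3),
        nx.star_graph(4),
        nx.complete_graph(4),
        nx.cycle_graph(5),
        nx.wheel_graph(6),
        nx.barbell_graph(3, 2),
        nx.lollipop_graph(4, 3),
    ]
    rng_seeds = [11, 23, 47]
    for s in rng_seeds:
        g = nx.erdos_renyi_graph(10, 0.35, seed=s)
        if nx.is_connected(g) and g.number_of_nodes() >= 3:
            suite.append(g)
    g12 = nx.erdos_renyi_graph(12, 0.3, seed=7)
    assert nx.is_connected(g12)
    suite.append(g12)
    return [nx.relabel_nodes(g, {n: str(n) for n in g.nodes}) for g in suite]


@pytest.fixture(scope="session")
def synthetic_default():
    """One default synthetic instance (255 nodes, seed 0)."""
    return synthetic.simulate(synthetic.SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def synthetic_metrics(synthetic_default):
    return topology.node_metrics(synthetic_default.graph)


@pytest.fixture(scope="session")
def separable_training():
    """Linearly separable three-class metric table with seed labels.

    Three tight Gaussian blobs in (aspl, bc, nc) space, 20 seeds per
    class, far enough apart that any sensible classifier is ~perfect.
    """
    rng = np.random.default_rng(42)
    centers = {"H": (2.0, 0.8, 6.0), "I": (4.0, 0.1, 20.0), "P": (7.0, 0.01, 3.0)}
    rows, labels = [], []
    for label, c in centers.items():
        pts = rng.normal(c, (0.1, 0.01, 0.5), size=(20, 3))
        rows.append(pts)
        labels += [label] * 20
    idx = pd.Index([f"n{i}" for i in range(60)], name="node")
    metrics = pd.DataFrame(np.vstack(rows), columns=["aspl", "bc", "nc"], index=idx)
    metrics["degree"] = 3
    seeds = pd.Series(labels, index=idx, name="seed_label")
    return metrics, seeds
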