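"""Synthetic networks and annotations with the structure the analysis assumes.

The generator plants a three-layer architecture mimicking a scale-free
PPI interactome:

* a dense, fully connected **core** of hub nodes (planted H) — these lie
  on nearly all cross-layer shortest paths and therefore carry the
  highest betweenness;
* a **shell** of intermediate nodes (planted I) attached mostly to the
  core — their neighbors are the high-degree hubs, so they carry the
  highest neighborhood connectivity;
* tree-like **fringes** of peripheral nodes (planted P) hanging off the
  shell — farthest from everything, so highest ASPL.

Gene-level constraint is drawn per planted class from normal
distributions whose means decrease from core to periphery, planting the
"constraint intensifies toward the center" gradient.  A focal gene set
(emulating hibernation-associated genes) is drawn mostly from
intermediate nodes, and its rate-accelerated members receive a positive
constraint offset.  Everything is deterministic under the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate_network",
           "generate_constraint", "generate_focal_set", "simulate"]


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic constraint-on-network instance.

    Defaults give a 255-node network (5 hubs, 50 intermediates, 200
    peripherals), a constraint gradient of class means 1.5 / 1.0 / 0.5
    on the PhyloP scale with SD 0.35, and an 18-gene focal set split 10
    accelerated / 8 decelerated with a +0.5 constraint offset for the
    accelerated genes.
    """

    n_hub: int = 5
    n_intermediate: int = 50
    n_peripheral: int = 200
    # attachment parameters
    i_hub_links: int = 2          # hub links per intermediate (plus coin-flip extra)
    p_shell_prob: float = 0.55    # peripheral attaches to shell vs earlier fringe
    i_cross_prob: float = 0.2     # intermediate-intermediate extra edge probability
    # constraint gradient (PhyloP-scale class means and noise SD)
    mu_hub: float = 1.5
    mu_intermediate: float = 1.0
    mu_peripheral: float = 0.5
    noise_sd: float = 0.35
    fringe_decay: float = 0.15    # constraint lost per hop of extra fringe depth
    # focal gene set
    focal_size: int = 18
    n_accelerated: int = 10
    focal_intermediate_fraction: float = 14 / 18
    direction_effect: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_hub < 3 or self.n_intermediate < 10 or self.n_peripheral < 10:
            raise ValueError("layer counts below classifier minimums "
                             "(need >= 3 hubs, >= 10 intermediate, >= 10 peripheral)")
        if not (self.mu_hub > self.mu_intermediate > self.mu_peripheral):
            raise ValueError("constraint gradient must decrease from hub to periphery")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.n_accelerated <= self.focal_size:
            raise ValueError("n_accelerated must be within the focal set size")
        n_i = round(self.focal_intermediate_fraction * self.focal_size)
        if n_i > self.n_intermediate or (self.focal_size - n_i) > self.n_peripheral:
            raise ValueError("focal set fractions infeasible for the layer sizes")

    @property
    def n_nodes(self) -> int:
        return self.n_hub + self.n_intermediate + self.n_peripheral


@dataclass
class SyntheticDataset:
    graph: nx.Graph
    truth: pd.DataFrame        # planted_class, focal, direction per node
    constraint: pd.DataFrame   # mean_phylop per node
    focal: pd.DataFrame        # gene (index), direction


def _node_ids(spec: SyntheticSpec) -> list[str]:
    width = len(str(spec.n_nodes - 1))
    return [f"G{i:0{width}d}" for i in range(spec.n_nodes)]


def _confidence(rng: np.random.Generator) -> float:
    # above the 0.7 high-confidence cut by construction; median near 0.9
    return float(0.7 + 0.3 * rng.beta(2.2, 1.2))


def generate_network(spec: SyntheticSpec) -> tuple[nx.Graph, pd.DataFrame]:
    """Build the planted three-layer graph and its ground-truth table.

    Returns the connected graph (edges carry a ``confidence`` in
    (0.7, 1]) and a DataFrame indexed by node with columns
    ``planted_class`` (H/I/P), ``focal`` (False) and ``direction`` (NA)
    — the latter two are filled in by :func:`simulate`.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ids = _node_ids(spec)
    hubs = ids[: spec.n_hub]
    inters = ids[spec.n_hub: spec.n_hub + spec.n_intermediate]
    periph = ids[spec.n_hub + spec.n_intermediate:]

    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, u in enumerate(hubs):
        for v in hubs[i + 1:]:
            g.add_edge(u, v, confidence=_confidence(rng))
    for j, v in enumerate(inters):
        k = spec.i_hub_links + int(rng.random() < 0.5)
        for u in rng.choice(hubs, size=min(k, len(hubs)), replace=False):
            g.add_edge(v, str(u), confidence=_confidence(rng))
        if j > 0 and rng.random() < spec.i_cross_prob:
            w = inters[int(rng.integers(0, j))]
            if w != v:
                g.add_edge(v, w, confidence=_confidence(rng))
    depth = {v: 0 for v in hubs + inters}
    for j, v in enumerate(periph):
        if j == 0 or rng.random() < spec.p_shell_prob:
            parent = inters[int(rng.integers(0, len(inters)))]
        else:
            parent = periph[int(rng.integers(0, j))]
        g.add_edge(v, parent, confidence=_confidence(rng))
        depth[v] = depth[parent] + 1

    truth = pd.DataFrame(
        {
            "planted_class": ["H"] * len(hubs) + ["I"] * len(inters)
            + ["P"] * len(periph),
            "focal": False,
            "direction": pd.Series([pd.NA] * len(ids), dtype="object"),
            "fringe_depth": [depth[v] for v in ids],
        },
        index=pd.Index(ids, name="node"),
    )
    return g, truth


def generate_focal_set(truth: pd.DataFrame, spec: SyntheticSpec) -> pd.DataFrame:
    """Draw the focal gene set from the planted classes.

    ``focal_intermediate_fraction`` of the genes come from planted-I
    nodes, the remainder from planted-P; direction labels split
    ``n_accelerated`` accelerated vs the rest decelerated, assigned at
    random.  Returns a DataFrame indexed by gene with a ``direction``
    column.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    n_i = round(spec.focal_intermediate_fraction * spec.focal_size)
    n_p = spec.focal_size - n_i
    pool_i = truth.index[truth["planted_class"] == "I"].to_numpy()
    pool_p = truth.index[truth["planted_class"] == "P"].to_numpy()
    genes = np.concatenate([
        rng.choice(pool_i, size=n_i, replace=False),
        rng.choice(pool_p, size=n_p, replace=False),
    ])
    rng.shuffle(genes)
    direction = np.array(["accelerated"] * spec.n_accelerated
                         + ["decelerated"] * (spec.focal_size - spec.n_accelerated))
    return pd.DataFrame({"direction": direction},
                        index=pd.Index(genes, name="gene"))


def generate_constraint(truth: pd.DataFrame, spec: SyntheticSpec) -> pd.DataFrame:
    """Per-gene mean PhyloP from the planted class gradient.

    ``mean_phylop ~ Normal(mu_class, noise_sd)``; focal genes planted as
    rate-accelerated receive an additional ``direction_effect``
    (faster-evolving genes sitting under higher constraint).

    The decline is gradual, not a three-level step: within the tree-like
    fringe, constraint additionally decays by ``fringe_decay`` per hop
    of depth below the shell (the ``fringe_depth`` column written by
    :func:`generate_network`), centered so the peripheral class mean
    stays exactly ``mu_peripheral``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 2)
    mu = {"H": spec.mu_hub, "I": spec.mu_intermediate, "P": spec.mu_peripheral}
    base = truth["planted_class"].map(mu).to_numpy(dtype=float)
    if spec.fringe_decay and "fringe_depth" in truth.columns:
        is_p = (truth["planted_class"] == "P").to_numpy()
        depth = truth["fringe_depth"].to_numpy(dtype=float)
        centered = depth[is_p] - depth[is_p].mean()
        base[is_p] -= spec.fringe_decay * centered
    values = base + rng.normal(0.0, spec.noise_sd, size=len(truth))
    accel = (truth["focal"] & (truth["direction"] == "accelerated")).to_numpy()
    values[accel] += spec.direction_effect
    return pd.DataFrame({"mean_phylop": values}, index=truth.index.copy())


def simulate(spec: SyntheticSpec | None = None, seed: int | None = None) -> SyntheticDataset:
    """Generate a complete synthetic instance: graph, truth, constraint, focal set."""
    spec = spec or SyntheticSpec()
    if seed is not None:
        spec = SyntheticSpec(**{**spec.__dict__, "seed": seed})
    graph, truth = generate_network(spec)
    focal = generate_focal_set(truth, spec)
    truth.loc[focal.index, "focal"] = True
    truth.loc[focal.index, "direction"] = focal["direction"]
    constraint = generate_constraint(truth, spec)
    return SyntheticDataset(graph=graph, truth=truth, constraint=constraint,
                            focal=focal)
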