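"""Network input/output and assembly of the analysis graph.

Networks are undirected :class:`networkx.Graph` objects whose nodes are
gene-symbol strings and whose edges carry a ``confidence`` attribute in
[0, 1].  STRING-style link files score edges on an integer 0-1000 scale;
``score_scale="thousand"`` rescales them.  The analysis graph is the
largest connected component of the confidence-filtered network, joined to
a per-gene attribute table (e.g. mean PhyloP constraint).
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeTableParseError",
    "read_edge_table",
    "read_network",
    "write_edge_table",
    "write_graphml",
    "largest_connected_component",
    "read_attribute_table",
    "write_attribute_table",
    "join_attributes",
]


class EdgeTableParseError(ValueError):
    """Raised when an edge-table row cannot be parsed; names the line."""


def _check_score(raw: float, scale: str, path: str, lineno: int) -> float:
    """Rescale a raw score to [0, 1] and validate it against the declared scale."""
    if scale == "unit":
        hi = 1.0
    elif scale == "thousand":
        hi = 1000.0
    else:
        raise ValueError(f"unknown score_scale {scale!r}; use 'unit' or 'thousand'")
    if not (0.0 <= raw <= hi):
        raise ValueError(
            f"{path}, line {lineno}: score {raw} outside declared scale "
            f"'{scale}' (expected 0..{hi:g})"
        )
    return raw / hi


def read_edge_table(
    path: str | Path,
    score_threshold: float = 0.7,
    score_scale: str = "unit",
    fmt: str | None = None,
) -> nx.Graph:
    """Read an edge table and return the confidence-filtered network.

    Parameters
    ----------
    path
        Delimited edge list (``node1  node2  score``, whitespace- or
        tab-separated, optional header), ``.sif`` file, or ``.graphml``
        file (chosen by extension unless ``fmt`` is given).
    score_threshold
        Edges are kept iff confidence is *strictly greater* than this
        value after rescaling to [0, 1].
    score_scale
        ``"unit"`` for 0-1 scores, ``"thousand"`` for STRING-style
        integer 0-1000 scores.  Never auto-detected; the choice is logged.

    Notes
    -----
    Self-loops are dropped.  Duplicate undirected A-B / B-A rows collapse
    to a single edge keeping the maximum confidence (conservative under
    the strict ``>`` filter).
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {"sif": "sif", ".sif": "sif", ".graphml": "graphml"}.get(suffix, "edgelist")
    logger.info("reading %s as %s with score_scale=%s, threshold=%g",
                path, fmt, score_scale, score_threshold)

    g = nx.Graph()
    if fmt == "graphml":
        raw = nx.read_graphml(path)
        for u, v, data in raw.edges(data=True):
            conf = _check_score(float(data.get("confidence", 1.0)), score_scale, str(path), 0)
            _add_edge(g, str(u), str(v), conf)
    else:
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if fmt == "sif":
                    # node1 <relation> node2 [node3 ...]; SIF carries no score
                    if len(fields) < 3:
                        raise EdgeTableParseError(
                            f"{path}, line {lineno}: SIF row needs >= 3 fields")
                    for target in fields[2:]:
                        _add_edge(g, fields[0], target, 1.0)
                    continue
                if len(fields) < 3:
                    raise EdgeTableParseError(
                        f"{path}, line {lineno}: expected >= 3 columns, got {len(fields)}")
                try:
                    raw_score = float(fields[2])
                except ValueError:
                    if lineno == 1:  # header row
                        continue
                    raise EdgeTableParseError(
                        f"{path}, line {lineno}: non-numeric score {fields[2]!r}") from None
                conf = _check_score(raw_score, score_scale, str(path), lineno)
                _add_edge(g, fields[0], fields[1], conf)

    drop = [(u, v) for u, v, d in g.edges(data=True)
            if d["confidence"] <= score_threshold]
    g.remove_edges_from(drop)
    g.remove_nodes_from([n for n in list(g) if g.degree(n) == 0])
    logger.info("network: %d nodes, %d edges after filtering (%d edges removed)",
                g.number_of_nodes(), g.number_of_edges(), len(drop))
    return g


def _add_edge(g: nx.Graph, u: str, v: str, confidence: float) -> None:
    if u == v:
        return
    if g.has_edge(u, v):
        g[u][v]["confidence"] = max(g[u][v]["confidence"], confidence)
    else:
        g.add_edge(u, v, confidence=confidence)


def read_network(path: str | Path, **kwargs) -> nx.Graph:
    """Alias for :func:`read_edge_table` accepting any supported dialect."""
    return read_edge_table(path, **kwargs)


def write_edge_table(g: nx.Graph, path: str | Path) -> None:
    """Write a tab-delimited edge list (node1, node2, confidence), sorted."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("node1\tnode2\tconfidence\n")
        for u, v, d in sorted(
            (tuple(sorted((u, v))) + (d,) for u, v, d in g.edges(data=True))
        ):
            fh.write(f"{u}\t{v}\t{d['confidence']:.6g}\n")


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, path)


def largest_connected_component(g: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Ties on size are broken by the component containing the
    lexicographically smallest node id.  The number of dropped nodes is
    logged.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty network has no connected component")
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    keep = comps[0]
    dropped = g.number_of_nodes() - len(keep)
    logger.info("largest connected component: %d nodes kept, %d dropped",
                len(keep), dropped)
    return g.subgraph(keep).copy()


def read_attribute_table(path: str | Path, index_col: int = 0) -> pd.DataFrame:
    """Read a node-attribute TSV (header row; column 1 = gene id)."""
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_attribute_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", lineterminator="\n")


def join_attributes(g: nx.Graph, table: pd.DataFrame) -> pd.DataFrame:
    """Restrict an attribute table to the nodes of a network.

    Returns the rows of ``table`` whose index is a network node, in
    network-independent (table) order.  No imputation is performed; the
    counts of unmatched network nodes and unmatched table rows are
    logged.  Duplicate gene ids in the table are an error (the upstream
    summarization, e.g. of per-isoform scores, must resolve them).
    """
    dup = table.index[table.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate gene ids in attribute table: {dup}")
    nodes = set(g.nodes)
    matched = table.loc[table.index.isin(nodes)]
    n_nodes_missing = len(nodes) - len(matched)
    n_rows_unmatched = len(table) - len(matched)
    logger.info("join_attributes: %d matched, %d network nodes without attributes, "
                "%d attribute rows not in network",
                len(matched), n_nodes_missing, n_rows_unmatched)
    return matched
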