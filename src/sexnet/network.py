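"""Undirected gene-interaction networks and sex-classed X–Y subnetworks.

All interaction evidence types (protein–protein, TF→gene, genetic) are
flattened to unique undirected edges on a simple graph; self-loops are
dropped.  A subnetwork X–Y consists of the class-X nodes that have at
least one class-Y neighbour, together with the unique X–Y edges.  The
wildcard class ``A`` matches any label.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "InteractionNetwork",
    "SubnetworkSummary",
    "ANY_CLASS",
    "read_edge_list",
    "write_edge_list",
    "merge_networks",
    "restrict_nodes",
    "subnetwork",
    "summarize_subnetwork",
]

log = logging.getLogger(__name__)

#: Wildcard node class matching every label.
ANY_CLASS = "A"

#: Short codes used in summary tables for the three real classes.
CLASS_CODES = {"unbiased": "U", "female": "F", "male": "M"}


class InteractionNetwork:
    """Simple undirected graph over gene identifiers.

    Thin wrapper around :class:`networkx.Graph` that enforces the simple-
    graph invariants (no self-loops, deduplicated edges) at construction.
    """

    def __init__(self, edges: Iterable[tuple[str, str]] = (),
                 nodes: Iterable[str] = ()):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        n_loops = 0
        for u, v in edges:
            if u == v:
                n_loops += 1
                continue
            g.add_edge(u, v)
        if n_loops:
            log.warning("dropped %d self-loop(s)", n_loops)
        self._g = g

    @classmethod
    def from_graph(cls, g: nx.Graph) -> "InteractionNetwork":
        net = cls.__new__(cls)
        h = nx.Graph()
        h.add_nodes_from(g.nodes)
        h.add_edges_from((u, v) for u, v in g.edges if u != v)
        net._g = h
        return net

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset((u, v)) for u, v in self._g.edges}

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def degree(self, node: str) -> int:
        return self._g.degree(node)

    def neighbors(self, node: str) -> set[str]:
        return set(self._g.neighbors(node))

    def __eq__(self, other) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"InteractionNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class SubnetworkSummary:
    """The nine per-subnetwork summary statistics.

    Degree statistics (mean/SD/quartiles) are computed under
    ``degree_mode``: ``"full"`` counts every edge a node has in the whole
    analysis network, ``"within"`` only the subnetwork's own edges.
    ``exponent``/``cutoff`` describe the power-law tail fit of the degree
    distribution and are filled in by the caller (see
    :mod:`sexnet.degree_stats`); they stay ``None`` when no fit was made.
    """

    network_code: str
    n_nodes: int
    n_edges: int
    edges_per_node: float  # nan when n_nodes == 0
    mean_degree: float
    sd_degree: float
    q25_degree: float
    q75_degree: float
    exponent: float | None = None
    cutoff: int | None = None
    degree_mode: str = "full"


def read_edge_list(path) -> InteractionNetwork:
    """Read a two-column whitespace-separated gene-pair file.

    Reversed and repeated pairs collapse to one undirected edge; self-loops
    are dropped with a warning.  A line with other than two tokens raises a
    ``ValueError`` naming the line number.
    """
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected two columns, "
                    f"got {len(tokens)}"
                )
            edges.append((tokens[0], tokens[1]))
    return InteractionNetwork(edges)


def write_edge_list(net: InteractionNetwork, path) -> None:
    """Write sorted unique edges, two columns per line (byte-stable)."""
    rows = sorted(tuple(sorted(e)) for e in net.edges)
    with open(path, "w") as fh:
        for u, v in rows:
            fh.write(f"{u}\t{v}\n")


def merge_networks(networks: Sequence[InteractionNetwork]) -> InteractionNetwork:
    """Union of node and edge sets (e.g. strict vs permissive groupings)."""
    if not networks:
        raise ValueError("merge_networks requires at least one network")
    g = nx.Graph()
    for net in networks:
        g.add_nodes_from(net.graph.nodes)
        g.add_edges_from(net.graph.edges)
    return InteractionNetwork.from_graph(g)


def restrict_nodes(net: InteractionNetwork, keep: Iterable[str]) -> InteractionNetwork:
    """Induced subgraph on ``keep``, then drop isolated nodes.

    The analysis network contains only genes that carry a bias value *and*
    retain at least one interaction partner after restriction.
    """
    keep = set(keep)
    sub = net.graph.subgraph(net.nodes & keep).copy()
    sub.remove_nodes_from(list(nx.isolates(sub)))
    out = InteractionNetwork.from_graph(sub)
    log.info("restrict_nodes: %d -> %d nodes, %d -> %d edges",
             net.n_nodes, out.n_nodes, net.n_edges, out.n_edges)
    return out


def _check_labels(net: InteractionNetwork, labels: Mapping[str, str]) -> None:
    missing = sorted(n for n in net.graph.nodes if n not in labels)
    if missing:
        raise ValueError(f"unlabeled network nodes: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))


def subnetwork(
    net: InteractionNetwork,
    labels: Mapping[str, str],
    x: str,
    y: str,
) -> tuple[set[str], set[frozenset]]:
    """Nodes of class ``x`` with a class-``y`` neighbour, plus X–Y edges.

    Classes are compared against ``labels`` values; ``ANY_CLASS`` matches
    everything.  Edge sets are unordered, so |edges(X,Y)| == |edges(Y,X)|.
    """
    _check_labels(net, labels)

    def is_class(node: str, cls: str) -> bool:
        return cls == ANY_CLASS or labels[node] == cls

    nodes = set()
    edges = set()
    for u, v in net.graph.edges:
        ux, vy = is_class(u, x) and is_class(v, y), is_class(v, x) and is_class(u, y)
        if ux:
            nodes.add(u)
        if vy:
            nodes.add(v)
        if ux or vy:
            edges.add(frozenset((u, v)))
    return nodes, edges


def summarize_subnetwork(
    net: InteractionNetwork,
    labels: Mapping[str, str],
    x: str,
    y: str,
    degree_mode: str = "full",
) -> SubnetworkSummary:
    """Node/edge counts and degree statistics for one X–Y subnetwork."""
    if degree_mode not in ("full", "within"):
        raise ValueError("degree_mode must be 'full' or 'within'")
    nodes, edges = subnetwork(net, labels, x, y)
    code = f"{x}-{y}"
    if not nodes:
        return SubnetworkSummary(code, 0, len(edges), math.nan,
                                 0.0, 0.0, 0.0, 0.0, degree_mode=degree_mode)
    if degree_mode == "full":
        degs = np.array([net.degree(n) for n in sorted(nodes)], dtype=float)
    else:
        within = nx.Graph()
        within.add_nodes_from(nodes)
        within.add_edges_from(tuple(e) for e in edges)
        degs = np.array([within.degree(n) for n in sorted(nodes)], dtype=float)
    return SubnetworkSummary(
        network_code=code,
        n_nodes=len(nodes),
        n_edges=len(edges),
        edges_per_node=len(edges) / len(nodes),
        mean_degree=float(degs.mean()),
        sd_degree=float(degs.std(ddof=0)),
        q25_degree=float(np.percentile(degs, 25)),
        q75_degree=float(np.percentile(degs, 75)),
        degree_mode=degree_mode,
    )


def subnetwork_degrees(
    net: InteractionNetwork,
    labels: Mapping[str, str],
    x: str,
    y: str,
    degree_mode: str = "within",
) -> list[int]:
    """Degree sequence of the X–Y subnetwork nodes, for distribution fits."""
    nodes, edges = subnetwork(net, labels, x, y)
    if degree_mode == "full":
        return [net.degree(n) for n in sorted(nodes)]
    within = nx.Graph()
    within.add_nodes_from(nodes)
    within.add_edges_from(tuple(e) for e in edges)
    return [within.degree(n) for n in sorted(nodes)]
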