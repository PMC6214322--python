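"""Undirected gene-network data model, component analysis and edge-list I/O.

A :class:`Network` is a simple undirected graph over string node labels,
the graph ``<N, E>`` on which every relevance and centrality measure in
this package is defined.  Node order is the order of first appearance, so
every downstream output is reproducible.  Networks are immutable from the
caller's point of view: removal operations return new networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx

__all__ = [
    "Network",
    "ComponentPartition",
    "load_edge_list",
    "write_edge_list",
    "node_sort_key",
]


def node_sort_key(label: str) -> tuple:
    """Numeric-aware sort key: integer labels sort numerically, others lexically."""
    try:
        return (0, int(label), "")
    except ValueError:
        return (1, 0, label)


class Network:
    """Simple undirected graph with ordered string nodes.

    Self-loops and duplicate edges are rejected; edge endpoints are added
    as nodes automatically.
    """

    def __init__(self, nodes: Iterable[str] = (), edges: Iterable[tuple[str, str]] = ()):
        self._g = nx.Graph()
        for n in nodes:
            self._g.add_node(str(n))
        for u, v in edges:
            self.add_edge_unchecked(str(u), str(v))

    def add_edge_unchecked(self, u: str, v: str) -> None:
        # internal builder hook: callers construct via __init__ / load_edge_list
        if u == v:
            raise ValueError(f"self-loop on node {u!r} is not allowed")
        self._g.add_edge(u, v)

    # -- basic queries ---------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return list(self._g.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [(u, v) for u, v in self._g.edges]

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def __iter__(self) -> Iterator[str]:
        return iter(self._g.nodes)

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def _check_node(self, i: str) -> None:
        if i not in self._g:
            raise KeyError(f"unknown node id {i!r}")

    def neighbors(self, i: str) -> set[str]:
        """N_i(E): the set of neighbours of node *i* (never contains *i*)."""
        self._check_node(i)
        return set(self._g.neighbors(i))

    def coalition_neighbors(self, S: Iterable[str]) -> set[str]:
        """N_S(E): union of the neighbour sets of the nodes in *S* (may intersect S)."""
        S = list(S)
        if not S:
            raise ValueError("coalition_neighbors requires a non-empty node set")
        out: set[str] = set()
        for i in S:
            self._check_node(i)
            out.update(self._g.neighbors(i))
        return out

    def degree(self, i: str) -> int:
        """d_i(E) = |N_i(E)|."""
        self._check_node(i)
        return self._g.degree(i)

    def degrees(self) -> dict[str, int]:
        return dict(self._g.degree())

    # -- component analysis & removal ------------------------------------
    def connected_components(self) -> "ComponentPartition":
        comps = [set(c) for c in nx.connected_components(self._g)]
        comps.sort(key=lambda c: min(node_sort_key(n) for n in c))
        return ComponentPartition(components=comps)

    def remove_nodes(self, S: Iterable[str]) -> "Network":
        """Induced subgraph on nodes(g) \\ S; the original network is unmodified."""
        S = set(S)
        for i in S:
            self._check_node(i)
        out = Network()
        out._g.add_nodes_from(n for n in self._g.nodes if n not in S)
        out._g.add_edges_from(
            (u, v) for u, v in self._g.edges if u not in S and v not in S
        )
        return out

    def subgraph(self, keep: Iterable[str]) -> "Network":
        keep = set(keep)
        return self.remove_nodes(n for n in self._g.nodes if n not in keep)

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    def __repr__(self) -> str:  # pragma: no cover
        return f"Network(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass
class ComponentPartition:
    """Maximal connected components of a network, ordered by smallest node label."""

    components: list[set[str]] = field(default_factory=list)

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.components]

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def n_singletons(self) -> int:
        return sum(1 for c in self.components if len(c) == 1)


def load_edge_list(path) -> Network:
    """Read an edge-list TSV into a :class:`Network`.

    One edge per line, two whitespace/tab-separated node ids (extra tokens
    ignored); ``#`` starts a comment; a single-token line declares an
    isolated node.  Duplicate and reversed-duplicate lines collapse to a
    single undirected edge.  Self-loop lines are rejected with their line
    number.
    """
    net = Network()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) == 1:
                net._g.add_node(tokens[0])
                continue
            u, v = tokens[0], tokens[1]
            if u == v:
                raise ValueError(f"{path}: self-loop {u!r} on line {lineno}")
            net._g.add_edge(u, v)
    return net


def write_edge_list(net: Network, path) -> None:
    """Write edges (endpoints sorted within a line, lines sorted), then isolated nodes."""
    lines = []
    for u, v in net.edges:
        a, b = sorted((u, v), key=node_sort_key)
        lines.append((node_sort_key(a), node_sort_key(b), f"{a}\t{b}"))
    lines.sort()
    isolated = sorted(
        (n for n in net.nodes if net.degree(n) == 0), key=node_sort_key
    )
    with open(path, "w") as fh:
        for _, _, text in lines:
            fh.write(text + "\n")
        for n in isolated:
            fh.write(n + "\n")
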