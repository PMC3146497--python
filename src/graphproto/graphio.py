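"""Graph and cohort I/O.

Graphs are undirected, simple, and uniquely labeled: every vertex carries a
distinct string label (a gene identifier in the co-expression setting) and
edges are unordered label pairs.  Cohorts group several such graphs — e.g. a
set of benign and a set of cancer co-expression networks inferred from
independent studies — and the structural distance measures in
:mod:`graphproto.structdist` assume that, where required, all graphs in a
cohort share one vertex set.

Supported formats are a two-column edge-list TSV (``#`` comments allowed; a
one-column line declares an isolated vertex; an optional third column is
parsed and discarded, since every measure here is topology-only) and GraphML.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "LabeledGraph",
    "Cohort",
    "read_edge_list",
    "write_edge_list",
    "read_graphml",
    "write_graphml",
    "read_groups",
    "write_groups",
    "align_vertex_sets",
    "largest_connected_component",
]


class LabeledGraph:
    """An undirected simple graph with unique string vertex labels.

    Thin wrapper around :class:`networkx.Graph` that enforces the invariants
    every distance measure relies on: no self-loops, no parallel edges, string
    labels.  The underlying networkx graph is exposed as :attr:`graph` for use
    with library algorithms.
    """

    __slots__ = ("name", "_g")

    def __init__(self, name: str, graph: nx.Graph):
        if graph.is_directed() or graph.is_multigraph():
            raise ValueError("LabeledGraph requires an undirected simple graph")
        loops = [u for u, v in nx.selfloop_edges(graph)]
        if loops:
            raise ValueError(f"self-loops not allowed (at {sorted(loops)[:5]})")
        for v in graph.nodes:
            if not isinstance(v, str):
                raise ValueError(f"vertex label {v!r} is not a string")
        self.name = str(name)
        self._g = graph

    @classmethod
    def from_edges(
        cls,
        name: str,
        edges: Iterable[tuple[str, str]],
        vertices: Iterable[str] = (),
    ) -> "LabeledGraph":
        g = nx.Graph()
        g.add_nodes_from(str(v) for v in vertices)
        g.add_edges_from((str(u), str(v)) for u, v in edges)
        return cls(name, g)

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def vertices(self) -> tuple[str, ...]:
        """Vertex labels in canonical (sorted) order."""
        return tuple(sorted(self._g.nodes))

    @property
    def edges(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(e) for e in self._g.edges)

    @property
    def n(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def is_connected(self) -> bool:
        return self.n > 0 and nx.is_connected(self._g)

    def with_name(self, name: str) -> "LabeledGraph":
        return LabeledGraph(name, self._g)

    def __eq__(self, other) -> bool:
        if not isinstance(other, LabeledGraph):
            return NotImplemented
        return (
            set(self._g.nodes) == set(other._g.nodes)
            and self.edges == other.edges
        )

    def __hash__(self):  # pragma: no cover - identity hashing only
        return id(self)

    def __repr__(self) -> str:
        return f"LabeledGraph({self.name!r}, n={self.n}, m={self.n_edges})"


@dataclass
class Cohort:
    """A named collection of graphs partitioned into groups.

    ``group_of`` maps each graph name to its group label (e.g. ``"benign"``
    or ``"cancer"``).  Every graph must belong to exactly one group.
    """

    graphs: list[LabeledGraph]
    group_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        names = [g.name for g in self.graphs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate graph names in cohort")
        missing = [n for n in names if n not in self.group_of]
        if self.group_of and missing:
            raise ValueError(f"graphs missing from group table: {missing}")

    @property
    def names(self) -> list[str]:
        return [g.name for g in self.graphs]

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.graphs:
            seen.setdefault(self.group_of[g.name], None)
        return list(seen)

    def subset(self, group: str) -> list[LabeledGraph]:
        return [g for g in self.graphs if self.group_of[g.name] == group]


def read_edge_list(path: str | Path, name: str | None = None) -> LabeledGraph:
    """Read a graph from a two-column edge-list TSV.

    Lines starting with ``#`` are comments.  A one-column line declares an
    isolated vertex.  A third column (edge weight) is accepted and dropped.
    A self-loop line is rejected with its line number.
    """
    path = Path(path)
    if name is None:
        name = path.stem
    g = nx.Graph()
    n_content = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            n_content += 1
            fields = line.split("\t")
            if len(fields) == 1:
                g.add_node(fields[0])
                continue
            u, v = fields[0], fields[1]
            if u == v:
                raise ValueError(
                    f"{path}:{lineno}: self-loop {u!r}-{v!r} not allowed"
                )
            g.add_edge(u, v)
    if n_content == 0:
        warnings.warn(f"{path}: empty edge list, returning empty graph")
    return LabeledGraph(name, g)


def write_edge_list(g: LabeledGraph, path: str | Path) -> None:
    """Write a graph as edge-list TSV (round-trips with :func:`read_edge_list`)."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in g.graph.edges):
            fh.write(f"{u}\t{v}\n")
        for v in sorted(v for v in g.graph.nodes if g.graph.degree[v] == 0):
            fh.write(f"{v}\n")


def read_graphml(path: str | Path, name: str | None = None) -> LabeledGraph:
    """Read a graph from GraphML; node ids become vertex labels."""
    path = Path(path)
    g = nx.read_graphml(path)
    if g.is_directed():
        g = g.to_undirected()
    g = nx.Graph(g)  # drop multi-edges if any
    g.remove_edges_from(nx.selfloop_edges(g))
    h = nx.Graph()
    h.add_nodes_from(str(v) for v in g.nodes)
    h.add_edges_from((str(u), str(v)) for u, v in g.edges)
    return LabeledGraph(name if name is not None else path.stem, h)


def write_graphml(g: LabeledGraph, path: str | Path) -> None:
    nx.write_graphml(g.graph, path)


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a (graph_name, group) TSV into a mapping; duplicates rejected."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            name, group = fields[0], fields[1]
            if name in mapping:
                raise ValueError(f"{path}:{lineno}: duplicate graph name {name!r}")
            mapping[name] = group
    return mapping


def write_groups(group_of: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(group_of):
            fh.write(f"{name}\t{group_of[name]}\n")


def align_vertex_sets(cohort: Cohort) -> Cohort:
    """Bring every graph onto the union vertex set.

    Added vertices are isolated; edge sets are untouched.  Idempotent.  The
    aligned cohort is the precondition for the edit-distance and whole-graph
    distribution measures, which require a shared vertex set.
    """
    if not cohort.graphs:
        raise ValueError("cohort must contain at least one graph")
    union: set[str] = set()
    for g in cohort.graphs:
        union.update(g.graph.nodes)
    aligned = []
    for g in cohort.graphs:
        h = g.graph.copy()
        h.add_nodes_from(union - set(h.nodes))
        aligned.append(LabeledGraph(g.name, h))
    return Cohort(aligned, dict(cohort.group_of))


def largest_connected_component(g: LabeledGraph) -> LabeledGraph:
    """Induced subgraph on the largest connected component.

    Ties between equally large components are broken by the lexicographically
    smallest member label, so the result is deterministic.
    """
    if g.n == 0:
        return LabeledGraph(g.name, nx.Graph())
    comps = [sorted(c) for c in nx.connected_components(g.graph)]
    best = sorted(comps, key=lambda c: (-len(c), c[0]))[0]
    return LabeledGraph(g.name, nx.Graph(g.graph.subgraph(best)))
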