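"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from graphproto import LabeledGraph


@pytest.fixture
def p3() -> LabeledGraph:
    return LabeledGraph.from_edges("P3", [("a", "b"), ("b", "c")])


@pytest.fixture
def p4() -> LabeledGraph:
    return LabeledGraph.from_edges("P4", [("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def c4() -> LabeledGraph:
    return LabeledGraph.from_edges(
        "C4", [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")]
    )


@pytest.fixture
def c5() -> LabeledGraph:
    return LabeledGraph.from_edges(
        "C5", [(f"v{i}", f"v{(i + 1) % 5}") for i in range(5)]
    )


@pytest.fixture
def star4() -> LabeledGraph:
    """Star on 4 vertices: one center, three leaves."""
    return LabeledGraph.from_edges(
        "star4", [("c", "l1"), ("c", "l2"), ("c", "l3")]
    )


def complete_graph(n: int, prefix: str = "v") -> LabeledGraph:
    labels = [f"{prefix}{i}" for i in range(n)]
    return LabeledGraph.from_edges(
        f"K{n}", itertools.combinations(labels, 2), vertices=labels
    )


@pytest.fixture
def k4() -> LabeledGraph:
    return complete_graph(4)


@pytest.fixture
def k5() -> LabeledGraph:
    return complete_graph(5)


def random_labeled_graph(
    n: int, p: float, rng: np.random.Generator, name: str = "rand"
) -> LabeledGraph:
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    labels = {i: f"v{i:02d}" for i in g.nodes}
    return LabeledGraph(name, nx.relabel_nodes(g, labels))


def random_connected_graph(
    n: int, p: float, rng: np.random.Generator, name: str = "rand"
) -> LabeledGraph:
    while True:
        g = random_labeled_graph(n, p, rng, name)
        if g.is_connected():
            return g


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the implementation paths they check)
# ---------------------------------------------------------------------------


def brute_force_orbits(g: LabeledGraph) -> list[set[str]]:
    """Vertex orbits by testing all n! permutations for automorphism.

    Exponential; only usable for n <= 8.  Two vertices share an orbit iff
    some adjacency-preserving permutation maps one to the other.
    """
    verts = list(g.vertices)
    edges = {frozenset(e) for e in g.edges}
    n = len(verts)
    parent = {v: v for v in verts}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for perm in itertools.permutations(verts):
        sigma = dict(zip(verts, perm))
        if all(frozenset((sigma[u], sigma[v])) in edges for u, v in
               (tuple(e) for e in edges)):
            for v in verts:
                ra, rb = find(v), find(sigma[v])
                if ra != rb:
                    parent[rb] = ra
    orbits: dict[str, set[str]] = {}
    for v in verts:
        orbits.setdefault(find(v), set()).add(v)
    return sorted(orbits.values(), key=lambda s: min(s))


def brute_force_distance_counts(g: LabeledGraph) -> dict[int, int]:
    """Unordered finite-pair shortest-path length counts via Floyd-Warshall."""
    from scipy.sparse.csgraph import floyd_warshall

    verts = g.vertices
    n = len(verts)
    idx = {v: i for i, v in enumerate(verts)}
    adj = np.zeros((n, n))
    for u, v in (tuple(e) for e in g.edges):
        adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = 1
    dist = floyd_warshall(adj, unweighted=True)
    counts: dict[int, int] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d = dist[i, j]
            if np.isfinite(d) and d > 0:
                counts[int(d)] = counts.get(int(d), 0) + 1
    return counts


def brute_force_wilcoxon_p(a: list[float], b: list[float]) -> float:
    """Exact two-sided rank-sum p by enumerating all rank assignments.

    Assumes no ties.  Two-sided p = 2 * min(P(U <= u), P(U >= u)), capped
    at 1, where U is the Mann-Whitney statistic of the first sample.
    """
    n1, n2 = len(a), len(b)
    ranks = {v: r + 1 for r, v in enumerate(sorted(a + b))}
    u_obs = sum(ranks[v] for v in a) - n1 * (n1 + 1) / 2
    us = []
    all_ranks = list(range(1, n1 + n2 + 1))
    for combo in itertools.combinations(all_ranks, n1):
        us.append(sum(combo) - n1 * (n1 + 1) / 2)
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_le, p_ge))
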