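"""Structural distributions and graph distance measures.

Five pairwise distances between uniquely-labeled networks are provided:

``pged``
    Normalized graph edit distance.  Because all graphs live on one fixed,
    uniquely-labeled vertex set, the minimum edit sequence consists of edge
    insertions/deletions only and its cost equals the edge symmetric
    difference ``|E1 Δ E2|``.  Normalizing by the maximum possible number of
    edges ``n(n-1)/2`` maps the extreme edit (complete vs. edgeless) to 1.

``kld_degree``, ``kld_distance``, ``kld_spheres``, ``kld_orbits``
    Kullback-Leibler divergences ``D(P||Q) = Σ_i P_i log(P_i/Q_i)`` between
    structural probability distributions of the two graphs: the degree
    distribution, the shortest-path (distance) distribution, sphere-based
    vertex probabilities, and the distribution of automorphism-orbit sizes.
    Degree and distance distributions are computed on the complete, possibly
    disconnected graph; the sphere and orbit measures are defined on
    connected graphs only, so those two reduce each input to its largest
    connected component first.

Zero probabilities are replaced by a small ``epsilon`` inside the divergence
for numerical stability (no renormalization); the divergence is asymmetric,
with the first graph supplying the reference distribution ``P``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import igraph as ig
import networkx as nx
import numpy as np

from .graphio import LabeledGraph, largest_connected_component

__all__ = [
    "MEASURES",
    "StructuralDistribution",
    "SphereConfig",
    "KLDConfig",
    "degree_distribution",
    "distance_distribution",
    "sphere_probabilities",
    "orbit_distribution",
    "automorphism_orbits",
    "kld",
    "pged",
    "graph_distance",
    "structural_distribution",
]

#: The five distance measures, in canonical reporting order.
MEASURES = ("pged", "kld_degree", "kld_distance", "kld_spheres", "kld_orbits")

#: Measures defined only on connected graphs (reduced to the LCC internally).
CONNECTED_ONLY = ("kld_spheres", "kld_orbits")


@dataclass(frozen=True)
class StructuralDistribution:
    """A discrete probability distribution over a structural feature.

    For ``degree``, ``distance`` and ``orbit`` kinds the support is the
    integer range ``support_start .. support_start + len(probs) - 1``
    (degree k starting at 0; path length l and orbit size s starting at 1).
    For the ``sphere`` kind the support is the graph's vertex set and
    ``labels`` carries the vertex labels, in sorted order, aligned with
    ``probs``.
    """

    kind: str
    support_start: int
    probs: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.size == 0:
            raise ValueError("empty distribution")
        if (p < 0).any():
            raise ValueError("negative probabilities")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {p.sum()}, not 1")
        if self.labels is not None and len(self.labels) != p.size:
            raise ValueError("labels/probs length mismatch")

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.support_start, self.support_start + self.probs.size)

    def to_tsv(self, path: str | Path) -> None:
        """Export as two-column TSV (support value, probability)."""
        with open(path, "w") as fh:
            fh.write(f"# kind={self.kind}\n")
            keys = self.labels if self.labels is not None else self.support
            for k, p in zip(keys, self.probs):
                fh.write(f"{k}\t{p:.12g}\n")


@dataclass(frozen=True)
class SphereConfig:
    """Weights for the sphere-based information functional.

    The functional assigns ``f(v) = Σ_j c_j |S_j(v)|`` where ``S_j(v)`` is
    the j-th sphere (vertices at exact shortest-path distance j from v) and
    the weights decrease exponentially, ``c_j = weight_base**j``, emphasizing
    vertices close to v.
    """

    weight_base: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.weight_base < 1.0:
            raise ValueError("weight_base must lie in (0, 1)")


@dataclass(frozen=True)
class KLDConfig:
    """Numerical settings for the Kullback-Leibler divergence."""

    epsilon: float = 1e-10
    log_base: str = "e"  # "e" (nats) or "2" (bits)

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.log_base not in ("e", "2"):
            raise ValueError("log_base must be 'e' or '2'")


def degree_distribution(g: LabeledGraph) -> StructuralDistribution:
    """P(k) = fraction of vertices with exactly k neighbors, k = 0..k_max.

    Computed on the complete (possibly disconnected) graph; after cohort
    alignment isolated vertices contribute to P(0).
    """
    if g.n == 0:
        raise ValueError("degree distribution undefined for empty graph")
    degs = np.array([d for _, d in g.graph.degree()], dtype=int)
    counts = np.bincount(degs, minlength=degs.max() + 1)
    return StructuralDistribution("degree", 0, counts / g.n)


def distance_distribution(g: LabeledGraph) -> StructuralDistribution:
    """P(l) = fraction of connected vertex pairs at shortest-path distance l.

    Unordered pairs; infinite distances (cross-component pairs) are ignored,
    so the distribution is defined on disconnected graphs as long as at
    least one edge exists.  The support runs l = 1..diameter (of the largest
    finite distance).
    """
    if g.n == 0:
        raise ValueError("distance distribution undefined for empty graph")
    counts: dict[int, int] = {}
    for _, dists in nx.all_pairs_shortest_path_length(g.graph):
        for l in dists.values():
            if l > 0:
                counts[l] = counts.get(l, 0) + 1
    if not counts:
        raise ValueError(
            "distance distribution undefined: graph has no connected vertex pair"
        )
    diam = max(counts)
    arr = np.zeros(diam, dtype=float)
    for l, c in counts.items():
        arr[l - 1] = c / 2  # each unordered pair counted twice
    return StructuralDistribution("distance", 1, arr / arr.sum())


def sphere_probabilities(
    g: LabeledGraph, cfg: SphereConfig = SphereConfig()
) -> StructuralDistribution:
    """Sphere-based vertex probabilities p(v) = f(v) / Σ_u f(u).

    ``f(v) = Σ_{j=1..ecc(v)} c_j |S_j(v)|`` with ``c_j = weight_base**j``.
    Defined on connected graphs with at least two vertices (callers pass the
    largest connected component).  Probabilities are returned over vertices
    in sorted-label order.
    """
    if g.n == 0:
        raise ValueError("sphere probabilities undefined for empty graph")
    if not g.is_connected():
        raise ValueError(
            "sphere probabilities require a connected graph; "
            "reduce to the largest connected component first"
        )
    if g.n == 1:
        raise ValueError("sphere probabilities undefined for a single vertex")
    labels = g.vertices
    f = np.zeros(len(labels))
    index = {v: i for i, v in enumerate(labels)}
    b = cfg.weight_base
    for v, dists in nx.all_pairs_shortest_path_length(g.graph):
        sizes = np.bincount(list(dists.values()))
        js = np.arange(1, sizes.size)
        f[index[v]] = float(np.sum(b ** js * sizes[1:]))
    total = f.sum()
    return StructuralDistribution("sphere", 0, f / total, labels=labels)


def _to_igraph(g: LabeledGraph) -> tuple[ig.Graph, tuple[str, ...]]:
    labels = g.vertices
    index = {v: i for i, v in enumerate(labels)}
    edges = [(index[u], index[v]) for u, v in g.graph.edges]
    return ig.Graph(n=len(labels), edges=edges), labels


def automorphism_orbits(g: LabeledGraph) -> list[set[str]]:
    """Vertex orbits of the automorphism group of the unlabeled topology.

    Exact orbits are obtained from a generating set of the automorphism
    group (BLISS canonical-labeling search via igraph) by uniting each
    vertex with its images under every generator; the connected classes of
    that relation are the orbits.
    """
    if g.n == 0:
        raise ValueError("orbits undefined for empty graph")
    igg, labels = _to_igraph(g)
    n = len(labels)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for gen in igg.automorphism_group():
        for v, image in enumerate(gen):
            union(v, image)
    orbits: dict[int, set[str]] = {}
    for v in range(n):
        orbits.setdefault(find(v), set()).add(labels[v])
    return sorted(orbits.values(), key=lambda s: min(s))


def orbit_distribution(g: LabeledGraph) -> StructuralDistribution:
    """P(s) = n_s / N_orb over orbit sizes s = 1..max.

    ``n_s`` counts the automorphism orbits containing exactly s vertices and
    ``N_orb`` is the total number of orbits.  Defined on connected graphs
    (callers pass the largest connected component).
    """
    if g.n == 0:
        raise ValueError("orbit distribution undefined for empty graph")
    if not g.is_connected():
        raise ValueError(
            "orbit distribution requires a connected graph; "
            "reduce to the largest connected component first"
        )
    orbits = automorphism_orbits(g)
    sizes = np.array([len(o) for o in orbits], dtype=int)
    counts = np.bincount(sizes, minlength=sizes.max() + 1)[1:]
    return StructuralDistribution("orbit", 1, counts / len(orbits))


def _aligned_vectors(
    p: StructuralDistribution, q: StructuralDistribution
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-pad two same-kind distributions onto their union support."""
    if p.kind != q.kind:
        raise ValueError(f"kind mismatch: {p.kind} vs {q.kind}")
    if p.labels is not None or q.labels is not None:
        union = sorted(set(p.labels or ()) | set(q.labels or ()))
        pi = {v: i for i, v in enumerate(p.labels or ())}
        qi = {v: i for i, v in enumerate(q.labels or ())}
        pv = np.array([p.probs[pi[v]] if v in pi else 0.0 for v in union])
        qv = np.array([q.probs[qi[v]] if v in qi else 0.0 for v in union])
        return pv, qv
    if p.support_start != q.support_start:
        raise ValueError("support_start mismatch for same-kind distributions")
    size = max(p.probs.size, q.probs.size)
    pv = np.zeros(size)
    qv = np.zeros(size)
    pv[: p.probs.size] = p.probs
    qv[: q.probs.size] = q.probs
    return pv, qv


def kld(
    p: StructuralDistribution,
    q: StructuralDistribution,
    cfg: KLDConfig = KLDConfig(),
) -> float:
    """Kullback-Leibler divergence D(P||Q) between same-kind distributions.

    Supports are aligned to the union support by zero-padding; every zero
    entry of either vector is then replaced by ``cfg.epsilon`` (without
    renormalization) so the divergence stays finite when Q has empty bins.
    Asymmetric: the first argument is the reference distribution.
    """
    pv, qv = _aligned_vectors(p, q)
    eps = cfg.epsilon
    pv = np.where(pv == 0.0, eps, pv)
    qv = np.where(qv == 0.0, eps, qv)
    d = float(np.sum(pv * np.log(pv / qv)))
    if cfg.log_base == "2":
        d /= np.log(2.0)
    return d


def pged(g1: LabeledGraph, g2: LabeledGraph) -> float:
    """Normalized graph edit distance on a shared uniquely-labeled vertex set.

    With identical vertex sets the optimal edit sequence touches edges only,
    so GED = |E1 Δ E2| with unit insert/delete costs, and
    pGED = GED / (n(n-1)/2).  Symmetric; 0 for identical graphs; 1 for the
    complete vs. the edgeless graph.
    """
    if set(g1.graph.nodes) != set(g2.graph.nodes):
        raise ValueError(
            "pged requires identical vertex sets; align the cohort first"
        )
    n = g1.n
    if n < 2:
        return 0.0
    ged = len(g1.edges ^ g2.edges)
    return ged / (n * (n - 1) / 2)


def structural_distribution(
    g: LabeledGraph,
    measure: str,
    sphere_cfg: SphereConfig = SphereConfig(),
) -> StructuralDistribution:
    """The distribution underlying a KLD measure, with LCC reduction applied
    for the connected-only measures."""
    if measure == "kld_degree":
        return degree_distribution(g)
    if measure == "kld_distance":
        return distance_distribution(g)
    if measure == "kld_spheres":
        return sphere_probabilities(largest_connected_component(g), sphere_cfg)
    if measure == "kld_orbits":
        return orbit_distribution(largest_connected_component(g))
    raise ValueError(f"unknown KLD measure {measure!r}")


def graph_distance(
    g1: LabeledGraph,
    g2: LabeledGraph,
    measure: str,
    sphere_cfg: SphereConfig = SphereConfig(),
    kld_cfg: KLDConfig = KLDConfig(),
) -> float:
    """Dispatch to one of the five distance measures.

    For the KLD measures the result is D(P_{g1} || P_{g2}) — the first graph
    supplies the reference distribution.
    """
    if measure == "pged":
        return pged(g1, g2)
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    p = structural_distribution(g1, measure, sphere_cfg)
    q = structural_distribution(g2, measure, sphere_cfg)
    return kld(p, q, kld_cfg)
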