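"""Synthetic cohorts with known ground truth.

Real inputs to the prototyping workflow are co-expression networks inferred
from independent expression studies: sparse graphs on a shared gene set with
heavy-tailed (approximately power-law) degree distributions, where networks
within a group are perturbed variants of a common underlying structure.
This module emulates exactly that:

* a **base graph** drawn from the Barabási–Albert preferential-attachment
  model (sparse, scale-free, uniquely labeled ``g0001..gN``);
* **perturbed copies** obtained by rewiring a fixed fraction of edges —
  edges removed uniformly at random and replaced by uniformly sampled
  non-edges, so the edge count is preserved and distances reflect rewiring
  rather than density;
* **two-group cohorts** whose groups are independent perturbations of a
  shared (or group-specific) base at group-specific noise levels, emitted
  together with a ground-truth record of bases, seeds and noise levels.

Defaults mirror the motivating study design: group sizes 6 and 7 on a
shared vertex set, sparse scale-free topology.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .graphio import Cohort, LabeledGraph, write_edge_list, write_groups

__all__ = [
    "CohortSpec",
    "make_base_graph",
    "perturb",
    "make_cohort",
    "make_planted_set",
    "write_cohort",
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a two-group synthetic cohort.

    ``attachment_edges`` is the number of edges each newly attached vertex
    brings in the preferential-attachment construction (graph sparsity);
    ``rewire_fractions`` are the per-group perturbation noise levels.
    """

    n_vertices: int = 500
    attachment_edges: int = 2
    group_sizes: tuple[int, int] = (6, 7)
    rewire_fractions: tuple[float, float] = (0.02, 0.02)
    group_names: tuple[str, str] = ("benign", "cancer")
    shared_base: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.attachment_edges < 1 or self.n_vertices <= self.attachment_edges:
            raise ValueError("require n_vertices > attachment_edges >= 1")
        if any(s < 2 for s in self.group_sizes):
            raise ValueError("group sizes must be >= 2")
        if any(not 0.0 <= f <= 1.0 for f in self.rewire_fractions):
            raise ValueError("rewire fractions must lie in [0, 1]")


def _child_seeds(seed: int, k: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(k, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]


def _labels(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i + 1:0{width}d}" for i in range(n)]


def make_base_graph(spec: CohortSpec, index: int = 0) -> LabeledGraph:
    """Preferential-attachment base graph, deterministic under the seed.

    ``index`` distinguishes the two group bases when ``shared_base`` is
    False.  The construction starts from ``attachment_edges`` isolated seed
    vertices and attaches each new vertex with ``attachment_edges`` edges,
    giving m·(n−m) edges in total.
    """
    seed = _child_seeds(spec.seed, 2)[index]
    raw = nx.barabasi_albert_graph(spec.n_vertices, spec.attachment_edges, seed=seed)
    labels = _labels(spec.n_vertices)
    g = nx.relabel_nodes(raw, {i: labels[i] for i in raw.nodes})
    return LabeledGraph(f"base_{index}", g)


def perturb(g: LabeledGraph, rewire_fraction: float, seed: int) -> LabeledGraph:
    """Rewire a fraction of edges, preserving vertex set and edge count.

    ``floor(fraction·|E|)`` edges are removed uniformly at random and the
    same number of distinct non-edges of the original graph are added,
    sampled uniformly.  Raises if the graph is too dense to place the
    replacement edges.
    """
    if not 0.0 <= rewire_fraction <= 1.0:
        raise ValueError("rewire_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    edges = sorted(tuple(sorted(e)) for e in g.graph.edges)
    n_rewire = int(rewire_fraction * len(edges))
    if n_rewire == 0:
        return LabeledGraph(g.name, g.graph.copy())
    labels = g.vertices
    n = len(labels)
    max_edges = n * (n - 1) // 2
    n_non_edges = max_edges - len(edges)
    if n_non_edges < n_rewire:
        raise ValueError(
            f"graph too dense: need {n_rewire} replacement non-edges, "
            f"only {n_non_edges} exist"
        )
    remove_idx = rng.choice(len(edges), size=n_rewire, replace=False)
    removed = {edges[i] for i in remove_idx}
    existing = set(edges)
    new_edges: set[tuple[str, str]] = set()
    if n_non_edges <= 4 * n_rewire:
        # dense regime: enumerate non-edges and sample exactly
        non_edges = [
            (labels[i], labels[j])
            for i in range(n)
            for j in range(i + 1, n)
            if (labels[i], labels[j]) not in existing
        ]
        pick = rng.choice(len(non_edges), size=n_rewire, replace=False)
        new_edges = {non_edges[i] for i in pick}
    else:
        while len(new_edges) < n_rewire:
            i, j = rng.integers(0, n, size=2)
            if i == j:
                continue
            e = (labels[min(i, j)], labels[max(i, j)])
            if e in existing or e in new_edges:
                continue
            new_edges.add(e)
    h = g.graph.copy()
    h.remove_edges_from(removed)
    h.add_edges_from(new_edges)
    return LabeledGraph(g.name, h)


def make_cohort(spec: CohortSpec) -> tuple[Cohort, dict]:
    """Two groups of independent perturbations, with a ground-truth record.

    Each group's graphs are independent rewirings of its base graph at the
    group's noise level.  The returned ground truth records the spec, the
    per-graph rewiring seeds and the base graphs' names so experiments can
    verify recovery against construction.
    """
    bases = [make_base_graph(spec, 0)]
    bases.append(bases[0] if spec.shared_base else make_base_graph(spec, 1))
    total = sum(spec.group_sizes)
    seeds = _child_seeds(spec.seed + 1, total)
    graphs: list[LabeledGraph] = []
    group_of: dict[str, str] = {}
    truth_graphs = {}
    k = 0
    for gi, (grp, size, frac) in enumerate(
        zip(spec.group_names, spec.group_sizes, spec.rewire_fractions)
    ):
        for i in range(size):
            name = f"{grp}_{i + 1:02d}"
            pg = perturb(bases[gi], frac, seeds[k]).with_name(name)
            graphs.append(pg)
            group_of[name] = grp
            truth_graphs[name] = {
                "group": grp,
                "base": bases[gi].name,
                "rewire_fraction": frac,
                "seed": seeds[k],
            }
            k += 1
    truth = {
        "spec": asdict(spec),
        "bases": {b.name: {"n": b.n, "edges": b.n_edges} for b in bases[:1]}
        if spec.shared_base
        else {b.name: {"n": b.n, "edges": b.n_edges} for b in bases},
        "graphs": truth_graphs,
    }
    return Cohort(graphs, group_of), truth


def make_planted_set(
    n_vertices: int = 500,
    attachment_edges: int = 2,
    n_copies: int = 6,
    rewire_fraction: float = 0.02,
    seed: int = 0,
) -> list[LabeledGraph]:
    """A base graph followed by independent perturbed copies.

    The base is the planted ground-truth prototype: it sits at rewiring
    distance f from every copy while the copies sit at roughly 2f from one
    another, so prototype selection should recover it.
    """
    spec = CohortSpec(
        n_vertices=n_vertices, attachment_edges=attachment_edges, seed=seed
    )
    base = make_base_graph(spec).with_name("base")
    seeds = _child_seeds(seed + 1, n_copies)
    copies = [
        perturb(base, rewire_fraction, s).with_name(f"copy_{i + 1:02d}")
        for i, s in enumerate(seeds)
    ]
    return [base] + copies


def write_cohort(
    cohort: Cohort, truth: dict, outdir: str | Path
) -> list[Path]:
    """Write a cohort as edge-list TSVs + groups.tsv + truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for g in cohort.graphs:
        p = outdir / f"{g.name}.tsv"
        write_edge_list(g, p)
        written.append(p)
    gp = outdir / "groups.tsv"
    write_groups(cohort.group_of, gp)
    written.append(gp)
    tp = outdir / "truth.json"
    with open(tp, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(tp)
    return written
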