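"""Prototype selection: pick the network with minimal mean distance.

Given a set of m networks and a pairwise distance measure d, the graph
prototype is

    G* = argmin_i  d̄_i,      d̄_i = (1/(m-1)) Σ_{j≠i} d(G_i, G_j)

i.e. the existing network closest on average to all others — a representative
selected from the set, not a consensus construction.  For the asymmetric KLD
measures the default convention averages outgoing distances D(P_i || P_j)
(row means); incoming (column) means are available behind a flag.

No quality threshold is applied: one network is always selected, regardless
of how large the distances are.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .graphio import LabeledGraph
from .structdist import (
    KLDConfig,
    MEASURES,
    SphereConfig,
    kld,
    pged,
    structural_distribution,
)

__all__ = [
    "DistanceMatrix",
    "PrototypeResult",
    "distance_matrix",
    "mean_distances",
    "select_prototype",
]

#: tie tolerance for co-minimal mean distances
TIE_TOL = 1e-12


@dataclass
class DistanceMatrix:
    """m×m pairwise distances for one measure; row i holds d(G_i, ·)."""

    measure: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.names = tuple(self.names)
        v = np.asarray(self.values, dtype=float)
        m = len(self.names)
        if v.shape != (m, m):
            raise ValueError(f"expected {m}x{m} matrix, got {v.shape}")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-9:
            raise ValueError("diagonal must be ~0")
        if v.min(initial=0.0) < -1e-12:
            raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def m(self) -> int:
        return len(self.names)

    def submatrix(self, names: list[str]) -> "DistanceMatrix":
        idx = [self.names.index(n) for n in names]
        return DistanceMatrix(
            self.measure, tuple(names), self.values[np.ix_(idx, idx)]
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# measure=%s (rows: from, cols: to)\n" % self.measure)
            fh.write("name\t" + "\t".join(self.names) + "\n")
            for name, row in zip(self.names, self.values):
                fh.write(name + "\t" + "\t".join(f"{x:.12g}" for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        measure = "unknown"
        names: list[str] = []
        rows: list[list[float]] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# measure="):
                    measure = line.split("=", 1)[1].split()[0]
                    continue
                if not line or line.startswith("#") or line.startswith("name\t"):
                    continue
                fields = line.split("\t")
                names.append(fields[0])
                rows.append([float(x) for x in fields[1:]])
        return cls(measure, tuple(names), np.array(rows))


@dataclass
class PrototypeResult:
    """Mean distances per graph and the selected prototype for one measure."""

    measure: str
    mean_distances: dict[str, float]
    prototype: str
    ties: list[str]


def distance_matrix(
    graphs: list[LabeledGraph],
    measure: str,
    sphere_cfg: SphereConfig = SphereConfig(),
    kld_cfg: KLDConfig = KLDConfig(),
) -> DistanceMatrix:
    """All pairwise distances under one measure.

    For the KLD measures each graph's structural distribution is computed
    once and reused across the m(m-1) pairs, which matters for the
    shortest-path and orbit based measures on larger networks.
    """
    if len(graphs) < 2:
        raise ValueError("need at least 2 graphs for a distance matrix")
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    names = tuple(g.name for g in graphs)
    m = len(graphs)
    values = np.zeros((m, m))
    if measure == "pged":
        for i in range(m):
            for j in range(i + 1, m):
                values[i, j] = values[j, i] = pged(graphs[i], graphs[j])
    else:
        dists = [structural_distribution(g, measure, sphere_cfg) for g in graphs]
        for i in range(m):
            for j in range(m):
                if i != j:
                    values[i, j] = kld(dists[i], dists[j], kld_cfg)
    return DistanceMatrix(measure, names, values)


def mean_distances(
    dm: DistanceMatrix, direction: str = "row"
) -> dict[str, float]:
    """Mean distance from each graph to all others, excluding the diagonal.

    ``direction="row"`` averages outgoing distances d(G_i, ·) (the default,
    used for prototype selection); ``"column"`` averages incoming ones —
    identical for symmetric measures.
    """
    if dm.m < 2:
        raise ValueError("need at least 2 graphs")
    v = dm.values if direction == "row" else dm.values.T
    if direction not in ("row", "column"):
        raise ValueError("direction must be 'row' or 'column'")
    off = v.sum(axis=1) - np.diag(v)
    means = off / (dm.m - 1)
    return {name: float(d) for name, d in zip(dm.names, means)}


def select_prototype(
    dm: DistanceMatrix, direction: str = "row"
) -> PrototypeResult:
    """Select the graph with minimal mean distance to the rest of the set.

    Exact ties (within 1e-12 of the minimum) are reported in ``ties`` and
    broken deterministically by input order.
    """
    means = mean_distances(dm, direction=direction)
    best = min(means.values())
    ties = [n for n in dm.names if means[n] <= best + TIE_TOL]
    return PrototypeResult(dm.measure, means, ties[0], ties)
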