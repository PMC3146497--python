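"""Between-group statistics, feature clustering, and prototype topology.

Three analyses sit on top of the per-measure distance matrices:

* **Group comparison** — for each measure, the within-group pairwise
  distances of the two groups are compared with a two-sided Wilcoxon
  rank-sum (Mann-Whitney) test, Bonferroni-corrected across measures.
  Symmetric measures (pGED) contribute each unordered pair once,
  asymmetric KLD measures contribute both directions.
* **Feature clustering** — each network is described by its mean distance
  to the other networks of its own group, one feature per measure; rows
  are min-max normalized jointly over all networks (without group
  information), and the columns are clustered agglomeratively with
  Euclidean distance (complete or average linkage).
* **Topology summaries** of selected prototypes — hub-degree table,
  eccentricities, diameter, average path length (largest connected
  component), average local clustering coefficient; plus a two-sample
  Kolmogorov-Smirnov comparison of eccentricity distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats
from scipy.cluster import hierarchy

from .graphio import LabeledGraph, largest_connected_component
from .prototyping import DistanceMatrix

__all__ = [
    "MeasureComparison",
    "CohortComparison",
    "ClusterFeatures",
    "TopologySummary",
    "within_group_distances",
    "within_group_mean_distances",
    "compare_groups",
    "compare_cohort",
    "cluster_features",
    "topology_summary",
    "compare_eccentricities",
]

SYMMETRIC_MEASURES = ("pged",)


@dataclass
class MeasureComparison:
    """Wilcoxon rank-sum comparison of within-group distances for one measure."""

    measure: str
    statistic: float  # Mann-Whitney U of the first group
    p_raw: float
    p_adjusted: float
    significant: bool
    n_a: int
    n_b: int
    method: str  # "exact" or "asymptotic"


@dataclass
class CohortComparison:
    rows: list[MeasureComparison]
    samples: dict[str, dict[str, list[float]]] = field(default_factory=dict)
    alpha: float = 0.05


@dataclass
class ClusterFeatures:
    """Per-measure normalized feature matrix and its column dendrogram."""

    measures: tuple[str, ...]
    names: tuple[str, ...]
    matrix: np.ndarray  # rows = measures, columns = graphs, in [0, 1]
    linkage_method: str
    linkage: np.ndarray  # scipy linkage matrix over columns


@dataclass
class TopologySummary:
    name: str
    hub_table: list[tuple[int, int]]  # (degree, count), degree descending
    eccentricities: dict[str, int]  # on the largest connected component
    diameter: int
    avg_path_length: float
    avg_clustering: float


def within_group_distances(
    dm: DistanceMatrix, groups: dict[str, str]
) -> dict[str, list[float]]:
    """Within-group pairwise distance samples, per group.

    Symmetric measures yield each unordered pair once (m_g(m_g-1)/2 values);
    asymmetric measures yield ordered pairs (m_g(m_g-1) values), since
    D(P_i||P_j) and D(P_j||P_i) are genuinely different observations.
    """
    missing = [n for n in dm.names if n not in groups]
    if missing:
        raise ValueError(f"graphs without group assignment: {missing}")
    symmetric = dm.measure in SYMMETRIC_MEASURES
    out: dict[str, list[float]] = {}
    group_order: list[str] = []
    for n in dm.names:
        if groups[n] not in group_order:
            group_order.append(groups[n])
    for grp in group_order:
        idx = [i for i, n in enumerate(dm.names) if groups[n] == grp]
        vals: list[float] = []
        for a, i in enumerate(idx):
            for j in idx[a + 1 :] if symmetric else idx:
                if i != j:
                    vals.append(float(dm.values[i, j]))
        if len(idx) < 2:
            warnings.warn(f"group {grp!r} has fewer than 2 graphs; no distances")
        out[grp] = vals
    return out


def within_group_mean_distances(
    dm: DistanceMatrix, groups: dict[str, str]
) -> dict[str, float]:
    """Mean distance from each graph to the other graphs of its own group
    (row/outgoing direction)."""
    out: dict[str, float] = {}
    for i, n in enumerate(dm.names):
        idx = [
            j
            for j, other in enumerate(dm.names)
            if j != i and groups[other] == groups[n]
        ]
        if not idx:
            warnings.warn(f"graph {n!r} is alone in its group; mean set to 0")
            out[n] = 0.0
        else:
            out[n] = float(dm.values[i, idx].mean())
    return out


def compare_groups(
    samples_a: list[float],
    samples_b: list[float],
    n_measures: int = 1,
    alpha: float = 0.05,
    measure: str = "",
) -> MeasureComparison:
    """Two-sided Wilcoxon rank-sum test with Bonferroni adjustment.

    The exact null distribution is used when both samples have at most 25
    observations and there are no ties; otherwise the normal approximation
    with continuity and tie correction.  The adjusted p-value is
    min(1, raw_p * n_measures).
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 25 and b.size <= 25 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    p_raw = float(res.pvalue)
    p_adj = min(1.0, p_raw * n_measures)
    return MeasureComparison(
        measure=measure,
        statistic=float(res.statistic),
        p_raw=p_raw,
        p_adjusted=p_adj,
        significant=p_adj < alpha,
        n_a=int(a.size),
        n_b=int(b.size),
        method=method,
    )


def compare_cohort(
    matrices: dict[str, DistanceMatrix],
    groups: dict[str, str],
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
) -> CohortComparison:
    """Wilcoxon comparison of the two groups' within-group distances, for
    every measure, Bonferroni-corrected by the number of measures run."""
    n_measures = len(matrices)
    rows = []
    samples: dict[str, dict[str, list[float]]] = {}
    for measure, dm in matrices.items():
        wg = within_group_distances(dm, groups)
        samples[measure] = {group_a: wg[group_a], group_b: wg[group_b]}
        rows.append(
            compare_groups(
                wg[group_a], wg[group_b], n_measures, alpha, measure=measure
            )
        )
    return CohortComparison(rows=rows, samples=samples, alpha=alpha)


def cluster_features(
    mean_dists: dict[str, dict[str, float]],
    linkage: str = "complete",
) -> ClusterFeatures:
    """Min-max normalized feature matrix and agglomerative clustering.

    ``mean_dists`` maps measure -> (graph name -> within-group mean
    distance).  Each measure's row is normalized to [0, 1] over all graphs
    jointly; a constant row carries no information and is set to 0 with a
    warning.  Columns (networks) are clustered with Euclidean distance and
    the requested linkage (complete or average).
    """
    if linkage not in ("complete", "average"):
        raise ValueError("linkage must be 'complete' or 'average'")
    measures = tuple(mean_dists)
    names: tuple[str, ...] = ()
    for vals in mean_dists.values():
        if not names:
            names = tuple(vals)
        elif set(names) != set(vals):
            raise ValueError("measures cover different graph sets")
    mat = np.zeros((len(measures), len(names)))
    for r, measure in enumerate(measures):
        row = np.array([mean_dists[measure][n] for n in names], dtype=float)
        span = row.max() - row.min()
        if span == 0:
            warnings.warn(f"constant feature row for {measure!r}; set to 0")
            mat[r] = 0.0
        else:
            mat[r] = (row - row.min()) / span
    Z = hierarchy.linkage(mat.T, method=linkage, metric="euclidean")
    return ClusterFeatures(measures, names, mat, linkage, Z)


def topology_summary(g: LabeledGraph) -> TopologySummary:
    """Topological characterization of one network.

    The hub table lists the 15 largest distinct degree values with the
    number of vertices attaining each.  Eccentricities, diameter and average
    path length are computed on the largest connected component; the average
    local clustering coefficient is taken over all LCC vertices, with
    degree-<2 vertices contributing 0.
    """
    if g.n == 0:
        raise ValueError("topology summary undefined for empty graph")
    degs = sorted((d for _, d in g.graph.degree()), reverse=True)
    hub_table: list[tuple[int, int]] = []
    for d in degs:
        if hub_table and hub_table[-1][0] == d:
            hub_table[-1] = (d, hub_table[-1][1] + 1)
        elif len(hub_table) < 15:
            hub_table.append((d, 1))
        else:
            break
    lcc = largest_connected_component(g)
    ecc = {v: int(e) for v, e in nx.eccentricity(lcc.graph).items()}
    diameter = max(ecc.values())
    apl = (
        float(nx.average_shortest_path_length(lcc.graph)) if lcc.n > 1 else 0.0
    )
    clust = nx.clustering(lcc.graph)  # 0 for degree-<2 vertices
    avg_clust = float(np.mean(list(clust.values())))
    return TopologySummary(
        name=g.name,
        hub_table=hub_table,
        eccentricities=ecc,
        diameter=diameter,
        avg_path_length=apl,
        avg_clustering=avg_clust,
    )


def compare_eccentricities(
    g1: LabeledGraph, g2: LabeledGraph
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on vertex eccentricities.

    Eccentricities are computed on each graph's largest connected component;
    returns (KS statistic D, p-value)."""
    if g1.n == 0 or g2.n == 0:
        raise ValueError("eccentricity comparison undefined for empty graph")
    e1 = list(nx.eccentricity(largest_connected_component(g1).graph).values())
    e2 = list(nx.eccentricity(largest_connected_component(g2).graph).values())
    res = stats.ks_2samp(e1, e2, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
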