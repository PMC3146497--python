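# Methods

## Model and procedure

The package operates on cohorts of undirected simple graphs with unique
string vertex labels. A cohort is first **aligned**: every graph's vertex
set is extended to the union of all vertex sets (added vertices are
isolated). Alignment is the precondition for the edit-distance measure and
makes whole-graph distributions comparable; in the co-expression setting it
corresponds to restricting all studies to a common gene universe.

For a set of m graphs and a pairwise distance d, the **graph prototype** is
the existing network with minimal mean distance to the others,
d̄ᵢ = (1/(m−1)) Σ_{j≠i} d(Gᵢ, Gⱼ). Selection is a representative choice,
not a consensus construction, and is applied with no quality threshold: one
network is always selected. Exact ties (within 1e-12) are broken by input
order and reported.

### Distance measures

* **pGED.** On a fixed uniquely-labeled vertex set, vertex operations are
  never needed and unit-cost edge edits give GED = |E₁ Δ E₂|, computed as a
  set symmetric difference. The normalization constant is the maximum
  possible edge count n(n−1)/2, mapping complete↔edgeless to 1.0; it is
  configurable in principle but fixed here because sparse biological
  networks live at pGED ≪ 1 either way. For n < 2 no edge slots exist and
  the distance is defined as 0.
* **KLD measures.** D(P‖Q) = Σᵢ Pᵢ log(Pᵢ/Qᵢ) over one of four structural
  distributions. Same-kind distributions are zero-padded to the union
  support (for sphere distributions, aligned on the union of vertex
  labels), then every zero entry of either vector is replaced by
  ε = 1e-10 **without renormalization**; the perturbation is bounded by
  support·ε and keeps the divergence finite when the second graph has empty
  bins. Natural logarithm by default (nats); base 2 available. Prototype
  selection is invariant to the base. The KLD is asymmetric; by convention
  the first (candidate) graph supplies the reference P, and mean distances
  average the outgoing direction D(Pᵢ‖Pⱼ) (row means). Incoming (column)
  means are available behind a flag.

### Structural distributions

* **Degree** P(k) = (#vertices of degree k)/n, k = 0..k_max, on the
  complete, possibly disconnected graph — isolated vertices created by
  alignment contribute to P(0).
* **Distance** P(l) = (#unordered vertex pairs at shortest-path distance
  l)/N, l = 1..diameter, where N counts finite pairs only; defined for any
  graph with at least one edge.
* **Sphere vertex probabilities** p(v) = f(v)/Σᵤ f(u) with the information
  functional f(v) = Σ_{j=1..ecc(v)} cⱼ·|Sⱼ(v)|, Sⱼ(v) the set of vertices
  at exact distance j from v, and exponentially decreasing weights
  cⱼ = bʲ. The default base b = 0.5 emphasizes the immediate neighborhood —
  the vertices most affected by information spreading from v; b is
  configurable in (0,1). Requires a connected graph with ≥ 2 vertices.
* **Orbit sizes** P(s) = n_s/N_orb, where n_s counts automorphism orbits of
  exactly s vertices and N_orb is the total number of orbits. Orbits are
  exact: a generating set of the automorphism group is computed with
  igraph's BLISS backend and vertices are united with their images under
  every generator. (Color refinement alone would merge non-equivalent
  vertices; the test suite checks the orbits against brute-force
  enumeration of all vertex permutations for n ≤ 7.)

The sphere and orbit measures are defined on connected graphs, so the
corresponding distance operations reduce each input to its largest connected
component (ties between equal components broken by smallest member label).

### Group statistics

Within-group pairwise distances of two groups are compared per measure with
a two-sided Wilcoxon rank-sum (Mann-Whitney) test: the exact null
distribution when both samples have ≤ 25 tie-free observations, otherwise
the normal approximation with continuity and tie correction. Symmetric
measures contribute each unordered pair once (m_g(m_g−1)/2 values),
asymmetric KLD measures both directions (m_g(m_g−1) values) — the two
directions are genuinely different observations. P-values are
Bonferroni-adjusted by the number of measures run (default 5), α = 0.05.

For pattern discovery each network is described by its mean distance to the
other networks *of its own group*, one feature per measure; rows are
min-max normalized over all networks jointly (without group information;
constant rows carry no information and are zeroed with a warning) and the
networks are clustered agglomeratively with Euclidean distance and complete
or average linkage.

Prototype topology reports: the 15 largest distinct degree values with
counts (hub table, computed on the full graph), per-vertex eccentricities,
diameter (= max eccentricity) and average path length on the largest
connected component, and the mean local clustering coefficient over all LCC
vertices with degree-<2 vertices contributing 0 (a stated convention;
excluding them is the other common choice). Eccentricity distributions of
two networks are compared with a two-sample Kolmogorov-Smirnov test.

## Synthetic cohorts

The generator emulates the statistical structure of multi-study
co-expression cohorts: a **Barabási–Albert preferential-attachment base
graph** (sparse, heavy-tailed degree distribution) on labels `g0001..gN`,
and per-group **edge rewiring** that removes ⌊f·|E|⌋ edges uniformly and
replaces them with uniformly sampled non-edges. Rewiring preserves the edge
count so that distances reflect structural change, not density. Defaults:
n = 500 vertices, 2 attachment edges per vertex (≈ 996 edges), group sizes
(6, 7), rewire fraction 0.02 per group, shared base graph, fully
deterministic under the spec seed. These sizes keep every experiment in the
test suite within seconds while preserving the qualitative regime of
interest (sparse, hub-dominated, lightly perturbed).

What the generator does **not** emulate: expression-level noise and the
network-inference step (mutual-information estimation), study-specific gene
coverage, and correlated (non-uniform) edge rewiring. Passing tests
therefore demonstrate correctness of the measures, the selection criterion
and the statistics on structured random graphs — not robustness to
inference artifacts in real co-expression data.

## Numerical choices and edge cases

* ε = 1e-10 for KLD zero-replacement; distributions are stored un-ε'd and
  substitute only inside the divergence.
* Distribution supports are trimmed to the last non-zero entry and padded
  pairwise on comparison; degree support starts at k = 0, distance and
  orbit supports at 1.
* Distance matrices cache each graph's distribution once per measure
  (m distributions instead of m(m−1)).
* Empty graphs are rejected by every distribution; an edgeless graph has no
  finite vertex pair and no distance distribution; single-vertex graphs
  have f ≡ 0 and no sphere probabilities.
* mean-distance ties within 1e-12 are surfaced; runs are deterministic and
  output tables byte-identical under identical config + seed.

## Known limitations

* **Anti-conservative group test under strong per-graph effects.** The
  rank-sum test treats the within-group pairwise distances as independent,
  but they follow d(Gᵢ,Gⱼ) ≈ aᵢ + aⱼ + eᵢⱼ. With 6–7 graphs per group, a
  measure whose per-graph effects aᵢ are large — notably the degree-KLD on
  sparse networks, where the divergence is dominated by ε-penalized
  occupancy flicker of rare high-degree bins — yields markedly inflated
  type-I error (measured ≈ 16–23% at a nominal Bonferroni-adjusted 5% on
  equal-noise synthetic cohorts; `scripts/acceptance.py` reports the rate
  honestly). pGED, whose perturbation amount is homogeneous across graphs
  (every synthetic graph rewires exactly ⌊f|E|⌋ edges), is calibrated
  (≈ 3–7%) under the same conditions. Significant between-group results for
  KLD measures on small cohorts should therefore be read as descriptive,
  not confirmatory.
* Orbit computation is exact but the orbit-size distribution of large
  sparse random graphs is extremely coarse (most vertices are singleton
  orbits), so `kld_orbits` often degenerates and produces ties.
* The selection criterion always returns a prototype, however distant; no
  upper threshold on d̄ is applied.
* No weighted or directed graphs; weights in input files are parsed and
  dropped because every measure is topology-only.
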