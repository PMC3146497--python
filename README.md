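# graphproto

Structural comparison and **graph prototype selection** for cohorts of
uniquely-labeled biological networks.

## The problem

Integrative network biology often faces a set of comparable networks — for
example gene co-expression networks inferred from several independent
expression studies of the same disease — and needs one representative to
analyze further. Matching edges across studies is burdensome; instead, one
can select an existing network as the **graph prototype**: the network with
the least average structural distance to all others in its set,

    G* = argmin_i  d̄_i ,     d̄_i = 1/(m−1) · Σ_{j≠i} d(G_i, G_j) .

This package implements that selection for five distance measures, the
between-group statistics that ask whether within-group distances differ
between two cohorts (e.g. benign vs. cancer), and the topological
characterization of the selected prototypes. A synthetic-cohort generator
with known ground truth makes every step testable end to end.

## Distance measures

All networks are undirected, simple, and uniquely labeled (shared vertex set
after alignment).

| measure | definition |
|---|---|
| `pged` | normalized graph edit distance. On a fixed uniquely-labeled vertex set the optimal edit sequence touches edges only, so GED = \|E₁ Δ E₂\| and pGED = GED / (n(n−1)/2). |
| `kld_degree` | Kullback-Leibler divergence D(P‖Q) = Σᵢ Pᵢ log(Pᵢ/Qᵢ) between the two degree distributions P(k). |
| `kld_distance` | KLD between shortest-path-length distributions P(l), l = 1..diameter (finite pairs only). |
| `kld_spheres` | KLD between sphere-based vertex probabilities p(v) ∝ Σⱼ cⱼ·\|Sⱼ(v)\|, with Sⱼ(v) the j-th sphere around v and exponentially decreasing weights cⱼ = bʲ (b = 0.5). |
| `kld_orbits` | KLD between the distributions of automorphism-orbit sizes (orbits = classes of topologically equivalent vertices). |

Degree and distance distributions are computed on the complete, possibly
disconnected network; the sphere and orbit measures work on connected graphs
only and reduce each network to its largest connected component. Zero
probabilities are replaced by ε = 1e-10 inside the divergence; the KLD is
asymmetric, and mean distances default to the outgoing direction
D(Pᵢ‖P·). All conventions are configurable and logged with every run.

## Worked example

Generate a synthetic cohort — 6 "benign" and 7 "cancer" networks, each a
rewired copy of one 500-vertex scale-free base graph, with the cancer group
rewired at twice the noise (4% vs 2% of edges) — then run the full
comparison:

```sh
graphproto synth --out demo/cohort --seed 42 --noise 0.02,0.04
graphproto compare --graphs demo/cohort --groups demo/cohort/groups.tsv \
                   --out demo/results
```

`demo/results/prototypes.tsv` lists the selected prototype per measure and
group (excerpt):

```
measure   group   prototype   mean_distance
pged      benign  benign_01   0.000599599198397
pged      cancer  cancer_06   0.00121576486306
kld_spheres benign benign_06  0.00313987998129
kld_spheres cancer cancer_04  0.0113282928891
```

The benign prototype sits at mean pGED ≈ 0.0006 from its group — about half
the cancer group's 0.0012, reflecting the doubled rewiring noise.
`wilcoxon.tsv` holds the between-group tests (two-sided rank-sum on the
within-group distance samples, Bonferroni ×5):

```
measure      W    n_benign n_cancer p_raw              p_adjusted         significant
pged         0    15       21       2.63437295259e-07  1.31718647629e-06  true
kld_degree   555  30       42       0.394801318292     1                  false
kld_spheres  0    30       42       6.47068062463e-13  3.23534031231e-12  true
kld_orbits   185  30       42       2.22117806772e-07  1.11058903386e-06  true
```

Three of five measures separate the groups in this replicate. Each selected
prototype also gets a topology report (`topology_benign_01.tsv`: diameter 7,
average path length 3.78, average clustering 0.032, top hub degree 51).

The same workflow runs on real networks: put one edge-list TSV (or GraphML
file) per network in a directory, list their group assignments in a
two-column TSV, and point `graphproto compare` at them.

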