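"""Structural distributions, KLD, and the five distance measures."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graphproto import (
    LabeledGraph,
    degree_distribution,
    distance_distribution,
    graph_distance,
    kld,
    orbit_distribution,
    pged,
    sphere_probabilities,
)
from graphproto.structdist import (
    MEASURES,
    KLDConfig,
    SphereConfig,
    StructuralDistribution,
    automorphism_orbits,
)

from conftest import (
    brute_force_distance_counts,
    brute_force_orbits,
    complete_graph,
    random_connected_graph,
    random_labeled_graph,
)


def dist(probs, kind="degree", start=0, labels=None):
    return StructuralDistribution(kind, start, np.array(probs, dtype=float),
                                  labels=labels)


class TestStructuralDistribution:
    def test_rejects_bad_vectors(self):
        with pytest.raises(ValueError, match="sum"):
            dist([0.5, 0.4])
        with pytest.raises(ValueError, match="negative"):
            dist([1.5, -0.5])
        with pytest.raises(ValueError, match="empty"):
            dist([])

    def test_support_and_tsv_export(self, tmp_path):
        d = dist([0.25, 0.75], kind="distance", start=1)
        assert list(d.support) == [1, 2]
        p = tmp_path / "d.tsv"
        d.to_tsv(p)
        rows = [l.split("\t") for l in p.read_text().splitlines()
                if not l.startswith("#")]
        assert rows[0][0] == "1" and float(rows[1][1]) == 0.75


class TestDegreeDistribution:
    def test_star(self, star4):
        d = degree_distribution(star4)
        assert d.support_start == 0
        np.testing.assert_allclose(d.probs, [0, 0.75, 0, 0.25])

    def test_regular_and_edgeless(self, c5):
        np.testing.assert_allclose(degree_distribution(c5).probs, [0, 0, 1])
        edgeless = LabeledGraph.from_edges(
            "e", [], vertices=[f"v{i}" for i in range(10)])
        np.testing.assert_allclose(degree_distribution(edgeless).probs, [1.0])

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            degree_distribution(LabeledGraph("e", nx.Graph()))


class TestDistanceDistribution:
    def test_path_p4(self, p4):
        d = distance_distribution(p4)
        assert d.support_start == 1
        np.testing.assert_allclose(d.probs, [3 / 6, 2 / 6, 1 / 6])

    def test_complete_graph(self, k5):
        np.testing.assert_allclose(distance_distribution(k5).probs, [1.0])

    def test_disconnected_counts_finite_pairs_only(self):
        g = LabeledGraph.from_edges("g", [("a", "b"), ("c", "d")])
        d = distance_distribution(g)
        np.testing.assert_allclose(d.probs, [1.0])

    def test_edgeless_rejected(self):
        g = LabeledGraph.from_edges("g", [], vertices=["a", "b"])
        with pytest.raises(ValueError, match="no connected vertex pair"):
            distance_distribution(g)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 30))
    def test_matches_floyd_warshall_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        g = random_labeled_graph(n, 0.15, rng)
        if g.n_edges == 0:
            return
        counts = brute_force_distance_counts(g)
        total = sum(counts.values())
        expected = np.zeros(max(counts))
        for l, c in counts.items():
            expected[l - 1] = c / total
        np.testing.assert_allclose(distance_distribution(g).probs, expected)


class TestSphereProbabilities:
    def test_p3_hand_computed(self, p3):
        d = sphere_probabilities(p3, SphereConfig(weight_base=0.5))
        assert d.labels == ("a", "b", "c")
        np.testing.assert_allclose(d.probs, [0.3, 0.4, 0.3])

    @pytest.mark.parametrize(
        "maker",
        [
            lambda: LabeledGraph.from_edges(
                "C5", [(f"v{i}", f"v{(i + 1) % 5}") for i in range(5)]),
            lambda: complete_graph(6),
            lambda: LabeledGraph(
                "Q3",
                nx.relabel_nodes(nx.hypercube_graph(3),
                                 {v: str(v) for v in nx.hypercube_graph(3)})),
        ],
        ids=["cycle", "complete", "hypercube"],
    )
    def test_uniform_on_vertex_transitive_graphs(self, maker):
        g = maker()
        d = sphere_probabilities(g)
        np.testing.assert_allclose(d.probs, np.full(g.n, 1 / g.n))

    def test_c5_functional_value(self, c5):
        # f(v) = 0.5*2 + 0.25*2 = 1.5 for every vertex of the 5-cycle
        d = sphere_probabilities(c5)
        np.testing.assert_allclose(d.probs, np.full(5, 0.2))

    def test_rejects_disconnected_and_single_vertex(self):
        g = LabeledGraph.from_edges("g", [("a", "b")], vertices=["c"])
        with pytest.raises(ValueError, match="connected"):
            sphere_probabilities(g)
        one = LabeledGraph.from_edges("one", [], vertices=["a"])
        with pytest.raises(ValueError, match="single vertex"):
            sphere_probabilities(one)


class TestOrbitDistribution:
    def test_p3_two_orbits(self, p3):
        d = orbit_distribution(p3)
        np.testing.assert_allclose(d.probs, [0.5, 0.5])

    def test_k4_single_orbit(self, k4):
        d = orbit_distribution(k4)
        np.testing.assert_allclose(d.probs, [0, 0, 0, 1])

    def test_star_center_and_leaves(self, star4):
        d = orbit_distribution(star4)
        np.testing.assert_allclose(d.probs, [0.5, 0, 0.5])

    def test_orbits_p3(self, p3):
        assert automorphism_orbits(p3) == [{"a", "c"}, {"b"}]

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 7))
    def test_matches_brute_force_oracle(self, seed, n):
        """Orbits from group generators equal orbits from testing all n!
        permutations, on random connected graphs."""
        rng = np.random.default_rng(seed)
        g = random_connected_graph(n, 0.5, rng)
        assert automorphism_orbits(g) == brute_force_orbits(g)

    def test_rejects_disconnected(self):
        g = LabeledGraph.from_edges("g", [("a", "b")], vertices=["c"])
        with pytest.raises(ValueError, match="connected"):
            orbit_distribution(g)


class TestKLD:
    def test_identical_distributions_give_zero(self):
        p = dist([0.2, 0.3, 0.5])
        assert kld(p, p) == 0.0

    def test_hand_computed_value(self):
        p = dist([0.5, 0.5])
        q = dist([0.9, 0.1])
        expected = 0.5 * np.log(5 / 9) + 0.5 * np.log(5)
        assert kld(p, q) == pytest.approx(expected, abs=1e-12)
        assert kld(p, q) == pytest.approx(0.5108, abs=1e-4)

    def test_zero_bins_finite_via_epsilon(self):
        p = dist([0.5, 0.5, 0.0])
        q = dist([1.0, 0.0, 0.0])
        v = kld(p, q, KLDConfig(epsilon=1e-10))
        assert np.isfinite(v) and v > 0
        # closed form: 0.5 ln(0.5/1) + 0.5 ln(0.5/eps)
        assert v == pytest.approx(0.5 * np.log(0.5) + 0.5 * np.log(0.5e10),
                                  abs=1e-9)

    def test_union_support_padding(self):
        p = dist([1.0])
        q = dist([0.5, 0.5])
        assert np.isfinite(kld(p, q)) and np.isfinite(kld(q, p))

    def test_kind_mismatch_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            kld(dist([1.0], kind="degree"), dist([1.0], kind="orbit", start=1))

    def test_log_base_2(self):
        p = dist([0.5, 0.5])
        q = dist([0.9, 0.1])
        assert kld(p, q, KLDConfig(log_base="2")) == pytest.approx(
            kld(p, q) / np.log(2))

    def test_label_alignment_for_sphere_kind(self):
        p = dist([0.4, 0.6], kind="sphere", labels=("a", "b"))
        q = dist([0.5, 0.5], kind="sphere", labels=("b", "c"))
        assert np.isfinite(kld(p, q))
        assert kld(p, p) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1), min_size=2, max_size=8),
           st.lists(st.floats(0.01, 1), min_size=2, max_size=8))
    def test_non_negative(self, raw_p, raw_q):
        """D(P||Q) >= 0 up to epsilon-induced error (Gibbs' inequality)."""
        p = dist(np.array(raw_p) / np.sum(raw_p))
        q = dist(np.array(raw_q) / np.sum(raw_q))
        assert kld(p, q) >= -1e-12


class TestPGED:
    def test_identity_zero(self, p4):
        assert pged(p4, p4) == 0.0

    def test_complete_vs_edgeless_is_one(self, k4):
        edgeless = LabeledGraph.from_edges("e", [], vertices=k4.vertices)
        assert pged(k4, edgeless) == 1.0

    def test_p3_variants(self):
        g1 = LabeledGraph.from_edges("g1", [("a", "b"), ("b", "c")])
        g2 = LabeledGraph.from_edges("g2", [("a", "b"), ("a", "c")])
        assert pged(g1, g2) == pytest.approx(2 / 3)

    def test_vertex_set_mismatch_rejected(self, p3, p4):
        with pytest.raises(ValueError, match="vertex sets"):
            pged(p3, p4)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_symmetry_on_random_aligned_pairs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 25))
        g1 = random_labeled_graph(n, 0.3, rng, "g1")
        g2 = random_labeled_graph(n, 0.3, rng, "g2")
        assert pged(g1, g2) == pged(g2, g1)
        assert 0.0 <= pged(g1, g2) <= 1.0


class TestGraphDistance:
    @pytest.mark.parametrize("measure", MEASURES)
    def test_self_distance_zero(self, c5, measure):
        assert graph_distance(c5, c5, measure) == pytest.approx(0.0, abs=1e-9)

    def test_kld_degree_c5_vs_k5(self, c5, k5):
        # supports {2} vs {4} aligned to 0..4; value dominated by ln(1/eps)
        v = graph_distance(c5, k5, "kld_degree", kld_cfg=KLDConfig())
        assert v == pytest.approx(np.log(1e10), rel=1e-3)

    def test_connected_only_measures_reduce_to_lcc(self, p4):
        with_isolate = LabeledGraph.from_edges(
            "P4i", [("a", "b"), ("b", "c"), ("c", "d")], vertices=["e"])
        for m in ("kld_orbits", "kld_spheres"):
            assert graph_distance(with_isolate, p4, m) == pytest.approx(0.0)

    def test_unknown_measure_rejected(self, p4):
        with pytest.raises(ValueError, match="unknown measure"):
            graph_distance(p4, p4, "euclidean")

    @pytest.mark.parametrize("measure", MEASURES[1:])
    def test_distributions_sum_to_one(self, measure):
        """Every distribution backing a KLD measure is a proper probability
        vector with trimmed (positive-tail) support."""
        from graphproto.structdist import structural_distribution

        rng = np.random.default_rng(7)
        g = random_connected_graph(12, 0.3, rng)
        d = structural_distribution(g, measure)
        assert d.probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert d.probs[-1] > 0
        assert (d.probs >= 0).all()
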