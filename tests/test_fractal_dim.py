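import math
import random

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldsrank import fractal_dim as fd
from ldsrank.graph_io import single_source_distances
from oracles import lffd_oracle, lfd_oracle, ols_slope


class TestSphereCounts:
    def test_growth_tree_counts(self, growth_tree):
        net, center = growth_tree
        prof = single_source_distances(net, center)
        assert fd.sphere_counts(prof) == [6, 11, 15, 19]

    def test_path_counts(self):
        net = nx.path_graph(["A", "B", "C"])
        assert fd.sphere_counts(single_source_distances(net, "A")) == [2, 3]

    def test_nine_cycle_counts(self):
        net = nx.cycle_graph(list(range(9)))
        assert fd.sphere_counts(single_source_distances(net, 0)) == [3, 5, 7, 9]

    def test_isolated_center_empty(self):
        assert fd.sphere_counts({"x": 0}) == []

    def test_cumulative_and_terminal(self):
        rng = random.Random(7)
        for _ in range(15):
            g = nx.gnp_random_graph(rng.randint(2, 30), 0.15,
                                    seed=rng.randint(0, 2**31 - 1))
            for v in g.nodes():
                prof = single_source_distances(g, v)
                counts = fd.sphere_counts(prof)
                assert all(b <= a for b, a in zip(counts, counts[1:]))
                if counts:
                    assert counts[-1] == len(prof)


class TestGaussianMembership:
    def test_center_is_one(self):
        assert fd.gaussian_membership(0, 3) == 1.0

    def test_boundary_value(self):
        assert fd.gaussian_membership(1, 1) == pytest.approx(math.exp(-0.5))

    def test_d_equals_r_invariance(self):
        assert fd.gaussian_membership(3, 3) == fd.gaussian_membership(1, 1)

    def test_zero_radius_rejected(self):
        with pytest.raises(ValueError):
            fd.gaussian_membership(1, 0)

    @given(d=st.integers(0, 20), r=st.integers(1, 20))
    @settings(derandomize=True)
    def test_bounded_in_unit_interval(self, d, r):
        a = fd.gaussian_membership(d, r)
        assert 0.0 < a <= 1.0
        assert (a == 1.0) == (d == 0)


class TestFuzzySphereValues:
    def test_kite_hub_printed_values(self, kite):
        prof = single_source_distances(kite, "7")
        vals = fd.fuzzy_sphere_values(prof)
        assert [round(v, 4) for v in vals] == [0.6627, 0.8627, 0.8981, 0.9059]

    def test_isolated_node_is_one(self):
        assert fd.fuzzy_sphere_value({"x": 0}, 1) == 1.0

    def test_values_in_unit_interval(self, synthetic):
        net = synthetic.network
        for v in list(net.nodes())[:25]:
            prof = single_source_distances(net, v)
            for val in fd.fuzzy_sphere_values(prof):
                assert 0.0 < val <= 1.0


class TestLogLogSlope:
    def test_sphere_count_worked_example(self):
        fit = fd.loglog_slope([(1, 6), (2, 11), (3, 15), (4, 19)])
        assert round(fit.slope, 4) == 0.8295
        assert fit.n_points == 4

    def test_exact_quadratic(self):
        fit = fd.loglog_slope([(1, 1), (2, 4), (3, 9)])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_fuzzy_worked_example(self):
        fit = fd.loglog_slope(
            [(1, 0.6627), (2, 0.8627), (3, 0.8981), (4, 0.9059)]
        )
        assert round(fit.slope, 4) == 0.2312

    def test_too_few_points_unfittable(self):
        with pytest.raises(fd.UnfittableError):
            fd.loglog_slope([(1, 5.0)])

    def test_nonpositive_y_rejected(self):
        with pytest.raises(ValueError):
            fd.loglog_slope([(1, 1.0), (2, 0.0)])

    @given(
        c=st.floats(0.1, 10),
        k=st.floats(-3, 3),
        n=st.integers(3, 12),
    )
    @settings(derandomize=True)
    def test_recovers_exact_power_law(self, c, k, n):
        pts = [(r, c * r**k) for r in range(1, n + 1)]
        fit = fd.loglog_slope(pts)
        assert fit.slope == pytest.approx(k, abs=1e-8)
        assert fit.intercept == pytest.approx(math.log(c), abs=1e-7)


class TestLfd:
    def test_growth_tree_center(self, growth_tree):
        net, center = growth_tree
        assert round(fd.lfd(net, center), 4) == 0.8295

    def test_star_center_falls_back_to_zero(self, caplog):
        net = nx.star_graph(["hub", "a", "b", "c"])
        with caplog.at_level("WARNING"):
            assert fd.lfd(net, "hub") == 0.0
        assert "unfittable" in caplog.text

    def test_large_cycle_matches_closed_form_oracle(self):
        net = nx.cycle_graph(list(range(101)))
        counts = [2 * r + 1 for r in range(1, 51)]
        expect = ols_slope(
            [math.log(r) for r in range(1, 51)], [math.log(c) for c in counts]
        )
        got = fd.lfd(net, 0)
        assert got == pytest.approx(expect, abs=1e-12)
        assert 0.85 <= got <= 1.0

    def test_unknown_node(self, kite):
        with pytest.raises(KeyError):
            fd.lfd(kite, "ghost")


class TestLffd:
    def test_kite_hub(self, kite):
        assert round(fd.lffd(kite, "7"), 4) == 0.2312

    def test_isolated_node_zero(self):
        net = nx.Graph()
        net.add_node("solo")
        assert fd.lffd(net, "solo") == 0.0

    def test_matches_independent_oracle_on_random_graphs(self):
        rng = random.Random(11)
        for _ in range(10):
            g = nx.gnp_random_graph(rng.randint(3, 25), rng.uniform(0.1, 0.5),
                                    seed=rng.randint(0, 2**31 - 1))
            nodes, edges = list(g.nodes()), list(g.edges())
            for v in nodes:
                assert fd.lffd(g, v) == pytest.approx(
                    lffd_oracle(nodes, edges, v), abs=1e-10
                )
                assert fd.lfd(g, v) == pytest.approx(
                    lfd_oracle(nodes, edges, v), abs=1e-10
                )

    def test_degenerate_components_are_exactly_zero(self):
        net = nx.Graph([("a", "b")])  # both endpoints have eccentricity 1
        net.add_node("iso")
        for v in net.nodes():
            assert fd.lfd(net, v) == 0.0
            assert fd.lffd(net, v) == 0.0


class TestBatch:
    def test_kite_batch_matches_per_node(self, kite):
        allv = fd.lffd_all(kite)
        assert len(allv) == 10
        assert round(allv["7"], 4) == 0.2312
        assert allv == {v: fd.lffd(kite, v) for v in kite.nodes()}

    def test_empty_network(self):
        assert fd.lffd_all(nx.Graph()) == {}
        assert fd.lfd_all(nx.Graph()) == {}

    def test_random_graph_batch_equivalence(self):
        g = nx.gnp_random_graph(50, 0.1, seed=3)
        assert fd.lffd_all(g) == {v: fd.lffd(g, v) for v in g.nodes()}
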