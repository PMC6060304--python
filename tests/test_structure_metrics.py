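"""Components, targeted removal, rewiring nulls and rich-club curves."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

import threadnet as tn
from threadnet.errors import ConfigError, EmptyInputError
from threadnet.network_build import UndirectedView
from threadnet.structure_metrics import _rich_club_curve_raw


def view_of(edges, nodes=()) -> UndirectedView:
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges, weight=1)
    return UndirectedView(graph=g)


def bfs_components(g: nx.Graph) -> set[frozenset]:
    """Independent oracle: plain breadth-first reachability."""
    seen, comps = set(), set()
    for start in g.nodes:
        if start in seen:
            continue
        frontier, comp = [start], {start}
        while frontier:
            nxt = []
            for u in frontier:
                for v in g.neighbors(u):
                    if v not in comp:
                        comp.add(v)
                        nxt.append(v)
            frontier = nxt
        seen |= comp
        comps.add(frozenset(comp))
    return comps


class TestComponents:
    def test_toy(self, toy_log):
        view = tn.undirected_projection(tn.build_reply_network(toy_log))
        part = tn.connected_components(view)
        assert part.components == [frozenset({"A", "B", "C"})]

    def test_registry_singletons(self, toy_log):
        view = tn.undirected_projection(tn.build_reply_network(toy_log))
        part = tn.connected_components(view, registry_nodes={"A", "B", "C", "D"})
        assert part.largest_size == 3
        assert frozenset({"D"}) in part.components

    def test_path_graph(self):
        part = tn.connected_components(view_of(nx.path_graph(10).edges))
        assert part.sizes == [10]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bfs_oracle(self, seed):
        g = nx.gnp_random_graph(40, 0.06, seed=seed)
        part = tn.connected_components(UndirectedView(graph=g))
        assert set(part.components) == bfs_components(g)


class TestLargestComponentSeries:
    def test_toy_week_zero_is_one(self, toy_log):
        series = tn.largest_component_fraction_series(
            toy_log, tn.weekly_cumulative_networks(toy_log))
        assert series["largest_component_fraction"].iloc[0] == pytest.approx(1.0)

    def test_disjoint_dyads_half(self):
        import pandas as pd
        from threadnet.model import Post, PostLog

        ts = pd.Timestamp("2020-01-01T00:00:00+00:00")
        posts = [
            Post("p1", "t1", None, "A", ts, 1),
            Post("p2", "t1", "p1", "B", ts + pd.Timedelta(days=1), 2),
            Post("p3", "t2", None, "C", ts + pd.Timedelta(days=2), 1),
            Post("p4", "t2", "p3", "D", ts + pd.Timedelta(days=3), 2),
        ]
        log = PostLog(posts=posts)
        series = tn.largest_component_fraction_series(
            log, tn.weekly_cumulative_networks(log))
        assert series["largest_component_fraction"].iloc[-1] == pytest.approx(0.5)

    def test_blf_reaches_qualitative_band(self, blf_log):
        """A connected majority emerges: the mature community keeps
        60-100% of posting users in the largest component."""
        series = tn.largest_component_fraction_series(
            blf_log, tn.weekly_cumulative_networks(blf_log))
        tail = series["largest_component_fraction"].iloc[len(series) // 2:]
        assert ((tail >= 0.6) & (tail <= 1.0)).all()


class TestRemoval:
    def test_toy_one_third(self, toy_log):
        view = tn.undirected_projection(tn.build_reply_network(toy_log))
        curve = tn.targeted_removal_curve(view, [0.0, 1 / 3])
        assert curve.values[0] == pytest.approx(1.0)
        assert curve.values[1] == pytest.approx(1 / 3)

    def test_star_hub_removal(self):
        curve = tn.targeted_removal_curve(view_of(nx.star_graph(9).edges), [0.1])
        assert curve.values[0] == pytest.approx(1 / 10)

    def test_monotone_nonincreasing(self, blf_view):
        fr = list(np.linspace(0, 0.3, 16))
        curve = tn.targeted_removal_curve(blf_view, fr)
        assert (np.diff(curve.values) <= 1e-12).all()

    def test_empty_raises(self):
        with pytest.raises(EmptyInputError):
            tn.targeted_removal_curve(view_of([]), [0.0])


class TestRichClubRaw:
    def test_hand_example(self):
        view = view_of([(1, 2), (1, 3), (1, 4), (2, 3)])
        # degrees 3,2,2,1 -> S(k=2) = {1,2,3}, all 3 possible edges present
        assert tn.rich_club_raw(view, 2) == pytest.approx(1.0)

    def test_complete_graph(self):
        view = view_of(nx.complete_graph(5).edges)
        for k in range(5):
            assert tn.rich_club_raw(view, k) == pytest.approx(1.0)

    def test_star_undefined(self):
        assert tn.rich_club_raw(view_of(nx.star_graph(4).edges), 2) is None

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_networkx_shifted_threshold(self, seed):
        """Our >= k convention equals networkx's > k at threshold k+1."""
        g = nx.gnp_random_graph(50, 0.12, seed=seed)
        g.remove_nodes_from(list(nx.isolates(g)))
        view = UndirectedView(graph=g)
        reference = nx.rich_club_coefficient(g, normalized=False)
        for k, phi in reference.items():
            ours = tn.rich_club_raw(view, k + 1)
            if ours is not None:
                assert ours == pytest.approx(phi)

    def test_vectorized_curve_matches_scalar(self, blf_view):
        ks = tn.default_k_grid(blf_view)
        curve = _rich_club_curve_raw(blf_view, ks)
        for k, r in zip(ks, curve):
            scalar = tn.rich_club_raw(blf_view, int(k))
            if scalar is None:
                assert np.isnan(r)
            else:
                assert r == pytest.approx(scalar)


class TestRewiring:
    def test_degree_sequence_preserved(self):
        g = nx.barabasi_albert_graph(100, 3, seed=1)
        view = UndirectedView(graph=g)
        null = tn.degree_preserving_rewire(view, 10 * g.number_of_edges(), seed=4)
        assert sorted(d for _, d in null.graph.degree()) == sorted(
            d for _, d in g.degree())

    def test_triangle_is_rigid(self):
        view = view_of(nx.complete_graph(3).edges)
        null = tn.degree_preserving_rewire(view, 100, seed=0)
        assert set(map(frozenset, null.graph.edges)) == set(
            map(frozenset, view.graph.edges))

    def test_seeds_give_different_edge_sets_same_degrees(self):
        g = nx.barabasi_albert_graph(100, 3, seed=2)
        view = UndirectedView(graph=g)
        a = tn.degree_preserving_rewire(view, 10 * g.number_of_edges(), seed=1)
        b = tn.degree_preserving_rewire(view, 10 * g.number_of_edges(), seed=2)
        assert set(a.graph.edges) != set(b.graph.edges)
        assert sorted(d for _, d in a.graph.degree()) == sorted(
            d for _, d in b.graph.degree())

    def test_deterministic_given_seed(self):
        g = nx.gnp_random_graph(40, 0.1, seed=3)
        view = UndirectedView(graph=g)
        a = tn.degree_preserving_rewire(view, 500, seed=9)
        b = tn.degree_preserving_rewire(view, 500, seed=9)
        assert set(a.graph.edges) == set(b.graph.edges)

    def test_too_few_edges(self):
        with pytest.raises(ConfigError):
            tn.degree_preserving_rewire(view_of([(1, 2)]), 10, seed=0)


class TestNormalizedCurve:
    def test_planted_rich_club_above_one(self):
        """Four high-degree nodes forming a clique atop a sparse periphery."""
        g = nx.Graph()
        hubs = [0, 1, 2, 3]
        g.add_edges_from((a, b) for i, a in enumerate(hubs) for b in hubs[i + 1:])
        leaf = 4
        for h in hubs:  # give each hub a handful of pendant neighbours
            for _ in range(5):
                g.add_edge(h, leaf)
                leaf += 1
        # sparse periphery chain so the graph is not just a star union
        g.add_edges_from((leaf + i, leaf + i + 1) for i in range(10))
        curve = tn.normalized_rich_club_curve(
            UndirectedView(graph=g), k_values=[2, 8], n_nulls=20, seed=5)
        rho_high = curve.normalized[list(curve.k_values).index(8)]
        assert rho_high > 1.0

    def test_erdos_renyi_concentrates_near_one(self):
        g = nx.gnp_random_graph(300, 0.03, seed=7)
        g.remove_nodes_from(list(nx.isolates(g)))
        view = UndirectedView(graph=g)
        curve = tn.normalized_rich_club_curve(view, n_nulls=20, seed=8)
        ok = curve.defined
        dev = np.abs(curve.normalized[ok] - 1.0)
        assert (dev <= 3.0 * curve.null_std[ok] / curve.null_mean[ok] + 1e-9).all()

    def test_undefined_propagates(self):
        view = view_of(nx.star_graph(4).edges)
        curve = tn.normalized_rich_club_curve(view, k_values=[1, 2], n_nulls=3, seed=0)
        assert curve.defined[0] and not curve.defined[1]
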