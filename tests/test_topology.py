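"""Topology panel, Louvain communities, G(n, m) nulls, display filter."""

import itertools

import networkx as nx
import numpy as np
import pytest

import tsen
from tsen.glv import InteractionNetwork


def _wrap(g: nx.DiGraph) -> InteractionNetwork:
    return InteractionNetwork(g, kind="consensus", rank="family")


def _complete_digraph(n: int) -> nx.DiGraph:
    g = nx.DiGraph()
    for i, j in itertools.permutations(range(n), 2):
        g.add_edge(i, j, weight=1.0, sign=1)
    return g


class TestTopologyMetrics:
    def test_complete_digraph(self):
        rep = tsen.topology_metrics(_complete_digraph(3))
        assert rep.density == 1.0
        assert rep.diameter == 1
        assert not rep.disconnected

    def test_edgeless_graph_flagged(self):
        g = nx.empty_graph(10, create_using=nx.DiGraph)
        rep = tsen.topology_metrics(g)
        assert rep.density == 0.0
        assert rep.disconnected

    def test_diameter_radius_match_bfs_oracle(self, rng):
        g = nx.gnm_random_graph(50, 120, seed=4, directed=True)
        rep = tsen.topology_metrics(g)
        # independent oracle: BFS all-pairs on the undirected projection
        und = {i: set() for i in g.nodes}
        for u, v in g.edges:
            und[u].add(v)
            und[v].add(u)

        def bfs(src):
            dist = {src: 0}
            frontier = [src]
            while frontier:
                nxt = []
                for n in frontier:
                    for m in und[n]:
                        if m not in dist:
                            dist[m] = dist[n] + 1
                            nxt.append(m)
                frontier = nxt
            return dist

        comps = list(nx.connected_components(nx.Graph(g.to_undirected())))
        comp = max(comps, key=len)
        eccs = [max(bfs(s)[t] for t in comp if t in bfs(s)) for s in comp]
        assert rep.diameter == max(eccs)
        assert rep.radius == min(eccs)
        assert rep.radius <= rep.diameter

    def test_mean_degree(self):
        g = _complete_digraph(4)  # each node: in 3 + out 3
        rep = tsen.topology_metrics(g)
        assert rep.mean_degree == pytest.approx(6.0)

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            tsen.topology_metrics(nx.empty_graph(1, create_using=nx.DiGraph))


def _all_partitions(nodes):
    nodes = list(nodes)
    if not nodes:
        yield []
        return
    first = nodes[0]
    for rest in _all_partitions(nodes[1:]):
        for i in range(len(rest)):
            yield rest[:i] + [rest[i] | {first}] + rest[i + 1:]
        yield rest + [{first}]


def _exhaustive_q(g: nx.Graph) -> float:
    return max(
        nx.community.modularity(g, p) for p in _all_partitions(g.nodes) if p
    )


FIXTURES = {
    "two_triangles": nx.disjoint_union(nx.cycle_graph(3), nx.cycle_graph(3)),
    "barbell": nx.barbell_graph(3, 1),
    "star6": nx.star_graph(5),
    "cycle6": nx.cycle_graph(6),
    "complete5": nx.complete_graph(5),
    "path7": nx.path_graph(7),
    "lollipop7": nx.lollipop_graph(4, 3),
    "two_squares": nx.disjoint_union(nx.cycle_graph(4), nx.cycle_graph(4)),
    "cube8": nx.convert_node_labels_to_integers(nx.hypercube_graph(3)),
}


class TestCommunitiesModularity:
    def test_two_disconnected_triangles(self):
        g = nx.DiGraph(FIXTURES["two_triangles"].to_directed())
        parts, q = tsen.communities_modularity(g)
        assert len(parts) == 2
        assert q == pytest.approx(0.5)

    def test_complete_graph_single_community(self):
        g = nx.DiGraph(FIXTURES["complete5"].to_directed())
        parts, q = tsen.communities_modularity(g)
        assert len(parts) == 1
        assert q == pytest.approx(0.0)

    @pytest.mark.parametrize("name", sorted(FIXTURES))
    def test_matches_exhaustive_partition_optimum(self, name):
        und = FIXTURES[name]
        g = nx.DiGraph(und.to_directed())
        _, q = tsen.communities_modularity(g)
        assert q == pytest.approx(_exhaustive_q(und), abs=1e-12)

    def test_dense_digraph_near_zero_modularity(self):
        g = nx.gnm_random_graph(80, int(0.9 * 80 * 79), seed=0, directed=True)
        _, q = tsen.communities_modularity(g)
        assert q < 0.05

    def test_reproducible(self):
        g = nx.gnm_random_graph(30, 60, seed=1, directed=True)
        assert (tsen.communities_modularity(g)[1]
                == tsen.communities_modularity(g)[1])


class TestFindHubs:
    def test_in_star_center(self):
        g = nx.DiGraph((f"leaf{i}", "center") for i in range(4))
        hubs_in, hubs_out, max_in, max_out = tsen.find_hubs(g)
        assert hubs_in == ["center"] and max_in == 4
        assert len(hubs_out) == 4 and max_out == 1

    def test_tied_out_hubs_both_returned(self):
        g = nx.DiGraph([("a", "x"), ("a", "y"), ("b", "x"), ("b", "z")])
        _, hubs_out, _, max_out = tsen.find_hubs(g)
        assert hubs_out == ["a", "b"] and max_out == 2

    def test_dominant_affecting_node(self):
        # one node affecting 345 others, the structural hub pattern
        g = nx.DiGraph(("hub", f"n{i}") for i in range(345))
        g.add_edge("n0", "n1")
        _, hubs_out, _, max_out = tsen.find_hubs(g)
        assert hubs_out == ["hub"] and max_out == 345


class TestRandomEnsemble:
    def test_complete_case_density_forced(self):
        ens = tsen.random_ensemble(10, 90, reps=5, seed=0)
        assert (ens.values["density"] == 1.0).all()

    def test_density_closed_form(self):
        ens = tsen.random_ensemble(100, 500, reps=20, seed=1)
        assert (ens.values["density"] == 500 / 9900).all()

    def test_mean_degree_conserved_every_replicate(self):
        ens = tsen.random_ensemble(40, 200, reps=10, seed=2)
        assert (ens.values["mean_degree"] == 2 * 200 / 40).all()

    def test_overfull_rejected(self):
        with pytest.raises(ValueError):
            tsen.random_ensemble(5, 21)

    def test_null_self_consistency(self):
        # a network drawn from G(n, m) should sit inside its own ensemble
        for seed in range(10):
            g = nx.gnm_random_graph(40, 300, seed=seed, directed=True)
            rep = tsen.compare_to_null(g, reps=30, seed=seed)
            for metric in ("density", "clustering", "mean_degree",
                           "modularity"):
                real = rep.metric(metric)
                mu = rep.random_mean[metric]
                sd = rep.random_std[metric]
                assert abs(real - mu) <= max(3 * sd, 1e-9), metric


class TestTopFractionEdges:
    def _net(self, m, seed=0):
        rng = np.random.default_rng(seed)
        g = nx.DiGraph()
        k = int(np.ceil((1 + np.sqrt(1 + 4 * m)) / 2)) + 1
        pairs = [(i, j) for i in range(k) for j in range(k) if i != j][:m]
        for (i, j), w in zip(pairs, rng.normal(size=m)):
            g.add_edge(f"n{i}", f"n{j}", weight=float(w), sign=int(np.sign(w)))
        return InteractionNetwork(g, kind="consensus", rank="family")

    def test_ten_percent_of_thousand(self):
        net = self._net(1000)
        assert tsen.top_fraction_edges(net, 0.1).n_edges == 100

    def test_keeps_largest_absolute_weights(self):
        g = nx.DiGraph()
        for k, w in enumerate([0.1, -5.0, 2.0, -0.2]):
            g.add_edge(f"u{k}", f"v{k}", weight=w, sign=int(np.sign(w)))
        net = InteractionNetwork(g, kind="consensus", rank="family")
        kept = tsen.top_fraction_edges(net, 0.5)
        weights = {d["weight"] for _, _, d in kept.graph.edges(data=True)}
        assert weights == {-5.0, 2.0}

    def test_empty_result_warns(self):
        net = self._net(10)
        with pytest.warns(UserWarning):
            out = tsen.top_fraction_edges(net, 0.01)
        assert out.n_edges == 0

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            tsen.top_fraction_edges(self._net(10), 0.0)
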