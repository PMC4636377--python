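"""Probabilistic network conversion, k-best paths, sub-network selection."""

import itertools

import networkx as nx
import numpy as np
import pytest

from evotrace.network import (annotate_overlap, k_best_paths, probabilize,
                              read_sif, select_subnetwork, write_sif)


def digraph(edges, probs=None):
    g = nx.DiGraph()
    for i, (u, v) in enumerate(edges):
        g.add_edge(u, v, type="protein-DNA",
                   probability=None if probs is None else probs[i])
    return g


class TestProbabilize:
    def test_uniform_out_degree_single_probability(self):
        g = digraph([("a", "b"), ("b", "c"), ("c", "a")])
        pg = probabilize(g)
        probs = {d["probability"] for _, _, d in pg.edges(data=True)}
        assert len(probs) == 1

    def test_rank_extremes_and_monotonicity(self):
        g = nx.DiGraph()
        g.add_edge("x", "low", type="protein-DNA")   # low: out-degree 1
        g.add_edge("low", "x", type="protein-DNA")
        g.add_edge("y", "hub", type="protein-DNA")   # hub: unique max degree
        for i in range(10):
            g.add_edge("hub", f"t{i}", type="protein-DNA")
        pg = probabilize(g, p_min=0.1, p_max=0.9)
        # the edge into the unique highest-out-degree terminal gets p_min
        assert pg.edges["y", "hub"]["probability"] == pytest.approx(0.1)
        # probability is non-increasing in terminal out-degree (rank sense)
        pairs = sorted((pg.out_degree(v), d["probability"])
                       for _, v, d in pg.edges(data=True))
        for (d1, p1), (d2, p2) in zip(pairs[:-1], pairs[1:]):
            if d1 < d2:
                assert p1 >= p2

    def test_star_graph_matches_explicit_rank_computation(self):
        g = nx.DiGraph()
        leaves = [f"l{i}" for i in range(4)]
        for leaf in leaves:
            g.add_edge("hub", leaf, type="protein-DNA")
            g.add_edge(leaf, "hub", type="protein-DNA")
        pg = probabilize(g, p_min=0.1, p_max=0.9)
        # terminal out-degrees: leaves have 1 (x4 edges), hub has 4 (x4 edges)
        # average percentile rank of the leaf group: ranks 1..4 -> mean 2.5
        # -> pct (2.5-1)/7; hub group: ranks 5..8 -> mean 6.5 -> pct (6.5-1)/7
        p_leaf = 0.1 + 0.8 * (1 - 1.5 / 7)
        p_hub = 0.1 + 0.8 * (1 - 5.5 / 7)
        for u, v, d in pg.edges(data=True):
            expected = p_leaf if v != "hub" else p_hub
            assert d["probability"] == pytest.approx(expected)
        assert p_hub < p_leaf  # edges into the hub are strictly cheaper

    def test_topology_preserved_and_empty_rejected(self):
        g = digraph([("a", "b")])
        pg = probabilize(g)
        assert set(pg.edges) == set(g.edges)
        with pytest.raises(ValueError):
            probabilize(nx.DiGraph())


def brute_force_paths(pg, source, target, k, max_len, cutoff):
    """Oracle: enumerate every simple path of <= max_len edges, keep those
    with probability >= cutoff, sort by (-prob, path), truncate to k."""
    out = []
    for path in nx.all_simple_paths(pg, source, target, cutoff=max_len):
        prob = 1.0
        for u, v in zip(path[:-1], path[1:]):
            prob *= pg.edges[u, v]["probability"]
        if prob >= cutoff:
            out.append((tuple(path), prob))
    out.sort(key=lambda x: (-x[1], x[0]))
    return out[:k]


class TestKBestPaths:
    def test_product_arithmetic(self):
        pg = digraph([("A", "B"), ("A", "C"), ("C", "B")], [0.9, 0.5, 0.8])
        paths = k_best_paths(pg, "A", "B", k=10, cutoff=0.0)
        assert paths[0] == (("A", "B"), pytest.approx(0.9))
        assert paths[1] == (("A", "C", "B"), pytest.approx(0.4))

    def test_k1_equals_dijkstra_on_neglog(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(10, 0.4, seed=3, directed=True)
        pg = nx.DiGraph()
        for u, v in g.edges:
            pg.add_edge(str(u), str(v), probability=float(rng.uniform(0.2, 1)))
        for u, v, d in pg.edges(data=True):
            d["weight"] = -np.log(d["probability"])
        best = k_best_paths(pg, "0", "1", k=1, max_len=100, cutoff=0.0)
        dij = nx.shortest_path(pg, "0", "1", weight="weight")
        assert best and list(best[0][0]) == dij

    def test_no_path_returns_empty(self):
        pg = digraph([("A", "B")], [0.9])
        assert k_best_paths(pg, "B", "A") == []

    def test_missing_node_and_self_pair_rejected(self):
        pg = digraph([("A", "B")], [0.9])
        with pytest.raises(KeyError):
            k_best_paths(pg, "A", "Z")
        with pytest.raises(ValueError):
            k_best_paths(pg, "A", "A")

    def test_matches_brute_force_on_random_graphs(self):
        """100 seeded random 8-node graphs: best-first search equals
        exhaustive simple-path enumeration (k=5, max_len=4, cutoff 0.01)."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            g = nx.gnp_random_graph(8, 0.35, seed=seed, directed=True)
            pg = nx.DiGraph()
            for u, v in g.edges:
                pg.add_edge(str(u), str(v),
                            probability=float(rng.uniform(0.05, 0.95)))
            if "0" not in pg or "7" not in pg:
                continue
            got = k_best_paths(pg, "0", "7", k=5, max_len=4, cutoff=0.01)
            want = brute_force_paths(pg, "0", "7", 5, 4, 0.01)
            assert [p for p, _ in got] == [p for p, _ in want], seed
            assert np.allclose([pr for _, pr in got], [pr for _, pr in want])

    def test_probabilities_non_increasing_and_paths_simple(self):
        rng = np.random.default_rng(9)
        g = nx.gnp_random_graph(12, 0.3, seed=9, directed=True)
        pg = nx.DiGraph()
        for u, v in g.edges:
            pg.add_edge(str(u), str(v), probability=float(rng.uniform(0.1, 1)))
        if "0" in pg and "5" in pg:
            paths = k_best_paths(pg, "0", "5", k=50, max_len=4, cutoff=0.0)
            probs = [p for _, p in paths]
            assert probs == sorted(probs, reverse=True)
            for path, _ in paths:
                assert len(set(path)) == len(path) <= 5


class TestSelectSubnetwork:
    def test_single_qualifying_edge_selected(self):
        pg = digraph([("A", "B")], [0.9])
        sub = select_subnetwork(pg, ["A", "B"], cost=0.5)
        assert set(sub.graph.edges) == {("A", "B")}
        assert sub.unconnected == []

    def test_single_edge_below_cost_not_selected(self):
        pg = digraph([("A", "B")], [0.4])
        sub = select_subnetwork(pg, ["A", "B"], cost=0.5)
        assert sub.graph.number_of_edges() == 0
        assert "A" in sub.unconnected and "B" in sub.unconnected

    def test_infinite_cost_empty(self):
        pg = digraph([("A", "B"), ("B", "C")], [0.9, 0.9])
        sub = select_subnetwork(pg, ["A", "C"], cost=float("inf"))
        assert sub.graph.number_of_edges() == 0

    def test_missing_genes_error(self):
        pg = digraph([("A", "B")], [0.9])
        with pytest.raises(ValueError, match="X"):
            select_subnetwork(pg, ["X", "Y"], cost=0.1)

    def test_hub_avoidance(self):
        """Two equal-length routes between mutated genes: the one through
        low-degree intermediaries wins after probabilization."""
        g = nx.DiGraph()
        g.add_edge("M1", "quiet", type="protein-DNA")
        g.add_edge("quiet", "M2", type="protein-DNA")
        g.add_edge("M1", "hub", type="protein-DNA")
        g.add_edge("hub", "M2", type="protein-DNA")
        for i in range(12):
            g.add_edge("hub", f"x{i}", type="protein-DNA")
        pg = probabilize(g)
        sub = select_subnetwork(pg, ["M1", "M2"], cost=0.02, k=1)
        assert "quiet" in sub.graph.nodes
        assert "hub" not in sub.graph.nodes

    def test_matches_exhaustive_optimum_on_disjoint_path_families(self):
        """With edge-disjoint candidate paths the objective
        sum(p_i) - cost*|edges| separates per path, so greedy equals the
        exhaustive optimum over all candidate subsets (20 seeded toys)."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pg = nx.DiGraph()
            n_routes = 4
            lens = rng.integers(1, 4, n_routes)
            for r in range(n_routes):
                nodes = ["S"] + [f"r{r}n{j}" for j in range(lens[r] - 1)] + ["T"]
                for u, v in zip(nodes[:-1], nodes[1:]):
                    pg.add_edge(u, v, probability=float(rng.uniform(0.05, 0.95)))
            cost = 0.1
            sub = select_subnetwork(pg, ["S", "T"], cost=cost, k=100,
                                    cutoff=0.0)
            candidates = brute_force_paths(pg, "S", "T", 100, 4, 0.0)
            best_obj, best_edges = 0.0, set()
            for mask in itertools.product([0, 1], repeat=len(candidates)):
                chosen = [c for c, m in zip(candidates, mask) if m]
                edges = {e for path, _ in chosen
                         for e in zip(path[:-1], path[1:])}
                obj = sum(pr for _, pr in chosen) - cost * len(edges)
                if obj > best_obj:
                    best_obj, best_edges = obj, edges
            assert set(sub.graph.edges) == best_edges, seed

    def test_monotone_in_cost(self):
        rng = np.random.default_rng(17)
        g = nx.gnp_random_graph(10, 0.35, seed=17, directed=True)
        pg = nx.DiGraph()
        for u, v in g.edges:
            pg.add_edge(str(u), str(v), probability=float(rng.uniform(0.2, 1)))
        genes = [n for n in ("0", "3", "7") if n in pg]
        subs = {}
        for cost in (0.05, 0.25, 0.6):
            subs[cost] = set(select_subnetwork(pg, genes, cost=cost,
                                               cutoff=0.0).graph.edges)
        assert subs[0.6] <= subs[0.25] <= subs[0.05]


class TestOverlapAndIO:
    def test_reference_all_and_disjoint(self):
        pg = digraph([("A", "B"), ("B", "C")], [0.9, 0.9])
        sub = select_subnetwork(pg, ["A", "B"], cost=0.1)
        full = pg
        both = annotate_overlap(sub, full, {"A", "B", "C"})
        assert both["inside_fraction"] == 1.0
        none = annotate_overlap(sub, full, {"Z"})
        assert none["inside_fraction"] == 0.0 and none["outside_fraction"] == 0.0

    def test_counting(self):
        pg = digraph([("A", "B"), ("B", "C")], [0.9, 0.9])
        sub = select_subnetwork(pg, ["A", "B"], cost=0.1)
        out = annotate_overlap(sub, pg, {"A", "C"})
        assert out["inside_fraction"] == pytest.approx(
            len({"A"} & set(sub.graph.nodes)) / len(sub.graph.nodes))

    def test_sif_roundtrip(self, tmp_path):
        path = tmp_path / "net.sif"
        path.write_text("A\tprotein-protein\tB\nB\tmetabolic\tC\n"
                        "C\tprotein-DNA\tA\n")
        g = read_sif(str(path))
        assert g.has_edge("A", "B") and g.has_edge("B", "A")  # pp expands
        assert g.has_edge("B", "C") and not g.has_edge("C", "B")
        out = tmp_path / "out.sif"
        write_sif(g, str(out))
        g2 = read_sif(str(out))
        assert set(g2.edges) == set(g.edges)

    def test_edge_list_column_order(self, tmp_path):
        path = tmp_path / "net.tsv"
        path.write_text("A\tB\tmetabolic\n")
        g = read_sif(str(path))
        assert g.has_edge("A", "B")
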