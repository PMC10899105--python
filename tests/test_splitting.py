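"""Neighbor subgraphs, normalized cuts, and node splitting."""

import itertools

import numpy as np
import pytest

from minipath import (BipartiteGraph, evaluate_all_nodes, evaluate_node,
                      neighbor_graph, ncut_value, split_nodes)
from minipath.splitting import NeighborGraph

from conftest import random_bipartite


def brute_force_w_i2(g: BipartiteGraph, a: str) -> dict:
    """Independent quadruple-loop oracle for the two-step neighbor weights."""
    if a in g.u_index:
        s_a = g.neighbors(a)
        others = [u for u in g.u_ids if u != a]
        pairs = {}
        for x, y in itertools.combinations(sorted(s_a), 2):
            total = sum(g.weight(b, x) * g.weight(b, y) for b in others)
            pairs[(x, y)] = total
        return pairs
    raise NotImplementedError


class TestNeighborGraph:
    def test_star_has_no_edges(self):
        g = BipartiteGraph.from_edges([("a", f"v{i}", 1) for i in range(4)])
        ng = neighbor_graph(g, "a")
        assert ng.size == 4 and ng.w.sum() == 0

    def test_single_two_step_path(self):
        g = BipartiteGraph.from_edges([
            ("a", "v1", 1), ("a", "v2", 1), ("b", "v1", 1), ("b", "v2", 1)])
        ng = neighbor_graph(g, "a")
        i, j = ng.nodes.index("v1"), ng.nodes.index("v2")
        assert ng.w[i, j] == 1          # one path via b

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        g = random_bipartite(rng, 6, 7, density=0.5, max_w=4)
        center = g.u_ids[0]
        ng = neighbor_graph(g, center)
        oracle = brute_force_w_i2(g, center)
        for (x, y), val in oracle.items():
            i, j = ng.nodes.index(x), ng.nodes.index(y)
            assert ng.w[i, j] == val == ng.w[j, i]

    def test_isolated_node_empty(self):
        g = BipartiteGraph(["a", "b"], ["v1"],
                           np.array([[0], [1]]))
        assert neighbor_graph(g, "a").size == 0


def exhaustive_min_ncut(w: np.ndarray) -> float:
    """Independent exhaustive search over all bipartitions (test oracle)."""
    n = w.shape[0]
    d = w.sum(axis=1)
    best = np.inf
    for r in range(1, n // 2 + 1):
        for combo in itertools.combinations(range(n), r):
            m1 = np.zeros(n, dtype=bool)
            m1[list(combo)] = True
            cut = w[np.ix_(m1, ~m1)].sum()
            if cut == 0:
                val = 0.0
            else:
                val = cut / d[m1].sum() + cut / d[~m1].sum()
            best = min(best, val)
    return best


class TestEvaluateNode:
    def test_two_components_ncut_zero(self):
        w = np.zeros((6, 6))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 2.0
        w[3, 4] = w[4, 3] = w[4, 5] = w[5, 4] = 3.0
        ng = NeighborGraph("c", [f"n{i}" for i in range(6)], w)
        cut = evaluate_node(ng)
        assert cut.status == "evaluated" and cut.ncut == 0.0
        assert sorted(map(sorted, (cut.part1, cut.part2))) == [
            ["n0", "n1", "n2"], ["n3", "n4", "n5"]]

    def test_too_few_neighbors(self):
        ng = NeighborGraph("c", ["n0", "n1", "n2"], np.ones((3, 3)))
        assert evaluate_node(ng).status == "too_few_neighbors"

    def test_three_components_unevaluable(self):
        w = np.zeros((6, 6))
        for i in (0, 2, 4):
            w[i, i + 1] = w[i + 1, i] = 1.0
        ng = NeighborGraph("c", [f"n{i}" for i in range(6)], w)
        assert evaluate_node(ng).status == "unevaluable_components"

    def test_worked_example_two_over_21(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 10.0
        w[2, 3] = w[3, 2] = 10.0
        w[1, 2] = w[2, 1] = 1.0
        ng = NeighborGraph("c", list("pqrs"), w)
        cut = evaluate_node(ng)
        assert cut.ncut == pytest.approx(2 / 21)
        assert sorted(map(sorted, (cut.part1, cut.part2))) == [
            ["p", "q"], ["r", "s"]]

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_matches_independent_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 10))
        w = rng.integers(0, 4, size=(n, n)).astype(float)
        w = w + w.T
        np.fill_diagonal(w, 0.0)
        ng = NeighborGraph("c", [f"n{i}" for i in range(n)], w)
        cut = evaluate_node(ng)
        if cut.status != "evaluated":
            return
        assert cut.ncut == pytest.approx(exhaustive_min_ncut(w), abs=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_spectral_never_beats_exact_and_usually_matches(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 10
        w = (rng.random((n, n)) < 0.6) * rng.integers(1, 5, (n, n)).astype(float)
        w = w + w.T
        np.fill_diagonal(w, 0.0)
        ng = NeighborGraph("c", [f"n{i}" for i in range(n)], w)
        exact = evaluate_node(ng, exact_max=n)
        spectral = evaluate_node(ng, exact_max=0)
        if exact.status != "evaluated":
            return
        assert spectral.ncut >= exact.ncut - 1e-12

    def test_ncut_range(self):
        rng = np.random.default_rng(55)
        for _ in range(20):
            n = int(rng.integers(2, 8))
            w = rng.random((n, n)) * (rng.random((n, n)) < 0.7)
            w = w + w.T
            np.fill_diagonal(w, 0.0)
            mask = np.zeros(n, dtype=bool)
            mask[: int(rng.integers(1, n))] = True
            if mask.all() or w.sum() == 0:
                continue
            assert 0.0 <= ncut_value(w, mask) <= 2.0


class TestEvaluateAllNodes:
    @pytest.mark.parametrize("seed", range(3))
    def test_matches_single_node_route(self, seed):
        rng = np.random.default_rng(seed)
        g = random_bipartite(rng, 8, 8, density=0.5, max_w=3)
        bulk = evaluate_all_nodes(g)
        for node in g.nodes():
            single = evaluate_node(neighbor_graph(g, node))
            assert bulk[node].status == single.status
            if single.status == "evaluated":
                assert bulk[node].ncut == pytest.approx(single.ncut)


class TestSplitNodes:
    def _fused_fixture(self):
        # two well-separated cliques joined through one fused-like center
        edges = []
        for i in range(3):
            for j in range(3):
                edges.append((f"L{i}", f"lv{j}", 5))
                edges.append((f"R{i}", f"rv{j}", 5))
        edges += [("F", f"lv{j}", 4) for j in range(3)]
        edges += [("F", f"rv{j}", 4) for j in range(3)]
        return BipartiteGraph.from_edges(edges)

    def test_low_ncut_node_is_split(self):
        g = self._fused_fixture()
        cuts = evaluate_all_nodes(g)
        assert cuts["F"].status == "evaluated"
        assert cuts["F"].ncut < 0.1
        out, split_map = split_nodes(g, cuts, 0.1)
        assert "F" in split_map
        assert out.n_nodes == g.n_nodes + 1
        entry = split_map["F"]
        for v in entry["part1"]:
            assert out.weight(entry["new_1"], v) == g.weight("F", v)
            assert out.weight(entry["new_2"], v) == 0

    def test_cutoff_zero_never_splits(self):
        g = self._fused_fixture()
        cuts = evaluate_all_nodes(g)
        out, split_map = split_nodes(g, cuts, 0.0)
        assert not split_map and out == g

    def test_negative_cutoff_rejected(self):
        g = self._fused_fixture()
        with pytest.raises(ValueError):
            split_nodes(g, evaluate_all_nodes(g), -0.1)

    def test_weight_conserved_except_both_split_edges(self):
        rng = np.random.default_rng(77)
        g = random_bipartite(rng, 10, 10, density=0.4, max_w=4)
        cuts = evaluate_all_nodes(g)
        cutoff = 0.8                      # aggressive: force both-split edges
        out, split_map = split_nodes(g, cuts, cutoff)
        split = set(split_map)
        lost = sum(w for u, v, w in g.edges() if u in split and v in split)
        assert out.total_weight == g.total_weight - lost

    def test_both_split_neighbors_lose_shared_edge(self):
        # force-split two adjacent nodes via a permissive cutoff
        rng = np.random.default_rng(78)
        for seed in range(20):
            g = random_bipartite(np.random.default_rng(seed), 8, 8,
                                 density=0.6, max_w=3)
            cuts = evaluate_all_nodes(g)
            out, split_map = split_nodes(g, cuts, 1.5)
            adjacent = [(u, v) for u, v, _ in g.edges()
                        if u in split_map and v in split_map]
            if adjacent:
                u, v = adjacent[0]
                for nu in (f"{u}.1", f"{u}.2"):
                    for nv in (f"{v}.1", f"{v}.2"):
                        assert out.weight(nu, nv) == 0
                return
        pytest.skip("no adjacent split pair found")
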