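"""Simulator calibration and error-injector bookkeeping."""

import numpy as np
import pytest
from scipy import stats

from minipath import (SimParams, SimScene, inject_fused_nodes,
                      inject_reactivity_bias, inject_spurious_crosslinks,
                      place_nodes, simulate_graph)
from minipath.simulate import replicate_edge_weights


class TestPlaceNodes:
    def test_bounds_and_determinism(self):
        s1 = place_nodes((200, 450), 4000, 0.5, seed=3)
        s2 = place_nodes((200, 450), 4000, 0.5, seed=3)
        assert (s1.xy >= 0).all()
        assert (s1.xy[:, 0] <= 200).all() and (s1.xy[:, 1] <= 450).all()
        assert np.array_equal(s1.xy, s2.xy) and s1.ids == s2.ids

    def test_type_counts_within_binomial_interval(self):
        n = 10_000
        scene = place_nodes((100, 100), n, 0.5, seed=11)
        n_u = sum(t == "U" for t in scene.types)
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.5)
        assert lo <= n_u <= hi

    def test_mask_array(self):
        mask = np.zeros((50, 80), dtype=bool)   # (rows=y, cols=x)
        mask[10:20, 30:40] = True
        scene = place_nodes(mask, 500, 0.5, seed=1)
        assert (scene.xy[:, 0] >= 30).all() and (scene.xy[:, 0] <= 40).all()
        assert (scene.xy[:, 1] >= 10).all() and (scene.xy[:, 1] <= 20).all()

    def test_zero_area_mask(self):
        with pytest.raises(ValueError, match="area"):
            place_nodes(np.zeros((5, 5), dtype=bool), 10, 0.5, seed=0)


class TestSimParams:
    def test_sigma_from_physical(self):
        p = SimParams(a=1.0, D=2.0, t=3.0, d=2)
        assert p.sigma == pytest.approx(np.sqrt(8 * 2 * 2.0 * 3.0), rel=1e-12)

    def test_inconsistent_sigma_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            SimParams(a=1.0, sigma=5.0, D=2.0, t=3.0, d=2)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            SimParams(a=-1.0, sigma=1.0)


class TestSimulateGraph:
    def test_coincident_pair_mean(self):
        draws = replicate_edge_weights(a=10, sigma=50, dist=0.0,
                                       n_draws=20_000, seed=5)
        se = np.sqrt(10 / len(draws))
        assert abs(draws.mean() - 10) < 3 * se

    def test_distance_attenuated_mean(self):
        # closed-form mean 10 * exp(-1) at dist == sigma
        draws = replicate_edge_weights(a=10, sigma=50, dist=50.0,
                                       n_draws=20_000, seed=6)
        expected = 10 * np.exp(-1)
        se = np.sqrt(expected / len(draws))
        assert abs(draws.mean() - expected) < 3 * se

    def test_zero_amplitude_empty(self):
        scene = place_nodes((50, 50), 100, 0.5, seed=2)
        g = simulate_graph(scene, SimParams(a=0.0, sigma=10), seed=3)
        assert g.n_edges == 0

    def test_no_same_type_edges(self):
        scene = place_nodes((50, 50), 200, 0.5, seed=4)
        g = simulate_graph(scene, SimParams(a=5, sigma=20), seed=5)
        u_set = set(scene.u_ids)
        for u, v, _ in g.edges():
            assert (u in u_set) != (v in u_set)

    def test_degree_monotone_in_sigma(self):
        scene = place_nodes((100, 100), 400, 0.5, seed=8)
        means = []
        for sigma in (5, 15, 40):
            g = simulate_graph(scene, SimParams(a=3, sigma=sigma), seed=9)
            means.append(g.n_edges)
        assert means[0] < means[1] < means[2]


def _small_graph(seed=0):
    scene = place_nodes((80, 80), 300, 0.5, seed=seed)
    return scene, simulate_graph(scene, SimParams(a=5, sigma=15), seed=seed + 1)


class TestInjectCrosslinks:
    def test_fraction_zero_identity(self):
        _, g = _small_graph()
        out, ledger = inject_spurious_crosslinks(g, 0.0, seed=1)
        assert out == g and not ledger.crosslinks

    def test_event_count_and_weight(self):
        _, g = _small_graph()
        target = round(0.10 * g.total_weight)
        out, ledger = inject_spurious_crosslinks(g, 0.10, seed=2)
        added = sum(w for _, _, w in ledger.crosslinks)
        assert added == target
        assert out.total_weight == g.total_weight + target

    def test_endpoints_opposite_types(self):
        _, g = _small_graph()
        out, ledger = inject_spurious_crosslinks(g, 0.05, seed=3)
        for u, v, _ in ledger.crosslinks:
            assert u in g.u_index and v in g.v_index

    def test_empty_graph_rejected(self):
        from minipath import BipartiteGraph, ValidationError
        with pytest.raises(ValidationError):
            inject_spurious_crosslinks(BipartiteGraph([], []), 0.1, seed=0)


class TestInjectFusedNodes:
    def test_fraction_zero_identity(self):
        _, g = _small_graph()
        out, ledger = inject_fused_nodes(g, 0.0, seed=1)
        assert out == g and not ledger.fusions

    def test_event_and_node_counts(self):
        scene = place_nodes((80, 80), 200, 0.5, seed=10)
        g = simulate_graph(scene, SimParams(a=5, sigma=15), seed=11)
        out, ledger = inject_fused_nodes(g, 0.05, seed=12)
        assert len(ledger.fusions) == 10
        assert out.n_nodes == g.n_nodes - 10

    def test_fused_weights_are_sums(self):
        from minipath import BipartiteGraph
        g = BipartiteGraph.from_edges([
            ("u1", "v1", 2), ("u2", "v1", 3), ("u1", "v2", 1),
            ("u3", "v2", 4), ("u4", "v2", 1), ("u3", "v1", 1)])
        # force exactly one fusion event; find one that fused two U nodes
        for seed in range(20):
            out, ledger = inject_fused_nodes(g, 1 / g.n_nodes, seed=seed)
            rec = ledger.fusions[0]
            if rec.original_1 in g.u_index:
                shared = set(g.neighbors(rec.original_1)) & set(
                    g.neighbors(rec.original_2))
                if shared:
                    v = shared.pop()
                    assert out.weight(rec.fused_id, v) == (
                        g.weight(rec.original_1, v) + g.weight(rec.original_2, v))
                    return
        pytest.skip("no U-side fusion with shared neighbor in 20 seeds")

    def test_same_type_constituents(self):
        _, g = _small_graph()
        out, ledger = inject_fused_nodes(g, 0.1, seed=13)
        for rec in ledger.fusions:
            assert ((rec.original_1 in g.u_index)
                    == (rec.original_2 in g.u_index))

    def test_ledger_neighbor_sets_match_prefusion(self):
        _, g = _small_graph()
        out, ledger = inject_fused_nodes(g, 0.05, seed=14)
        rec = ledger.fusions[0]
        assert set(rec.neighbors_1) == set(g.neighbors(rec.original_1))


class TestReactivityBias:
    def test_zero_fraction_reproduces_simulate(self):
        scene, _ = _small_graph()
        params = SimParams(a=5, sigma=15)
        g_plain = simulate_graph(scene, params, seed=21)
        g_bias, ledger = inject_reactivity_bias(scene, params, 0.0, 2.0, seed=21)
        assert g_bias == g_plain and not ledger.biased

    def test_bias_multiplies_mean(self):
        # isolated coincident pair, both nodes biased: mean a * factor^2
        ids = ["b0", "t0"]
        xy = np.zeros((2, 2))
        scene = SimScene(ids=ids, xy=xy, types=np.array(["U", "V"]),
                         mask=(10, 10))
        params = SimParams(a=5, sigma=10)
        rng = np.random.default_rng(30)
        draws = []
        for _ in range(3000):
            g, _ = inject_reactivity_bias(scene, params, 1.0, 2.0, seed=rng)
            draws.append(g.weight("b0", "t0") if g.n_edges else 0)
        expected = 5 * 4
        se = np.sqrt(expected / len(draws))
        assert abs(np.mean(draws) - expected) < 3 * se

    def test_ledger_lists_biased_nodes(self):
        scene, _ = _small_graph()
        _, ledger = inject_reactivity_bias(
            scene, SimParams(a=5, sigma=15), 0.1, 2.0, seed=31)
        assert len(ledger.biased) == round(0.1 * scene.n_nodes)


class TestLedgerIO:
    def test_json_round_trip(self, tmp_path):
        _, g = _small_graph()
        _, l1 = inject_spurious_crosslinks(g, 0.05, seed=40)
        _, l2 = inject_fused_nodes(g, 0.05, seed=41)
        l1.fusions = l2.fusions
        path = tmp_path / "ledger.json"
        l1.to_json(path)
        from minipath.simulate import ErrorLedger
        back = ErrorLedger.from_json(path)
        assert back.crosslinks == l1.crosslinks
        assert back.fusion_map() == l1.fusion_map()
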