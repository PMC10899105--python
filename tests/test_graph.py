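"""Bipartite graph model, UEI table I/O, and the experimental-data filters."""

import collections

import numpy as np
import pytest

from minipath import (BipartiteGraph, FormatError, ValidationError, aggregate,
                      iterative_low_product_filter, largest_component,
                      load_uei_table, read_count_filter, write_uei_table)

from conftest import make_uei_table, random_bipartite


class TestUEITableIO:
    def test_round_trip(self, uei_rows, tmp_path):
        table = make_uei_table(uei_rows)
        path = tmp_path / "uei.tsv"
        write_uei_table(table, path)
        loaded = load_uei_table(path)
        assert len(loaded) == 5
        assert loaded.records.equals(table.records)

    def test_header_only_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("beacon_id\ttarget_id\tuei_id\tread_count\n")
        assert len(load_uei_table(path)) == 0

    def test_zero_read_count_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("beacon_id\ttarget_id\tuei_id\tread_count\n"
                        "b1\tt1\tx1\t3\n"
                        "b1\tt2\tx2\t0\n")
        with pytest.raises(ValidationError, match="3"):
            load_uei_table(path)

    def test_missing_column(self, tmp_path):
        path = tmp_path / "cols.tsv"
        path.write_text("beacon_id\ttarget_id\tread_count\nb\tt\t1\n")
        with pytest.raises(FormatError, match="uei_id"):
            load_uei_table(path)

    def test_duplicate_uei_rejected(self):
        with pytest.raises(ValidationError, match="uei_id"):
            make_uei_table([("b1", "t1", "x1", 1), ("b2", "t1", "x1", 1)])


class TestAggregate:
    def test_counts_ueis_not_reads(self, uei_rows):
        g = aggregate(make_uei_table(uei_rows))
        # 3 UEIs on (b1, t1) despite 8 total reads; 1 on (b1, t2)
        assert g.weight("b1", "t1") == 3
        assert g.weight("b1", "t2") == 1
        assert g.weight("b2", "t1") == 1

    def test_bipartition_violation(self):
        table = make_uei_table([("n1", "t1", "x1", 1), ("b2", "n1", "x2", 1)])
        with pytest.raises(ValidationError, match="both"):
            aggregate(table)

    def test_random_table_weight_sum(self):
        rng = np.random.default_rng(7)
        pairs = [(f"b{i}", f"t{i % 3}") for i in range(10)]
        rows = []
        counter = collections.Counter()
        for k in range(100):
            b, t = pairs[rng.integers(0, 10)]
            rows.append((b, t, f"x{k}", int(rng.integers(1, 9))))
            counter[(b, t)] += 1
        g = aggregate(make_uei_table(rows))
        assert g.total_weight == 100
        for (b, t), n in counter.items():
            assert g.weight(b, t) == n


class TestReadCountFilter:
    def test_threshold(self, uei_rows):
        table = make_uei_table(uei_rows)
        assert len(read_count_filter(table, 4)) == 2

    def test_identity_and_empty(self, uei_rows):
        table = make_uei_table(uei_rows)
        assert read_count_filter(table, 1).records.equals(table.records)
        assert len(read_count_filter(table, 6)) == 0

    @pytest.mark.parametrize("lo,hi", [(1, 2), (2, 4), (3, 5)])
    def test_monotone(self, uei_rows, lo, hi):
        table = make_uei_table(uei_rows)
        kept_hi = set(read_count_filter(table, hi).records["uei_id"])
        kept_lo = set(read_count_filter(table, lo).records["uei_id"])
        assert kept_hi <= kept_lo


class TestIterativeLowProductFilter:
    def test_path_cascades_to_empty(self, path_graph):
        g = iterative_low_product_filter(path_graph)
        assert g.n_nodes == 0

    def test_k22_weight2_unchanged(self):
        g = BipartiteGraph.from_edges(
            [(u, v, 2) for u in ("u1", "u2") for v in ("v1", "v2")])
        assert iterative_low_product_filter(g) == g

    def test_single_weight2_edge_kept(self):
        core = [(u, v, 2) for u in ("u1", "u2") for v in ("v1", "v2")]
        g = BipartiteGraph.from_edges(core + [("u3", "v1", 2)])
        out = iterative_low_product_filter(g)
        assert "u3" in out.u_ids  # 2 products >= 2

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent_and_order_independent(self, seed):
        rng = np.random.default_rng(seed)
        g = random_bipartite(rng, 8, 8, density=0.25, max_w=2)
        once = iterative_low_product_filter(g)
        assert iterative_low_product_filter(once) == once
        # oracle: remove sub-threshold nodes one at a time in random order
        edges = dict(((u, v), w) for u, v, w in g.edges())
        alive = set(g.nodes())
        while True:
            strengths = collections.Counter()
            for (u, v), w in edges.items():
                strengths[u] += w
                strengths[v] += w
            weak = [n for n in alive if strengths[n] < 2]
            if not weak:
                break
            victim = weak[rng.integers(0, len(weak))]
            alive.discard(victim)
            edges = {e: w for e, w in edges.items() if victim not in e}
        assert set(once.nodes()) == alive


class TestLargestComponent:
    def test_connected_graph(self, k22):
        out, frac = largest_component(k22)
        assert out == k22 and frac == 1.0

    def test_two_components(self):
        big = [(f"u{i}", f"v{i}", 1) for i in range(3)]
        big += [(f"u{i}", f"v{(i + 1) % 3}", 1) for i in range(3)]  # 6-cycle
        small = [("x1", "y1", 1), ("x2", "y1", 1), ("x2", "y2", 1)]
        g = BipartiteGraph.from_edges(big + small)
        out, frac = largest_component(g)
        assert out.n_nodes == 6
        assert frac == pytest.approx(0.6)

    def test_empty_graph(self):
        g = BipartiteGraph([], [])
        out, frac = largest_component(g)
        assert out.n_nodes == 0 and frac == 0.0

    def test_tie_break_lexicographic(self):
        g = BipartiteGraph.from_edges([("a1", "z9", 1), ("b1", "c1", 1)])
        out, _ = largest_component(g)
        assert "a1" in out.nodes()


class TestGraphModel:
    def test_rejects_same_side_duplicates(self):
        with pytest.raises(ValidationError):
            BipartiteGraph(["n1"], ["n1"])

    def test_weight_symmetric_lookup(self, k22):
        assert k22.weight("v1", "u1") == k22.weight("u1", "v1") == 1

    def test_edge_tsv_round_trip(self, tmp_path, uei_rows):
        g = aggregate(make_uei_table(uei_rows))
        path = tmp_path / "edges.tsv"
        g.to_edge_tsv(path)
        assert BipartiteGraph.from_edge_tsv(path) == g

    def test_mtx_export(self, tmp_path, k22):
        import scipy.io
        path = tmp_path / "adj.mtx"
        k22.to_mtx(path)
        mat = scipy.io.mmread(path)
        assert mat.toarray().tolist() == k22.matrix.toarray().tolist()
        assert (path.parent / "adj.mtx.u.txt").read_text().split() == k22.u_ids

    def test_metadata(self, k22):
        meta = k22.metadata()
        assert meta == {"n_beacons": 2, "n_targets": 2,
                        "n_edges": 4, "total_ueis": 4}
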