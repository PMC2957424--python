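import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dysnet import (
    CoverInstance,
    RunConfig,
    build_instance,
    cleanup,
    expanding_greedy,
    expanding_greedy_2phase,
    hide_hubs,
    is_connected_cover,
)
from dysnet.dysregulation import DysregulationMatrix
from helpers import random_instance


class TestBuildInstance:
    def test_reconciliation(self):
        g = nx.Graph([("A", "B")])
        m = DysregulationMatrix(["A", "C"], ["u1", "u2"],
                                np.array([[1, 0], [1, 1]], dtype=bool), "UP")
        inst = build_instance(g, m, k=1, l=0)
        assert inst.cover_sets["A"] == {"u1"}
        assert inst.cover_sets["B"] == frozenset()      # connector node
        assert "C" not in inst.cover_sets                # not in network

    def test_l_bounds(self):
        g = nx.Graph([("A", "B")])
        m = DysregulationMatrix(["A"], ["u1", "u2"],
                                np.array([[1, 1]], dtype=bool), "UP")
        with pytest.raises(ValueError):
            build_instance(g, m, k=1, l=2)
        with pytest.raises(ValueError):
            build_instance(g, m, k=0, l=0)

    def test_no_overlap_errors(self):
        g = nx.Graph([("A", "B")])
        m = DysregulationMatrix(["X"], ["u1"], np.array([[1]], dtype=bool), "UP")
        with pytest.raises(ValueError):
            build_instance(g, m, k=1, l=0)

    def test_outlier_count_floor(self):
        assert RunConfig(outlier_fraction=0.20).outlier_count(3) == 0
        assert RunConfig(outlier_fraction=0.20).outlier_count(20) == 4
        assert RunConfig(outlier_fraction=0.20).outlier_count(29) == 5


class TestIsConnectedCover:
    def test_outlier_tolerance(self, triangle_instance):
        ok, outliers = is_connected_cover({"g1", "g2", "g3"}, triangle_instance)
        assert ok
        assert outliers == {"c2"}

    def test_disconnected_perfect_coverage_rejected(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        inst = CoverInstance(g, {"a": {"u1"}, "c": {"u1"}, "b": set(), "d": set()},
                             ["u1"], k=2, l=0)
        ok, _ = is_connected_cover({"a", "c"}, inst)
        assert not ok

    def test_full_coverage_no_outliers(self, path_instance):
        ok, outliers = is_connected_cover({"a", "b", "c"}, path_instance)
        assert ok and outliers == frozenset()

    def test_empty_set_is_false(self, path_instance):
        ok, outliers = is_connected_cover(set(), path_instance)
        assert not ok and outliers == {"u1", "u2", "u3"}


class TestHideHubs:
    def test_barren_star_hub_removed(self):
        # hub with 101 weakly covering leaves, in a graph where most
        # neighborhoods see heavy dysregulation: hub scores below the 75%
        # quantile and is removed; nothing else has degree > 100
        g = nx.star_graph(101)  # center 0, leaves 1..101
        g = nx.relabel_nodes(g, {v: f"n{v}" for v in g.nodes})
        sets = {v: {"u1"} for v in g.nodes}
        sets["n0"] = set()
        cases = [f"u{i}" for i in range(5)]
        clique = [f"q{i}" for i in range(40)]
        g.add_edges_from(
            (a, b) for i, a in enumerate(clique) for b in clique[i + 1:]
        )
        g.add_edge("n1", "q0")
        for q in clique:
            sets[q] = set(cases)
        out = hide_hubs(g, sets, hub_degree=100, hub_quantile=0.75)
        assert "n0" not in out.nodes
        assert all(q in out.nodes for q in clique)

    def test_degree_100_never_removed(self):
        g = nx.star_graph(100)  # center degree exactly 100
        g = nx.relabel_nodes(g, {v: f"n{v}" for v in g.nodes})
        out = hide_hubs(g, {v: set() for v in g.nodes}, hub_degree=100)
        assert "n0" in out.nodes

    def test_active_hub_retained(self):
        # hub whose neighbors all carry large cover sets scores in the top 25%
        g = nx.star_graph(101)
        g = nx.relabel_nodes(g, {v: f"h{v}" for v in g.nodes})
        cases = [f"u{i}" for i in range(10)]
        sets = {v: set(cases) for v in g.nodes if v != "h0"}
        sets["h0"] = set()
        out = hide_hubs(g, sets, hub_degree=100, hub_quantile=0.75)
        assert "h0" in out.nodes


class TestExpandingGreedy:
    def test_connector_node_included(self, path_instance):
        dp = expanding_greedy(path_instance, root="a")
        assert dp.nodes == {"a", "b", "c"}
        assert dp.root == "a" and dp.radius == 2

    def test_root_covering_everything(self, path_instance):
        inst = CoverInstance(path_instance.graph,
                             {"a": {"u1", "u2", "u3"}, "b": set(), "c": set()},
                             ["u1", "u2", "u3"], k=1, l=0)
        dp = expanding_greedy(inst, root="a")
        assert dp.nodes == {"a"} and dp.radius == 0

    def test_tie_broken_by_neighbor_coverage(self):
        # candidates y5 and y3 both newly cover 2 cases; y5's neighborhood
        # covers 5 distinct cases vs 3 -> y5 wins even though y3 is
        # lexicographically smaller ('a5' named to lose a lex tie-break)
        g = nx.Graph([("r", "zz"), ("r", "aa"), ("zz", "x5"), ("aa", "x3")])
        U = [f"u{i}" for i in range(1, 6)]
        sets = {"r": set(), "zz": {"u1", "u2"}, "aa": {"u1", "u2"},
                "x5": {"u1", "u2", "u3", "u4", "u5"}, "x3": {"u3", "u4", "u5"}}
        inst = CoverInstance(g, sets, U, k=1, l=3)
        dp = expanding_greedy(inst, root="r")
        assert "zz" in dp.nodes and "aa" not in dp.nodes

    def test_unreachable_coverage_fails(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        inst = CoverInstance(g, {"a": {"u1"}, "b": set(), "c": {"u2"}, "d": set()},
                             ["u1", "u2"], k=1, l=0)
        assert expanding_greedy(inst, root="a") is None

    def test_root_must_be_allowed(self, path_instance):
        with pytest.raises(ValueError):
            expanding_greedy(path_instance, root="a", allowed={"b", "c"})


class TestCleanup:
    def test_superfluous_leaf_removed(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "d")])
        inst = CoverInstance(
            g, {"a": {"u1"}, "b": {"u2"}, "c": {"u1", "u2"}, "d": {"u2"}},
            ["u1", "u2"], k=1, l=0,
        )
        from dysnet.cover import DPResult
        dp = DPResult(nodes=frozenset("abcd"), root="a", radius=3, k=1, l=0,
                      outliers=frozenset())
        cleaned = cleanup(dp, inst)
        assert cleaned.nodes == {"a", "b"}

    def test_minimal_cover_is_fixed_point(self, path_instance):
        dp = expanding_greedy(path_instance, root="a")
        once = cleanup(dp, path_instance)
        twice = cleanup(once, path_instance)
        assert once.nodes == dp.nodes == twice.nodes

    def test_invalid_input_rejected(self, path_instance):
        from dysnet.cover import DPResult
        bad = DPResult(nodes=frozenset({"a"}), root="a", radius=0, k=1, l=0,
                       outliers=frozenset())
        with pytest.raises(ValueError):
            cleanup(bad, path_instance)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_cleanup_valid_and_idempotent_fuzz(self, seed):
        rng = np.random.default_rng(seed)
        inst = random_instance(rng, n_nodes=12, n_cases=5, cover_p=0.4,
                               k=int(rng.integers(1, 3)), l=int(rng.integers(0, 2)))
        root = inst.nodes[int(rng.integers(len(inst.nodes)))]
        dp = expanding_greedy(inst, root=root)
        if dp is None:
            return
        cleaned = cleanup(dp, inst)
        ok, _ = is_connected_cover(cleaned.nodes, inst)
        assert ok and cleaned.size <= dp.size
        assert cleanup(cleaned, inst).nodes == cleaned.nodes


class TestTwoPhase:
    def test_l_zero_identical_to_single_phase(self, path_instance):
        one = cleanup(expanding_greedy(path_instance, root="a"), path_instance)
        two = expanding_greedy_2phase(path_instance, root="a")
        assert one.nodes == two.nodes

    def test_outlier_prehiding_beats_single_phase(self):
        # pass 1 is forced through a detour node covering a case that ends up
        # discarded; hiding that outlier up front reveals a 2-node cover
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "e")])
        sets = {"a": {"u1", "u2"}, "b": {"u1", "u3"}, "c": {"u1", "u2"},
                "e": {"u1", "u2"}}
        inst = CoverInstance(g, sets, ["u1", "u2", "u3"], k=2, l=1)
        single = cleanup(expanding_greedy(inst, root="a"), inst)
        two = expanding_greedy_2phase(inst, root="a")
        assert single.nodes == {"a", "b", "c"}
        assert two.nodes == {"a", "e"}
        assert two.size < single.size

    def test_never_worse_than_single_phase(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            inst = random_instance(rng, n_nodes=14, n_cases=6, cover_p=0.35,
                                   k=2, l=1)
            root = inst.nodes[int(rng.integers(len(inst.nodes)))]
            dp1 = expanding_greedy(inst, root=root)
            if dp1 is None:
                continue
            dp1 = cleanup(dp1, inst)
            dp2 = expanding_greedy_2phase(inst, root=root)
            assert dp2.size <= dp1.size
            ok, _ = is_connected_cover(dp2.nodes, inst)
            assert ok
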