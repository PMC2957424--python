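import networkx as nx
import numpy as np
import pytest

from dysnet import (
    CoverInstance,
    InfeasibleError,
    brute_force_mcc,
    is_connected_cover,
    min_radius_for_root,
    radius_scan,
    solve,
)
from helpers import oracle_radius_scan, random_instance


class TestMinRadiusForRoot:
    def test_star_center_needs_one_hop(self):
        g = nx.star_graph(4)
        g = nx.relabel_nodes(g, {v: f"n{v}" for v in g.nodes})
        sets = {"n0": set()} | {f"n{i}": {f"u{i}"} for i in range(1, 5)}
        inst = CoverInstance(g, sets, [f"u{i}" for i in range(1, 5)], k=1, l=0)
        assert min_radius_for_root(inst, "n0") == 1

    def test_self_sufficient_root_radius_zero(self, path_instance):
        inst = CoverInstance(path_instance.graph,
                             {"a": {"u1", "u2", "u3"}, "b": set(), "c": set()},
                             ["u1", "u2", "u3"], k=1, l=0)
        assert min_radius_for_root(inst, "a") == 0

    def test_isolated_empty_node_infeasible(self):
        g = nx.Graph()
        g.add_node("a")
        inst = CoverInstance(g, {"a": set()}, ["u1"], k=1, l=0)
        assert min_radius_for_root(inst, "a") is None

    def test_cap_halts_early(self, path_instance):
        # a's true radius is 2 (needs c for u3); with cap 1 it reports None
        assert min_radius_for_root(path_instance, "a") == 2
        assert min_radius_for_root(path_instance, "a", cap=1) is None

    def test_unknown_root_rejected(self, path_instance):
        with pytest.raises(ValueError):
            min_radius_for_root(path_instance, "zz")


class TestRadiusScan:
    def test_middle_node_wins_on_path(self):
        g = nx.path_graph(["a", "b", "c"])
        inst = CoverInstance(g, {"a": {"u1"}, "b": set(), "c": {"u2"}},
                             ["u1", "u2"], k=1, l=0)
        scan = radius_scan(inst)
        assert scan.r_min == 1
        assert scan.v_min == {"b"}
        assert scan.per_root["b"] == 1

    def test_infeasible_instance(self):
        g = nx.path_graph(["a", "b"])
        inst = CoverInstance(g, {"a": {"u1"}, "b": set()}, ["u1", "u2"], k=1, l=0)
        scan = radius_scan(inst)
        assert scan.r_min is None and scan.v_min == frozenset()

    def test_clique_with_self_sufficient_node(self):
        g = nx.complete_graph(["a", "b", "c"])
        inst = CoverInstance(g, {"a": {"u1", "u2"}, "b": {"u1"}, "c": set()},
                             ["u1", "u2"], k=1, l=0)
        scan = radius_scan(inst)
        assert scan.r_min == 0 and scan.v_min == {"a"}

    def test_agrees_with_uncapped_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            inst = random_instance(rng, n_nodes=15, n_cases=5, cover_p=0.25,
                                   k=int(rng.integers(1, 3)),
                                   l=int(rng.integers(0, 2)))
            r_min, v_min, per_root = oracle_radius_scan(inst)
            scan = radius_scan(inst)
            assert scan.r_min == r_min
            assert scan.v_min == v_min
            # capped values, where reported, must equal the uncapped oracle
            for v, r in scan.per_root.items():
                if r is not None:
                    assert r == per_root[v]

    def test_isomorphism_invariance(self):
        rng = np.random.default_rng(3)
        inst = random_instance(rng, n_nodes=12, n_cases=4, cover_p=0.3, k=2, l=1)
        mapping = {v: f"x{v}" for v in inst.graph.nodes}
        g2 = nx.relabel_nodes(inst.graph, mapping)
        sets2 = {mapping[v]: s for v, s in inst.cover_sets.items()}
        inst2 = CoverInstance(g2, sets2, inst.universe, inst.k, inst.l)
        s1, s2 = radius_scan(inst), radius_scan(inst2)
        assert s1.r_min == s2.r_min
        assert {mapping[v] for v in s1.v_min} == set(s2.v_min)

    def test_rmin_neighborhood_feasible_minus_one_not(self):
        rng = np.random.default_rng(5)
        checked = 0
        for _ in range(30):
            inst = random_instance(rng, n_nodes=12, n_cases=4, cover_p=0.3,
                                   k=1, l=0)
            scan = radius_scan(inst)
            if scan.r_min is None or scan.r_min == 0:
                continue
            for root in scan.v_min:
                ok, _ = is_connected_cover(inst.neighborhood(root, scan.r_min), inst)
                assert ok
                ok1, _ = is_connected_cover(
                    inst.neighborhood(root, scan.r_min - 1), inst)
                assert not ok1
                checked += 1
        assert checked > 10


class TestSolve:
    def test_path_example(self, path_instance):
        sols = solve(path_instance)
        assert len(sols) == 1
        assert sols[0].nodes == {"a", "b", "c"}
        assert sols[0].root == "b" and sols[0].radius == 1

    def test_single_node_optimum(self):
        g = nx.path_graph(["a", "b", "c"])
        inst = CoverInstance(g, {"a": set(), "b": {"u1", "u2"}, "c": set()},
                             ["u1", "u2"], k=1, l=0)
        sols = solve(inst)
        assert [s.nodes for s in sols] == [frozenset({"b"})]
        assert sols[0].radius == 0

    def test_symmetric_ties_all_returned(self):
        # two mirror-image roots give equal smallest covers
        g = nx.path_graph(["a", "b", "c", "d"])
        sets = {"a": {"u1"}, "b": {"u2"}, "c": {"u2"}, "d": {"u1"}}
        inst = CoverInstance(g, sets, ["u1", "u2"], k=1, l=0)
        sols = solve(inst)
        assert len(sols) >= 2
        assert {s.nodes for s in sols} == {frozenset({"a", "b"}), frozenset({"c", "d"})}
        assert len({s.root for s in sols}) == len(sols)

    def test_infeasible_raises(self):
        g = nx.path_graph(["a", "b"])
        inst = CoverInstance(g, {"a": {"u1"}, "b": set()}, ["u1", "u2"], k=1, l=0)
        with pytest.raises(InfeasibleError):
            solve(inst)

    def test_every_result_is_valid_cover(self):
        rng = np.random.default_rng(21)
        n_solved = 0
        for _ in range(50):
            inst = random_instance(rng, n_nodes=12, n_cases=5, cover_p=0.3,
                                   k=int(rng.integers(1, 3)),
                                   l=int(rng.integers(0, 2)))
            try:
                sols = solve(inst)
            except InfeasibleError:
                assert brute_force_mcc(inst)[0] is None
                continue
            n_solved += 1
            for dp in sols:
                ok, outliers = is_connected_cover(dp.nodes, inst)
                assert ok
                assert dp.outliers == outliers
                assert len(outliers) <= inst.l
                dist = dict(nx.single_source_shortest_path_length(
                    inst.graph, dp.root))
                assert all(dist[v] <= dp.radius for v in dp.nodes)
        assert n_solved > 20


class TestBruteForce:
    def test_path_optimum_is_three(self, path_instance):
        size, witness = brute_force_mcc(path_instance)
        assert size == 3 and witness == {"a", "b", "c"}

    def test_single_feasible_node(self):
        g = nx.path_graph(["a", "b"])
        inst = CoverInstance(g, {"a": {"u1"}, "b": set()}, ["u1"], k=1, l=0)
        assert brute_force_mcc(inst) == (1, frozenset({"a"}))

    def test_infeasible_returns_none(self):
        g = nx.path_graph(["a", "b"])
        inst = CoverInstance(g, {"a": {"u1"}, "b": set()}, ["u1", "u2"], k=1, l=0)
        assert brute_force_mcc(inst) == (None, None)

    def test_too_large_rejected(self):
        rng = np.random.default_rng(0)
        inst = random_instance(rng, n_nodes=20, n_cases=3)
        with pytest.raises(ValueError):
            brute_force_mcc(inst, max_nodes=14)

    def test_greedy_never_beats_optimum(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            inst = random_instance(rng, n_nodes=10, n_cases=4, cover_p=0.35,
                                   k=1, l=0)
            opt, _ = brute_force_mcc(inst)
            try:
                sols = solve(inst)
            except InfeasibleError:
                assert opt is None
                continue
            assert opt is not None
            assert sols[0].size >= opt
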