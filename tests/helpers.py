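"""Shared test utilities: random instances and independent oracles.

The oracles here deliberately avoid the package's fast paths: radii come
from networkx shortest-path lengths, coverage from collections.Counter, and
the greedy set-cover reference is a plain textbook implementation.
"""

from __future__ import annotations

from collections import Counter
from itertools import combinations

import networkx as nx
import numpy as np

from dysnet.cover import CoverInstance


def random_connected_graph(n: int, rng: np.random.Generator, extra_edge_p: float = 0.2) -> nx.Graph:
    """Random tree plus sprinkled extra edges; always connected."""
    g = nx.Graph()
    nodes = [f"n{i:02d}" for i in range(n)]
    g.add_nodes_from(nodes)
    for i in range(1, n):
        j = int(rng.integers(i))
        g.add_edge(nodes[i], nodes[j])
    for i, j in combinations(range(n), 2):
        if not g.has_edge(nodes[i], nodes[j]) and rng.random() < extra_edge_p:
            g.add_edge(nodes[i], nodes[j])
    return g


def random_instance(rng: np.random.Generator, n_nodes: int = 10,
                    n_cases: int = 4, cover_p: float = 0.3,
                    k: int = 1, l: int = 0) -> CoverInstance:
    """Random connected instance with iid Bernoulli cover sets."""
    g = random_connected_graph(n_nodes, rng)
    cases = [f"u{j}" for j in range(n_cases)]
    sets = {
        v: {u for u in cases if rng.random() < cover_p}
        for v in g.nodes
    }
    return CoverInstance(g, sets, cases, k, l)


def oracle_coverage_feasible(inst: CoverInstance, nodes) -> bool:
    counts = Counter()
    for v in nodes:
        counts.update(inst.cover_sets[v])
    under = sum(1 for u in inst.universe if counts[u] < inst.k)
    return under <= inst.l


def oracle_min_radius(inst: CoverInstance, root: str):
    """Per-root minimal feasible radius via networkx distances (no cap)."""
    dist = nx.single_source_shortest_path_length(inst.graph, root)
    max_d = max(dist.values())
    for r in range(max_d + 1):
        ball = [v for v, d in dist.items() if d <= r]
        if oracle_coverage_feasible(inst, ball):
            return r
    return None


def oracle_radius_scan(inst: CoverInstance):
    per_root = {v: oracle_min_radius(inst, v) for v in inst.graph.nodes}
    finite = [r for r in per_root.values() if r is not None]
    if not finite:
        return None, frozenset(), per_root
    r_min = min(finite)
    v_min = frozenset(v for v, r in per_root.items() if r == r_min)
    return r_min, v_min, per_root


def johnson_greedy_set_cover(sets: dict[str, frozenset], universe) -> list[str] | None:
    """Textbook greedy set cover: max new coverage, ties lexicographic."""
    uncovered = set(universe)
    chosen: list[str] = []
    while uncovered:
        best, best_gain = None, 0
        for name in sorted(sets):
            if name in chosen:
                continue
            gain = len(sets[name] & uncovered)
            if gain > best_gain:
                best, best_gain = name, gain
        if best is None:
            return None
        chosen.append(best)
        uncovered -= sets[best]
    return chosen


def hypergeom_tail_bruteforce(overlap: int, M: int, K: int, N: int) -> float:
    """P(X >= overlap) for hypergeometric(M, K, N) via direct comb sums."""
    from math import comb

    total = comb(M, N)
    return sum(
        comb(K, j) * comb(M - K, N - j)
        for j in range(overlap, min(K, N) + 1)
    ) / total
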