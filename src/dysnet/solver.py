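"""Minimal-radius driver for the connected (k,l)-cover search.

Biologically coherent modules tend to be compact, so rather than chasing the
globally smallest connected (k,l)-cover the driver first finds r_min — the
smallest radius r such that some node's r-neighborhood contains a valid
cover — then greedily solves MCC(k,l) inside every r_min-neighborhood that
admits one and reports the smallest result(s). The radius scan runs a BFS
from every node, maintaining a per-case counting array and testing the
coverage condition after each completed BFS level; once some root achieves
radius r*, later scans halt at level r*+1.

An exhaustive branch-free enumerator (:func:`brute_force_mcc`) provides the
exact optimum on small instances for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional

from .cover import (
    CoverInstance,
    DPResult,
    InfeasibleError,
    _induced_connected,
    cleanup,
    expanding_greedy,
    expanding_greedy_2phase,
    is_connected_cover,
)

__all__ = [
    "RadiusScan",
    "min_radius_for_root",
    "radius_scan",
    "solve",
    "brute_force_mcc",
]


@dataclass
class RadiusScan:
    """Outcome of the all-roots BFS radius search.

    ``r_min`` is None when no root admits a cover at any radius (infeasible
    instance). ``per_root`` maps each node to its minimal feasible radius;
    None marks roots whose radius exceeds the running cap (hence > r_min).
    """

    r_min: Optional[int]
    v_min: frozenset[str]
    per_root: dict[str, Optional[int]] = field(default_factory=dict)

    @property
    def feasible(self) -> bool:
        return self.r_min is not None


def _feasible_counts(inst: CoverInstance, node_indices: Iterable[int]) -> bool:
    """Coverage feasibility of a node set, ignoring connectivity."""
    counts = [0] * inst.n_cases
    for v in node_indices:
        m = inst.masks[v]
        while m:
            low = m & -m
            counts[low.bit_length() - 1] += 1
            m ^= low
    n_under = sum(1 for c in counts if c < inst.k)
    return n_under <= inst.l


def min_radius_for_root(inst: CoverInstance, v: str,
                        cap: Optional[int] = None) -> Optional[int]:
    """Smallest r <= cap whose r-neighborhood of ``v`` is coverage-feasible.

    BFS from ``v`` increments a per-case counting array as nodes are reached;
    after each completed level the (k,l) coverage condition is tested on the
    accumulated counts (the neighborhood is connected by construction, so the
    test is exactly CC(k,l) feasibility of the whole neighborhood). The root
    itself (level 0) counts before the first test. Returns None when no
    radius <= cap works; with cap set, the BFS halts at level cap+1.
    """
    if v not in inst._index:
        raise ValueError(f"node {v!r} not in the instance network")
    k, l = inst.k, inst.l
    n = inst.n_cases
    counts = [0] * n
    n_under = n

    def add(i: int) -> None:
        nonlocal n_under
        m = inst.masks[i]
        while m:
            low = m & -m
            u = low.bit_length() - 1
            counts[u] += 1
            if counts[u] == k:
                n_under -= 1
            m ^= low

    ri = inst.index(v)
    seen = {ri}
    add(ri)
    if n_under <= l:
        return 0
    frontier = [ri]
    r = 0
    while frontier:
        r += 1
        if cap is not None and r > cap:
            return None
        nxt = []
        for x in frontier:
            for w in inst.adj[x]:
                if w not in seen:
                    seen.add(w)
                    nxt.append(w)
                    add(w)
        if not nxt:
            return None  # component exhausted without feasibility
        if n_under <= l:
            return r
        frontier = nxt
    return None  # pragma: no cover


def _component_feasible(inst: CoverInstance) -> bool:
    """Quick necessary test: some connected component is coverage-feasible."""
    n_nodes = len(inst.nodes)
    seen = [False] * n_nodes
    for s in range(n_nodes):
        if seen[s]:
            continue
        comp = [s]
        seen[s] = True
        stack = [s]
        while stack:
            x = stack.pop()
            for w in inst.adj[x]:
                if not seen[w]:
                    seen[w] = True
                    comp.append(w)
                    stack.append(w)
        if _feasible_counts(inst, comp):
            return True
    return False


def radius_scan(inst: CoverInstance) -> RadiusScan:
    """Find r_min and the set V_min of roots feasible at that radius.

    Every node is tried as a BFS root in lexicographic order with a running
    radius cap (the best radius found so far); the cap only tightens, so the
    resulting (r_min, v_min) is independent of visitation order.
    """
    per_root: dict[str, Optional[int]] = {}
    if not _component_feasible(inst):
        return RadiusScan(None, frozenset(), {v: None for v in inst.nodes})
    best: Optional[int] = None
    for v in inst.nodes:
        r = min_radius_for_root(inst, v, cap=best)
        per_root[v] = r
        if r is not None and (best is None or r < best):
            best = r
    v_min = frozenset(v for v, r in per_root.items() if r == best)
    return RadiusScan(best, v_min, per_root)


def solve(inst: CoverInstance, use_two_phase: bool = True) -> list[DPResult]:
    """Find the smallest dysregulated pathway(s) at the minimal radius.

    For each root in V_min the search region is its r_min-neighborhood; the
    greedy expansion (two-phase by default) runs rooted there and the result
    is cleaned up and validated. All results tying the minimum size are
    returned, each carrying its root and realized radius.
    """
    scan = radius_scan(inst)
    if not scan.feasible:
        raise InfeasibleError(
            f"no connected ({inst.k},{inst.l})-cover exists in this instance"
        )
    results: list[DPResult] = []
    for root in sorted(scan.v_min):
        allowed = inst.neighborhood(root, scan.r_min)
        if use_two_phase:
            dp = expanding_greedy_2phase(inst, root, allowed)
        else:
            dp = expanding_greedy(inst, root, allowed)
            if dp is not None:
                dp = cleanup(dp, inst)
        if dp is None:  # pragma: no cover - cannot happen for V_min roots
            continue
        ok, _ = is_connected_cover(dp.nodes, inst)
        if not ok:  # pragma: no cover
            raise AssertionError("solver produced an invalid cover")
        results.append(dp)
    if not results:  # pragma: no cover
        raise InfeasibleError("all rooted searches failed")
    best = min(dp.size for dp in results)
    return [dp for dp in results if dp.size == best]


def smallest_dp_size(inst: CoverInstance, use_two_phase: bool = True) -> Optional[int]:
    """Size of the smallest DP, or None when the instance is infeasible."""
    try:
        return solve(inst, use_two_phase=use_two_phase)[0].size
    except InfeasibleError:
        return None


def brute_force_mcc(inst: CoverInstance, max_nodes: int = 14,
                    within: Optional[Iterable[str]] = None
                    ) -> tuple[Optional[int], Optional[frozenset[str]]]:
    """Exact minimum CC(k,l) size by exhaustive enumeration (test oracle).

    Enumerates node subsets in increasing cardinality, checking connectivity
    and the coverage condition; returns (optimal size, one witness) or
    (None, None) when infeasible. ``within`` restricts the candidate pool
    (e.g. to an r-neighborhood). Refuses instances beyond ``max_nodes``
    candidates — the problem is NP-hard and this is exponential.
    """
    pool = sorted(inst.nodes if within is None else set(within))
    if len(pool) > max_nodes:
        raise ValueError(
            f"brute force limited to {max_nodes} nodes, got {len(pool)}"
        )
    pool_idx = [inst.index(v) for v in pool]
    for size in range(1, len(pool_idx) + 1):
        for combo in combinations(pool_idx, size):
            cset = set(combo)
            if not _induced_connected(cset, inst):
                continue
            if _feasible_counts(inst, combo):
                return size, frozenset(inst.nodes[i] for i in combo)
    return None, None
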