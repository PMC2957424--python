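"""Connected (k,l)-cover machinery.

A *connected (k,l)-cover* (CC(k,l)) over a gene network G and per-gene cover
sets S_v (the cases in which gene v is dysregulated) is a node set C that
induces a connected subgraph and k-covers all but at most l of the n case
samples: at least n-l cases u satisfy |{v in C : u in S_v}| >= k. Finding a
minimum-cardinality CC(k,l) (the MCC(k,l) problem) generalizes set cover and
is NP-hard, so the production path is a rooted greedy expansion plus
practical heuristics (hub hiding, a two-phase outlier pass, and a clean-up
step); exact solvers for small instances live in :mod:`dysnet.solver`.

Internally nodes are mapped to integer indices (sorted lexicographically by
identifier, so ascending index order is the deterministic tie-break order)
and each cover set is a Python-int bitmask over case indices, which keeps the
greedy inner loop at a few ``int.bit_count`` calls per candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import math

import networkx as nx
import numpy as np

from .dysregulation import DysregulationMatrix

__all__ = [
    "CoverInstance",
    "DPResult",
    "InfeasibleError",
    "build_instance",
    "is_connected_cover",
    "coverage_counts",
    "hide_hubs",
    "expanding_greedy",
    "expanding_greedy_2phase",
    "cleanup",
]


class InfeasibleError(RuntimeError):
    """No connected (k,l)-cover exists for this instance."""


# ---------------------------------------------------------------------------
# instance
# ---------------------------------------------------------------------------


class CoverInstance:
    """A gene network, per-gene case cover sets, and the (k, l) parameters.

    ``universe`` is the ordered list of case samples (the elements to cover);
    every network node has a cover set (possibly empty: such nodes can still
    enter a cover as connectors). ``k`` is the per-case coverage requirement
    and ``l`` the number of case samples allowed to stay under-covered.
    """

    def __init__(self, graph: nx.Graph, cover_sets: Mapping[str, Iterable[str]],
                 universe: Sequence[str], k: int, l: int):
        n = len(universe)
        if k < 1:
            raise ValueError("k must be >= 1")
        if not 0 <= l < n:
            raise ValueError(f"l must satisfy 0 <= l < n_cases ({n}), got {l}")
        uni = list(universe)
        if len(set(uni)) != n:
            raise ValueError("duplicate case identifiers in universe")
        extra = set(cover_sets) - set(graph.nodes)
        if extra:
            raise ValueError(f"cover sets for non-network nodes: {sorted(extra)[:5]}")
        self.graph = graph
        self.universe: tuple[str, ...] = tuple(uni)
        self.k = int(k)
        self.l = int(l)
        self._case_index = {u: i for i, u in enumerate(self.universe)}
        uset = set(self.universe)
        self.cover_sets: dict[str, frozenset[str]] = {}
        for v in graph.nodes:
            s = frozenset(cover_sets.get(v, ()))
            if not s <= uset:
                raise ValueError(f"cover set of {v!r} contains non-universe cases")
            self.cover_sets[v] = s

        # fast index structures
        self.nodes: list[str] = sorted(graph.nodes)
        self._index = {v: i for i, v in enumerate(self.nodes)}
        self.adj: list[list[int]] = [
            sorted(self._index[w] for w in graph.neighbors(v)) for v in self.nodes
        ]
        self.masks: list[int] = [
            self._mask(self.cover_sets[v]) for v in self.nodes
        ]

    # -- bitmask helpers ---------------------------------------------------

    def _mask(self, cases: Iterable[str]) -> int:
        m = 0
        for u in cases:
            m |= 1 << self._case_index[u]
        return m

    def cases_from_mask(self, mask: int) -> frozenset[str]:
        return frozenset(
            self.universe[i] for i in range(len(self.universe)) if mask >> i & 1
        )

    @property
    def n_cases(self) -> int:
        return len(self.universe)

    def index(self, v: str) -> int:
        return self._index[v]

    # -- derived structures ------------------------------------------------

    def neighborhood(self, root: str, r: int) -> set[str]:
        """All nodes at graph distance <= r from ``root`` (includes root)."""
        ri = self._index[root]
        seen = {ri}
        frontier = [ri]
        for _ in range(r):
            nxt = []
            for v in frontier:
                for w in self.adj[v]:
                    if w not in seen:
                        seen.add(w)
                        nxt.append(w)
            if not nxt:
                break
            frontier = nxt
        return {self.nodes[i] for i in seen}

    def distances_from(self, root: str) -> dict[str, int]:
        ri = self._index[root]
        dist = {ri: 0}
        frontier = [ri]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for v in frontier:
                for w in self.adj[v]:
                    if w not in dist:
                        dist[w] = d
                        nxt.append(w)
            frontier = nxt
        return {self.nodes[i]: di for i, di in dist.items()}

    def with_cover_sets(self, cover_sets: Mapping[str, Iterable[str]]) -> "CoverInstance":
        return CoverInstance(self.graph, cover_sets, self.universe, self.k, self.l)

    def with_graph(self, graph: nx.Graph) -> "CoverInstance":
        sets = {v: self.cover_sets[v] for v in graph.nodes if v in self.cover_sets}
        return CoverInstance(graph, sets, self.universe, self.k, self.l)

    def restrict_universe(self, kept_cases: Sequence[str], l: int) -> "CoverInstance":
        kept = set(kept_cases)
        sets = {v: s & kept for v, s in self.cover_sets.items()}
        order = [u for u in self.universe if u in kept]
        return CoverInstance(self.graph, sets, order, self.k, l)


def build_instance(network: nx.Graph, m: DysregulationMatrix, k: int, l: int) -> CoverInstance:
    """Reconcile a network with a dysregulation matrix into a CoverInstance.

    Matrix genes absent from the network are dropped; network nodes absent
    from the matrix get empty cover sets (connector candidates). Raises if no
    matrix gene overlaps the network.
    """
    net_nodes = set(network.nodes)
    sets = m.cover_sets()
    kept = {g: s for g, s in sets.items() if g in net_nodes}
    if not kept:
        raise ValueError("no expression gene appears in the network")
    return CoverInstance(network, kept, list(m.cases), k, l)


# ---------------------------------------------------------------------------
# result container
# ---------------------------------------------------------------------------


@dataclass
class DPResult:
    """A solved dysregulated pathway: a validated connected (k,l)-cover."""

    nodes: frozenset[str]
    root: str
    radius: int
    k: int
    l: int
    outliers: frozenset[str]
    p_value: Optional[float] = None
    z_score: Optional[float] = None
    null_sizes: Optional[list] = None

    @property
    def size(self) -> int:
        return len(self.nodes)

    def to_dict(self) -> dict:
        return {
            "nodes": sorted(self.nodes),
            "root": self.root,
            "radius": self.radius,
            "k": self.k,
            "l": self.l,
            "outliers": sorted(self.outliers),
            "size": self.size,
            "p_value": self.p_value,
            "z_score": self.z_score,
            "null_sizes": self.null_sizes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DPResult":
        return cls(
            nodes=frozenset(d["nodes"]),
            root=d["root"],
            radius=int(d["radius"]),
            k=int(d["k"]),
            l=int(d["l"]),
            outliers=frozenset(d["outliers"]),
            p_value=d.get("p_value"),
            z_score=d.get("z_score"),
            null_sizes=d.get("null_sizes"),
        )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def coverage_counts(nodes: Iterable[str], inst: CoverInstance) -> dict[str, int]:
    """Per-case count of covering genes inside ``nodes``."""
    counts = dict.fromkeys(inst.universe, 0)
    for v in nodes:
        for u in inst.cover_sets[v]:
            counts[u] += 1
    return counts


def _induced_connected(idx_set: set[int], inst: CoverInstance) -> bool:
    if not idx_set:
        return False
    start = next(iter(idx_set))
    seen = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        for w in inst.adj[v]:
            if w in idx_set and w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == len(idx_set)


def is_connected_cover(C: Iterable[str], inst: CoverInstance) -> tuple[bool, frozenset[str]]:
    """Check the CC(k,l) conditions; return (valid, under-covered cases).

    Valid iff C is non-empty, induces a connected subgraph, and the number of
    cases covered fewer than k times is at most l. The returned set lists all
    under-covered cases (the permitted outliers when valid).
    """
    C = set(C)
    if not C <= set(inst.cover_sets):
        raise ValueError("C contains nodes outside the instance network")
    if not C:
        return False, frozenset(inst.universe)
    counts = coverage_counts(C, inst)
    under = frozenset(u for u, c in counts.items() if c < inst.k)
    connected = _induced_connected({inst.index(v) for v in C}, inst)
    return (connected and len(under) <= inst.l), under


# ---------------------------------------------------------------------------
# hub hiding
# ---------------------------------------------------------------------------


def _nearest_rank_quantile(values: Sequence[float], q: float) -> float:
    s = sorted(values)
    rank = max(1, math.ceil(q * len(s)))
    return s[rank - 1]


def hide_hubs(network: nx.Graph, cover_sets: Mapping[str, Iterable[str]],
              hub_degree: int = 100, hub_quantile: float = 0.75) -> nx.Graph:
    """Remove high-degree nodes with little dysregulation in their vicinity.

    Curated interaction networks over-connect well-studied genes; a naive
    cover will absorb such hubs regardless of disease relevance. Each node is
    scored by the mean cover-set size over its direct neighbors; a node is
    removed iff its degree strictly exceeds ``hub_degree`` AND its score is
    below the ``hub_quantile`` nearest-rank quantile of all nodes' scores.
    Removal is simultaneous (scores computed once on the input graph); the
    result may be disconnected.
    """
    if network.number_of_nodes() == 0:
        return network.copy()
    set_size = {v: len(set(cover_sets.get(v, ()))) for v in network.nodes}

    def score(v) -> float:
        nbrs = list(network.neighbors(v))
        if not nbrs:
            return 0.0
        return sum(set_size[w] for w in nbrs) / len(nbrs)

    scores = {v: score(v) for v in network.nodes}
    threshold = _nearest_rank_quantile(list(scores.values()), hub_quantile)
    drop = [
        v for v in network.nodes
        if network.degree(v) > hub_degree and scores[v] < threshold
    ]
    out = network.copy()
    out.remove_nodes_from(drop)
    return out


def apply_hub_hiding(inst: CoverInstance, hub_degree: int = 100,
                     hub_quantile: float = 0.75) -> CoverInstance:
    """Convenience: hub-hide an instance's network and rebuild it."""
    g = hide_hubs(inst.graph, inst.cover_sets, hub_degree, hub_quantile)
    if g.number_of_nodes() == inst.graph.number_of_nodes():
        return inst
    return inst.with_graph(g)


# ---------------------------------------------------------------------------
# greedy expansion
# ---------------------------------------------------------------------------


def _neighbor_union_size(v: int, inst: CoverInstance, allowed: set[int],
                         cache: dict[int, int]) -> int:
    # tie-break score: number of distinct cases covered by v's neighbors
    # (within the allowed search region)
    r = cache.get(v)
    if r is None:
        m = 0
        for w in inst.adj[v]:
            if w in allowed:
                m |= inst.masks[w]
        r = m.bit_count()
        cache[v] = r
    return r


def _greedy_indices(inst: CoverInstance, root: Optional[int],
                    allowed: set[int]) -> Optional[list[int]]:
    """Core greedy loop over integer indices; returns the pick order or None."""
    k, l = inst.k, inst.l
    n = inst.n_cases
    masks = inst.masks
    counts = [0] * n
    under = (1 << n) - 1  # bitmask of cases still below k coverage
    n_under = n
    tie_cache: dict[int, int] = {}

    def add(v: int) -> None:
        nonlocal under, n_under
        m = masks[v]
        while m:
            low = m & -m
            u = low.bit_length() - 1
            counts[u] += 1
            if counts[u] == k:
                under &= ~low
                n_under -= 1
            m ^= low

    picked: list[int] = []
    in_cover: set[int] = set()
    frontier: set[int] = set()

    def best_of(candidates: Iterable[int]) -> Optional[int]:
        best = None
        best_key = None
        for v in sorted(candidates):  # ascending index == lexicographic
            gain = (masks[v] & under).bit_count()
            if best_key is not None and gain < best_key[0]:
                continue
            tie = _neighbor_union_size(v, inst, allowed, tie_cache)
            key = (gain, tie)
            if best_key is None or key > best_key:
                best, best_key = v, key
        return best

    if root is None:
        root = best_of(allowed)
        if root is None:
            return None

    v = root
    while True:
        picked.append(v)
        in_cover.add(v)
        add(v)
        if n_under <= l:
            return picked
        frontier.discard(v)
        for w in inst.adj[v]:
            if w in allowed and w not in in_cover:
                frontier.add(w)
        if not frontier:
            return None
        v = best_of(frontier)


def _finish(picked: list[int], inst: CoverInstance, root_idx: int,
            base: CoverInstance | None = None) -> DPResult:
    """Build a validated DPResult against instance ``base`` (default inst)."""
    base = base or inst
    nodes = frozenset(inst.nodes[i] for i in picked)
    root = inst.nodes[root_idx]
    ok, under = is_connected_cover(nodes, base)
    if not ok:
        raise AssertionError("greedy produced an invalid cover")  # pragma: no cover
    dist = base.distances_from(root)
    radius = max(dist[v] for v in nodes)
    return DPResult(nodes=nodes, root=root, radius=radius, k=base.k, l=base.l,
                    outliers=under)


def expanding_greedy(inst: CoverInstance, root: Optional[str] = None,
                     allowed: Optional[Iterable[str]] = None) -> Optional[DPResult]:
    """Greedy expansion for MCC(k,l); returns None if the frontier exhausts.

    Starting from ``root`` (or, when None, from the unconstrained best first
    pick), repeatedly add the node adjacent to the partial cover that newly
    covers the most not-yet-k-covered cases; a candidate's contribution to a
    case counts only while that case's coverage is below k. Ties are broken
    by the number of distinct cases covered by the candidate's neighbors,
    then lexicographically. Stops when at most l cases remain under-covered.
    """
    if allowed is None:
        allowed_idx = set(range(len(inst.nodes)))
    else:
        allowed_idx = {inst.index(v) for v in allowed}
    root_idx: Optional[int] = None
    if root is not None:
        root_idx = inst.index(root)
        if root_idx not in allowed_idx:
            raise ValueError(f"root {root!r} not in the allowed node set")
    picked = _greedy_indices(inst, root_idx, allowed_idx)
    if picked is None:
        return None
    return _finish(picked, inst, picked[0])


def expanding_greedy_2phase(inst: CoverInstance, root: Optional[str] = None,
                            allowed: Optional[Iterable[str]] = None
                            ) -> Optional[DPResult]:
    """Two-pass greedy: identify outliers first, then re-solve without them.

    The single-pass greedy only reveals which l cases end up as outliers when
    it halts, so it may spend nodes covering cases that are then discarded.
    Pass 1 runs the plain greedy; its l least-covered cases (ties broken
    lexicographically) are removed from the universe and pass 2 re-runs with
    l = 0. Both results are cleaned up and the smaller is returned (pass 1 on
    ties), so the two-phase result is never worse than the single-phase one.
    """
    raw1 = expanding_greedy(inst, root, allowed)
    if raw1 is None:
        return None
    if inst.l == 0:
        return cleanup(raw1, inst)
    # outliers are read off the raw pass-1 cover, before clean-up
    counts = coverage_counts(raw1.nodes, inst)
    order = sorted(inst.universe, key=lambda u: (counts[u], u))
    O = order[: inst.l]
    r1 = cleanup(raw1, inst)
    kept = [u for u in inst.universe if u not in set(O)]
    inst2 = inst.restrict_universe(kept, l=0)
    try:
        r2 = expanding_greedy(inst2, root, allowed)
    except ValueError:
        r2 = None
    if r2 is None:
        return r1
    # re-express run 2 against the original instance (its outliers are in O)
    ok, under = is_connected_cover(r2.nodes, inst)
    if not ok:  # pragma: no cover - cannot happen: under <= O, |O| = l
        return r1
    dist = inst.distances_from(r2.root)
    r2 = DPResult(nodes=r2.nodes, root=r2.root,
                  radius=max(dist[v] for v in r2.nodes),
                  k=inst.k, l=inst.l, outliers=under)
    r2 = cleanup(r2, inst)
    return r2 if r2.size < r1.size else r1


# ---------------------------------------------------------------------------
# clean-up
# ---------------------------------------------------------------------------


def cleanup(dp: DPResult, inst: CoverInstance) -> DPResult:
    """Iteratively strip nodes needed neither for coverage nor connectivity.

    Scans nodes in lexicographic order, removing any node (never the root)
    whose removal keeps the induced subgraph connected and the (k,l)-cover
    condition satisfied; repeats until a full pass removes nothing. The
    result is a valid CC(k,l) no larger than the input; the operation is
    idempotent.
    """
    ok, _ = is_connected_cover(dp.nodes, inst)
    if not ok:
        raise ValueError("cleanup requires a valid connected (k,l)-cover")
    k, l = inst.k, inst.l
    C = {inst.index(v) for v in dp.nodes}
    root_idx = inst.index(dp.root)
    counts = [0] * inst.n_cases
    for v in C:
        m = inst.masks[v]
        while m:
            low = m & -m
            counts[low.bit_length() - 1] += 1
            m ^= low
    n_under = sum(1 for c in counts if c < k)

    changed = True
    while changed:
        changed = False
        for v in sorted(C):
            if v == root_idx or len(C) == 1:
                continue
            # coverage after removal
            m = inst.masks[v]
            delta_under = 0
            mm = m
            while mm:
                low = mm & -mm
                if counts[low.bit_length() - 1] == k:
                    delta_under += 1
                mm ^= low
            if n_under + delta_under > l:
                continue
            rest = C - {v}
            if not _induced_connected(rest, inst):
                continue
            C = rest
            mm = m
            while mm:
                low = mm & -mm
                counts[low.bit_length() - 1] -= 1
                mm ^= low
            n_under += delta_under
            changed = True
    nodes = frozenset(inst.nodes[i] for i in C)
    ok, under = is_connected_cover(nodes, inst)
    assert ok
    dist = inst.distances_from(dp.root)
    return DPResult(nodes=nodes, root=dp.root,
                    radius=max(dist[v] for v in nodes), k=k, l=l,
                    outliers=under, p_value=dp.p_value, z_score=dp.z_score,
                    null_sizes=dp.null_sizes)
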