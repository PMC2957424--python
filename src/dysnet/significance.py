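"""Empirical significance of module size and selection of the k parameter.

The null model shuffles gene identities over the fixed network topology:
cover sets are reattached to nodes by a uniform random permutation, which
preserves the degree sequence, |V|, |E| and the multiset of cover sets, and
destroys only the association between dysregulation and network position.
The empirical p-value of a real module of size s is the add-one-corrected
fraction of shuffled networks whose smallest module is of equal or smaller
size. k is chosen over a grid as the value with the most significant
empirical p; ties fall to the z-score of the real size against a normal fit
of the null sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cover import CoverInstance, apply_hub_hiding
from .solver import smallest_dp_size

__all__ = [
    "PermutationNull",
    "KSelection",
    "shuffle_gene_labels",
    "empirical_pvalue",
    "build_null",
    "select_k",
    "overlap_pvalue",
]


@dataclass
class PermutationNull:
    """Smallest-module sizes over label-shuffled networks for one k.

    ``sizes`` holds one entry per permutation; None marks a permutation in
    which no connected (k,l)-cover exists (treated as larger than any real
    size: an infeasible null network is evidence for the real signal).
    """

    k: int
    sizes: list[Optional[int]]
    n_permutations: int
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.sizes) != self.n_permutations:
            raise ValueError("sizes length must equal n_permutations")

    @property
    def finite_sizes(self) -> np.ndarray:
        return np.array([s for s in self.sizes if s is not None], dtype=float)

    def mean_sd(self) -> tuple[Optional[float], Optional[float]]:
        f = self.finite_sizes
        if len(f) < 2:
            return (float(f[0]) if len(f) else None), None
        return float(f.mean()), float(f.std(ddof=1))


@dataclass
class KSelection:
    """Per-k real size, empirical p and z-score, plus the chosen k."""

    table: dict[int, dict]
    chosen_k: int

    @property
    def chosen(self) -> dict:
        return self.table[self.chosen_k]


def shuffle_gene_labels(inst: CoverInstance, seed=None) -> CoverInstance:
    """Return an instance with cover sets permuted over network positions.

    ``seed`` may be an int, a Generator, or a pre-drawn permutation array of
    length |V| (indices into the sorted node list).
    """
    if isinstance(seed, np.ndarray):
        perm = seed
    else:
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        perm = rng.permutation(len(inst.nodes))
    new_sets = {
        inst.nodes[i]: inst.cover_sets[inst.nodes[int(p)]]
        for i, p in enumerate(perm)
    }
    return inst.with_cover_sets(new_sets)


def empirical_pvalue(real_size: int, null: PermutationNull) -> float:
    """Add-one permutation p-value: (#{null <= real} + 1) / (n + 1).

    Infeasible permutations never count as smaller-or-equal. The pseudo-count
    keeps the p-value strictly positive (floor 1/(n+1)).
    """
    hits = sum(1 for s in null.sizes if s is not None and s <= real_size)
    return (hits + 1) / (null.n_permutations + 1)


def _solve_permuted(inst: CoverInstance, perm: np.ndarray,
                    hub_degree: int, hub_quantile: float,
                    use_two_phase: bool) -> Optional[int]:
    shuffled = shuffle_gene_labels(inst, perm)
    # hub hiding is part of the pipeline, so the null traverses it too
    shuffled = apply_hub_hiding(shuffled, hub_degree, hub_quantile)
    return smallest_dp_size(shuffled, use_two_phase=use_two_phase)


def build_null(inst: CoverInstance, n_permutations: int = 200,
               seed: Optional[int] = 0, *, hub_degree: int = 100,
               hub_quantile: float = 0.75, use_two_phase: bool = True,
               permutations: Optional[Sequence[np.ndarray]] = None
               ) -> PermutationNull:
    """Distribution of smallest-module sizes over label-shuffled networks.

    ``inst`` must be the pre-hub-hiding instance: hiding is re-applied to
    every shuffled network (neighborhood scores change under relabeling).
    """
    if permutations is None:
        rng = np.random.default_rng(seed)
        permutations = [rng.permutation(len(inst.nodes)) for _ in range(n_permutations)]
    sizes = [
        _solve_permuted(inst, p, hub_degree, hub_quantile, use_two_phase)
        for p in permutations
    ]
    return PermutationNull(inst.k, sizes, len(sizes), seed)


def _zscore(real_size: int, null: PermutationNull) -> Optional[float]:
    mean, sd = null.mean_sd()
    if mean is None or sd is None or sd == 0:
        return None
    return (real_size - mean) / sd


def select_k(make_instance, k_grid: Sequence[int], n_permutations: int = 200,
             seed: int = 0, *, l: Optional[int] = None, hub_degree: int = 100,
             hub_quantile: float = 0.75, use_two_phase: bool = True) -> KSelection:
    """Scan k over a grid and pick the most significant module size.

    ``make_instance(k)`` must return the pre-hub-hiding CoverInstance for
    that k. The same permutation stream (drawn once from ``seed``) is reused
    across the grid for variance reduction. For each k the real network is
    solved, the permutation null built, and p / z computed; the chosen k
    minimizes p, with ties resolved by the most negative z (ks with an
    undefined z lose ties), then by smaller k.
    """
    k_grid = list(k_grid)
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    permutations = None
    table: dict[int, dict] = {}
    for k in k_grid:
        inst = make_instance(k)
        if permutations is None:
            rng = np.random.default_rng(seed)
            permutations = [rng.permutation(len(inst.nodes))
                            for _ in range(n_permutations)]
        hidden = apply_hub_hiding(inst, hub_degree, hub_quantile)
        real = smallest_dp_size(hidden, use_two_phase=use_two_phase)
        if real is None:
            table[k] = {"size": None, "p": None, "z": None,
                        "null_mean": None, "null_sd": None}
            continue
        null = build_null(inst, n_permutations, seed,
                          hub_degree=hub_degree, hub_quantile=hub_quantile,
                          use_two_phase=use_two_phase, permutations=permutations)
        p = empirical_pvalue(real, null)
        z = _zscore(real, null)
        mean, sd = null.mean_sd()
        table[k] = {"size": real, "p": p, "z": z,
                    "null_mean": mean, "null_sd": sd,
                    "null_sizes": list(null.sizes)}
    feasible = [k for k in k_grid if table[k]["p"] is not None]
    if not feasible:
        raise ValueError("no k in the grid admits a module on the real network")

    def key(k: int):
        row = table[k]
        z = row["z"]
        return (row["p"], 0 if z is not None else 1,
                z if z is not None else 0.0, k)

    chosen = min(feasible, key=key)
    return KSelection(table, chosen)


def overlap_pvalue(module_genes, reference_set, background_size: int) -> float:
    """Upper-tail hypergeometric p-value of the module/reference overlap.

    With a background of M genes containing a reference set of size K, the
    probability of drawing at least the observed overlap in a module-sized
    sample without replacement.
    """
    module = set(module_genes)
    reference = set(reference_set)
    M = int(background_size)
    if M < len(module) or M < len(reference):
        raise ValueError("background smaller than module or reference set")
    observed = len(module & reference)
    return float(stats.hypergeom.sf(observed - 1, M, len(reference), len(module)))
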