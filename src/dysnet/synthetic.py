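"""Synthetic networks and case/control studies with planted modules.

The generator emulates the data model the detector targets: a scale-free
protein-interaction-like network, control samples drawn from a per-gene
standard normal on the log2 scale, and a planted connected subnetwork in
which each non-outlier case has a random subset of the planted genes shifted
by an effect of delta control-sds. Because the affected genes differ from
case to case, no single gene need be differentially expressed overall — the
signal is only visible as a concentration of dysregulation events in one
network neighborhood, which is exactly the planted structure a connected
(k,l)-cover search should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np

from .io import CASE, CONTROL, ExpressionStudy

__all__ = [
    "PlantedInstance",
    "generate_network",
    "plant_dp",
    "recovery_metrics",
]

#: Background entries are sporadically shifted at this rate by default,
#: mimicking the null leakage of a p<0.05 calling threshold.
DEFAULT_FP_RATE = 0.05


@dataclass
class PlantedInstance:
    """A generated network + study with known planted truth."""

    network: nx.Graph
    study: ExpressionStudy
    planted_nodes: frozenset[str]
    outlier_cases: frozenset[str]
    k: int
    params: dict = field(default_factory=dict)

    def truth_dict(self) -> dict:
        return {
            "planted_nodes": sorted(self.planted_nodes),
            "outlier_cases": sorted(self.outlier_cases),
            "k": self.k,
            "params": self.params,
        }


def generate_network(n_nodes: int, model: str = "ba", seed: int = 0,
                     *, m: int = 2, p: float = 0.05) -> nx.Graph:
    """Generate a connected simple network.

    ``model="ba"`` grows a preferential-attachment graph (m edges per new
    node), giving the heavy-tailed degree distribution typical of protein
    interaction networks; ``model="er"`` draws an Erdos-Renyi G(n, p), keeps
    the largest component and re-grows to n_nodes by attaching each missing
    node to a uniformly random existing node. Node names are ``g0001``-style;
    the result is reproducible from the seed.
    """
    if n_nodes < 3:
        raise ValueError("n_nodes must be >= 3")
    rng = np.random.default_rng(seed)
    if model == "ba":
        if not 1 <= m < n_nodes:
            raise ValueError("need 1 <= m < n_nodes")
        g = nx.barabasi_albert_graph(n_nodes, m, seed=int(rng.integers(2**31)))
    elif model == "er":
        if not 0 < p <= 1:
            raise ValueError("need 0 < p <= 1")
        g = nx.gnp_random_graph(n_nodes, p, seed=int(rng.integers(2**31)))
        comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), sorted(c)))
        g = g.subgraph(comps[0]).copy()
        present = sorted(g.nodes)
        missing = [v for v in range(n_nodes) if v not in set(present)]
        for v in missing:
            anchor = int(rng.choice(sorted(g.nodes)))
            g.add_edge(v, anchor)
    else:
        raise ValueError(f"unknown network model {model!r}")
    width = len(str(n_nodes))
    mapping = {v: f"g{i + 1:0{width}d}" for i, v in enumerate(sorted(g.nodes))}
    return nx.relabel_nodes(g, mapping)


def _grow_connected_subset(g: nx.Graph, size: int, rng: np.random.Generator) -> set[str]:
    """Randomized BFS growth of a connected node set (small radius by design)."""
    nodes = sorted(g.nodes)
    root = nodes[int(rng.integers(len(nodes)))]
    chosen = {root}
    frontier = sorted(g.neighbors(root))
    while len(chosen) < size:
        if not frontier:
            raise ValueError(f"no connected subgraph of size {size} from {root}")
        v = frontier.pop(int(rng.integers(len(frontier))))
        if v in chosen:
            continue
        chosen.add(v)
        for w in sorted(g.neighbors(v)):
            if w not in chosen:
                frontier.append(w)
    return chosen


def plant_dp(network: nx.Graph, n_cases: int, n_controls: int, k: int,
             outlier_cases: int | Iterable[str] = 0, delta: float = 4.0,
             per_case_active: Optional[int] = None, seed: int = 0,
             *, planted_size: int = 15, direction: str = "UP",
             fp_rate: float = DEFAULT_FP_RATE,
             noise_sd: float = 1.0) -> PlantedInstance:
    """Plant a connected dysregulated module into a synthetic study.

    Controls are N(0, noise_sd) per gene on the log2 scale. A connected set
    of ``planted_size`` genes is grown by randomized BFS; in every
    non-outlier case a fresh random subset of ``per_case_active`` (default k)
    planted genes is shifted by +delta (UP; -delta for DOWN; random sign for
    DIFF). Outlier cases receive no planted shift. Background gene/case
    entries are shifted independently with probability ``fp_rate``.
    """
    if per_case_active is None:
        per_case_active = k
    if per_case_active < k:
        raise ValueError("per_case_active must be >= k")
    if planted_size > network.number_of_nodes():
        raise ValueError("planted size exceeds network size")
    if per_case_active > planted_size:
        raise ValueError("per_case_active must be <= planted_size")
    if direction not in ("UP", "DOWN", "DIFF"):
        raise ValueError(f"unknown direction {direction!r}")
    if n_controls < 2 or n_cases < 1:
        raise ValueError("need >= 2 controls and >= 1 case")

    rng = np.random.default_rng(seed)
    genes = sorted(network.nodes)
    gi = {g: i for i, g in enumerate(genes)}
    cases = [f"case{j + 1:03d}" for j in range(n_cases)]
    controls = [f"ctrl{j + 1:03d}" for j in range(n_controls)]
    samples = cases + controls
    labels = {s: CASE for s in cases} | {s: CONTROL for s in controls}

    if isinstance(outlier_cases, int):
        out_idx = sorted(rng.choice(n_cases, size=outlier_cases, replace=False).tolist()) \
            if outlier_cases else []
        outliers = {cases[j] for j in out_idx}
    else:
        outliers = set(outlier_cases)
        if not outliers <= set(cases):
            raise ValueError("explicit outlier_cases must be generated case ids")

    planted = _grow_connected_subset(network, planted_size, rng)
    planted_sorted = sorted(planted)

    values = rng.normal(0.0, noise_sd, size=(len(genes), len(samples)))

    def shift_sign() -> float:
        if direction == "UP":
            return delta
        if direction == "DOWN":
            return -delta
        return delta if rng.random() < 0.5 else -delta

    for j, case in enumerate(cases):
        if case not in outliers:
            active = rng.choice(planted_sorted, size=per_case_active, replace=False)
            for g in active:
                values[gi[g], j] += shift_sign()
        # sporadic background dysregulation
        if fp_rate > 0:
            background = [g for g in genes if g not in planted]
            flips = rng.random(len(background)) < fp_rate
            for g, f in zip(background, flips):
                if f:
                    values[gi[g], j] += shift_sign()

    study = ExpressionStudy(genes, samples, values, labels)
    params = {
        "n_cases": n_cases, "n_controls": n_controls, "k": k,
        "delta": delta, "per_case_active": per_case_active,
        "planted_size": planted_size, "direction": direction,
        "fp_rate": fp_rate, "noise_sd": noise_sd, "seed": seed,
    }
    return PlantedInstance(network, study, frozenset(planted),
                           frozenset(outliers), k, params)


def recovery_metrics(result_nodes: Iterable[str], truth_nodes: Iterable[str]
                     ) -> tuple[float, float, float]:
    """Precision, recall and Jaccard index of recovered vs planted nodes."""
    result = set(result_nodes)
    truth = set(truth_nodes)
    inter = len(result & truth)
    union = len(result | truth)
    precision = inter / len(result) if result else 0.0
    recall = inter / len(truth) if truth else 0.0
    jaccard = inter / union if union else 0.0
    return precision, recall, jaccard
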