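"""Model/results interface wrapping the full analysis pipeline.

Follows the fit/results convention of statistical modelling packages: a
:class:`DysregulatedPathwayModel` is constructed from the data (network +
labeled expression study + configuration) and ``fit()`` runs dysregulation
calling, hub hiding, the minimal-radius cover search and — unless disabled —
permutation significance and k selection, returning a
:class:`DysregulatedPathwayResults` with the module(s), their empirical
p-value and z-score, the per-k selection table and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx

from .config import RunConfig
from .cover import DPResult, apply_hub_hiding, build_instance
from .dysregulation import DysregulationMatrix, call_dysregulation
from .io import ExpressionStudy, collapse_probes, read_expression, read_network, read_probe_map
from .significance import KSelection, build_null, empirical_pvalue, select_k, _zscore
from .solver import solve

__all__ = ["DysregulatedPathwayModel", "DysregulatedPathwayResults"]


class DysregulatedPathwayModel:
    """Minimal connected dysregulated-subnetwork model for a case/control study.

    Parameters
    ----------
    network
        Undirected protein-interaction network over gene identifiers.
    study
        Log2-scale expression matrix with case/control sample labels.
    config
        Run parameters; keyword overrides are applied on top (e.g.
        ``direction="DOWN"``, ``k_grid=[5, 10]``).

    Examples
    --------
    >>> model = DysregulatedPathwayModel(network, study, direction="UP")
    >>> res = model.fit(k=10, seed=1)
    >>> print(res.summary())
    """

    def __init__(self, network: nx.Graph, study: ExpressionStudy,
                 config: Optional[RunConfig] = None, **overrides):
        if config is None:
            config = RunConfig(**overrides)
        elif overrides:
            config = RunConfig(**{**config.to_dict(), **overrides})
        self.network = network
        self.study = study
        self.config = config
        self._matrix: Optional[DysregulationMatrix] = None

    @classmethod
    def from_files(cls, network_path, matrix_path, labels_path,
                   probe_map_path=None, config: Optional[RunConfig] = None,
                   **overrides) -> "DysregulatedPathwayModel":
        if config is None:
            config = RunConfig(**overrides)
        elif overrides:
            config = RunConfig(**{**config.to_dict(), **overrides})
        network = read_network(network_path)
        study = read_expression(
            matrix_path, labels_path,
            log2_transform=config.log2_transform,
            allow_duplicate_genes=probe_map_path is not None,
        )
        if probe_map_path is not None:
            study = collapse_probes(study, read_probe_map(probe_map_path))
        return cls(network, study, config)

    @property
    def dysregulation(self) -> DysregulationMatrix:
        """Binary genes x cases call matrix (computed once, cached)."""
        if self._matrix is None:
            self._matrix = call_dysregulation(self.study, self.config)
        return self._matrix

    @property
    def n_cases(self) -> int:
        return len(self.study.case_samples)

    @property
    def outlier_count(self) -> int:
        return self.config.outlier_count(self.n_cases)

    def instance(self, k: int):
        """Pre-hub-hiding cover instance at a given k."""
        return build_instance(self.network, self.dysregulation, k,
                              self.outlier_count)

    def fit(self, k: Optional[int] = None, *,
            n_permutations: Optional[int] = None,
            seed: Optional[int] = None) -> "DysregulatedPathwayResults":
        """Run the pipeline and return results.

        With ``k`` given, solves at that single k; otherwise scans
        ``config.k_grid`` and selects the most significant k. Set
        ``n_permutations=0`` to skip the permutation null (no p/z, requires
        a fixed k).
        """
        cfg = self.config
        n_perm = cfg.n_permutations if n_permutations is None else n_permutations
        seed = cfg.seed if seed is None else seed
        selection: Optional[KSelection] = None

        if k is None:
            if n_perm <= 0:
                raise ValueError("k selection needs n_permutations > 0")
            selection = select_k(
                self.instance, cfg.k_grid, n_permutations=n_perm, seed=seed,
                hub_degree=cfg.hub_degree, hub_quantile=cfg.hub_quantile,
                use_two_phase=cfg.use_two_phase,
            )
            k = selection.chosen_k

        inst = self.instance(k)
        hidden = apply_hub_hiding(inst, cfg.hub_degree, cfg.hub_quantile)
        modules = solve(hidden, use_two_phase=cfg.use_two_phase)

        p = z = None
        null_sizes = None
        if selection is not None:
            row = selection.chosen
            p, z = row["p"], row["z"]
            null_sizes = row.get("null_sizes")
        elif n_perm > 0:
            null = build_null(inst, n_perm, seed,
                              hub_degree=cfg.hub_degree,
                              hub_quantile=cfg.hub_quantile,
                              use_two_phase=cfg.use_two_phase)
            p = empirical_pvalue(modules[0].size, null)
            z = _zscore(modules[0].size, null)
            null_sizes = list(null.sizes)
        modules = [
            DPResult(nodes=m.nodes, root=m.root, radius=m.radius, k=m.k,
                     l=m.l, outliers=m.outliers, p_value=p, z_score=z,
                     null_sizes=null_sizes)
            for m in modules
        ]
        return DysregulatedPathwayResults(
            model=self, k=k, l=self.outlier_count, modules=modules,
            p_value=p, z_score=z, selection=selection, seed=seed,
        )


@dataclass
class DysregulatedPathwayResults:
    """Fitted results: the minimal module(s) and their significance."""

    model: DysregulatedPathwayModel
    k: int
    l: int
    modules: list[DPResult]
    p_value: Optional[float]
    z_score: Optional[float]
    selection: Optional[KSelection] = None
    seed: Optional[int] = None

    @property
    def best(self) -> DPResult:
        """The first minimum-size module (lexicographically smallest root)."""
        return self.modules[0]

    @property
    def nodes(self) -> frozenset[str]:
        return self.best.nodes

    @property
    def size(self) -> int:
        return self.best.size

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Dysregulated subnetwork search",
            "=" * 46,
            f"direction:        {cfg.direction}",
            f"cases/controls:   {len(self.model.study.case_samples)}"
            f" / {len(self.model.study.control_samples)}",
            f"network:          {self.model.network.number_of_nodes()} nodes,"
            f" {self.model.network.number_of_edges()} edges",
            f"k (per-case):     {self.k}",
            f"l (outliers):     {self.l}",
            f"module size:      {self.size}",
            f"module radius:    {self.best.radius} (root {self.best.root})",
            f"tying modules:    {len(self.modules)}",
        ]
        if self.p_value is not None:
            lines.append(f"empirical p:      {self.p_value:.4g}")
        if self.z_score is not None:
            lines.append(f"z-score:          {self.z_score:.3f}")
        if self.selection is not None:
            lines.append("")
            lines.append("k-selection (size / p / z):")
            for kk in sorted(self.selection.table):
                row = self.selection.table[kk]
                mark = " <- chosen" if kk == self.selection.chosen_k else ""
                if row["p"] is None:
                    lines.append(f"  k={kk:<3d} infeasible{mark}")
                else:
                    zs = f"{row['z']:.2f}" if row["z"] is not None else "NA"
                    lines.append(
                        f"  k={kk:<3d} {row['size']:>4d} / {row['p']:.4g} / {zs}{mark}"
                    )
        lines.append("")
        lines.append("module genes: " + " ".join(sorted(self.nodes)))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "l": self.l,
            "p_value": self.p_value,
            "z_score": self.z_score,
            "seed": self.seed,
            "modules": [m.to_dict() for m in self.modules],
            "selection": (
                {str(kk): {a: b for a, b in row.items() if a != "null_sizes"}
                 for kk, row in self.selection.table.items()}
                if self.selection else None
            ),
        }
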