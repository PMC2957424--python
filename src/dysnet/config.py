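"""Run configuration for a dysregulated-subnetwork analysis."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

VALID_DIRECTIONS = ("UP", "DOWN", "DIFF")

#: Default grid of per-case dysregulation thresholds explored when k is not
#: fixed by the user.
DEFAULT_K_GRID = (5, 10, 15, 20, 25, 30)


@dataclass
class RunConfig:
    """Parameters of a full analysis run.

    Parameters
    ----------
    direction
        ``"UP"`` calls genes over-expressed in a case relative to controls,
        ``"DOWN"`` under-expressed, ``"DIFF"`` either.
    p_threshold
        Per-entry normal-model p-value gate for calling dysregulation.
    fold_threshold
        Minimum fold change (raw scale) between a case value and the control
        mean; both gates must pass.
    outlier_fraction
        Fraction of case samples allowed to fall below the k-coverage
        requirement; the outlier count l is ``floor(fraction * n_cases)``.
    k_grid
        Candidate values of k (dysregulated genes required per case) scanned
        during parameter selection.
    n_permutations
        Number of label-shuffled networks used for the empirical null.
    hub_degree
        Nodes of degree strictly greater than this are hub-hiding candidates.
    hub_quantile
        A hub is kept only if its neighborhood dysregulation score reaches
        this quantile of all neighborhood scores.
    log2_transform
        Apply ``log2(x + 1)`` to the expression matrix on load (for raw
        intensities); values are otherwise assumed already log2-scale.
    seed
        Seed for every stochastic step (permutations, synthetic data).
    """

    direction: str = "UP"
    p_threshold: float = 0.05
    fold_threshold: float = 1.4
    outlier_fraction: float = 0.20
    k_grid: Sequence[int] = field(default_factory=lambda: list(DEFAULT_K_GRID))
    n_permutations: int = 200
    hub_degree: int = 100
    hub_quantile: float = 0.75
    log2_transform: bool = False
    use_two_phase: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.direction not in VALID_DIRECTIONS:
            raise ValueError(
                f"direction must be one of {VALID_DIRECTIONS}, got {self.direction!r}"
            )
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must lie strictly between 0 and 1")
        if not self.fold_threshold > 1.0:
            raise ValueError("fold_threshold must exceed 1")
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise ValueError("outlier_fraction must lie in [0, 1)")
        self.k_grid = [int(k) for k in self.k_grid]
        if not self.k_grid or any(k < 1 for k in self.k_grid):
            raise ValueError("k_grid must be non-empty with positive entries")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")
        if self.hub_degree < 1:
            raise ValueError("hub_degree must be positive")
        if not 0.0 <= self.hub_quantile <= 1.0:
            raise ValueError("hub_quantile must lie in [0, 1]")

    def outlier_count(self, n_cases: int) -> int:
        """Number of outlier cases l = floor(outlier_fraction * n_cases)."""
        import math

        return int(math.floor(self.outlier_fraction * n_cases))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)
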