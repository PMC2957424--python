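"""Calling per-case gene dysregulation against a control-fitted normal model.

For each gene, the mean and standard deviation of its log2 expression across
control samples define a normal null. A gene is called dysregulated in a case
sample when (a) the normal-tail p-value of the case value beats the p
threshold for the chosen direction, and (b) the anti-logged fold change
between the case value and the control mean passes the fold threshold. Both
gates must pass; this mirrors the usual practice of combining a statistical
and an effect-size criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .io import ExpressionStudy

__all__ = [
    "ControlModel",
    "DysregulationMatrix",
    "fit_control_model",
    "case_pvalue",
    "call_dysregulation",
    "matrix_summary",
]


@dataclass
class ControlModel:
    """Per-gene normal model of control expression (mean, sample sd, n)."""

    genes: list[str]
    mean: np.ndarray
    sd: np.ndarray
    n_controls: int

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ValueError("need at least 2 control samples")
        if np.any(self.sd < 0):
            raise ValueError("negative standard deviation")

    @property
    def zero_sd_genes(self) -> list[str]:
        """Genes with constant control expression (normal model undefined)."""
        return [g for g, s in zip(self.genes, self.sd) if s == 0.0]

    def index(self, gene: str) -> int:
        return self.genes.index(gene)


@dataclass
class DysregulationMatrix:
    """Binary genes x cases incidence of dysregulation calls.

    Row v is the cover set S_v: the case samples in which gene v is called
    dysregulated. Equivalently the edge set of the bipartite gene/case graph.
    """

    genes: list[str]
    cases: list[str]
    incidence: np.ndarray
    direction: str

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=bool)
        if self.incidence.shape != (len(self.genes), len(self.cases)):
            raise ValueError("incidence shape mismatch")

    def cover_sets(self) -> dict[str, frozenset[str]]:
        """Map gene -> S_v (set of case ids in which it is dysregulated)."""
        cases = np.asarray(self.cases, dtype=object)
        return {
            g: frozenset(cases[self.incidence[i]])
            for i, g in enumerate(self.genes)
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.incidence.astype(int), index=self.genes, columns=self.cases
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def fit_control_model(study: ExpressionStudy) -> ControlModel:
    """Fit the per-gene control normal (mean, sd with ddof=1)."""
    ctrl = study.control_values
    if ctrl.shape[1] < 2:
        raise ValueError("need at least 2 control samples to fit the model")
    mean = ctrl.mean(axis=1)
    sd = ctrl.std(axis=1, ddof=1)
    return ControlModel(list(study.genes), mean, sd, ctrl.shape[1])


def case_pvalue(model: ControlModel, gene: str, case_value: float,
                direction: str) -> float:
    """Normal-tail p-value of one case value under a gene's control model.

    UP: upper tail; DOWN: lower tail; DIFF: two-sided (2 * min tail, capped
    at 1). Requires sd > 0.
    """
    i = model.index(gene)
    mu, sigma = model.mean[i], model.sd[i]
    if sigma <= 0:
        raise ValueError(f"gene {gene!r} has zero control sd; model undefined")
    z = (case_value - mu) / sigma
    upper = stats.norm.sf(z)
    lower = stats.norm.cdf(z)
    if direction == "UP":
        return float(upper)
    if direction == "DOWN":
        return float(lower)
    if direction == "DIFF":
        return float(min(1.0, 2.0 * min(upper, lower)))
    raise ValueError(f"unknown direction {direction!r}")


def call_dysregulation(study: ExpressionStudy, config: RunConfig) -> DysregulationMatrix:
    """Produce the binary genes x cases dysregulation matrix.

    Entry (v, u) is 1 iff the directional p-value of case u's value under
    gene v's control normal is below ``config.p_threshold`` AND the fold
    change ``2**(value - control_mean)`` passes ``config.fold_threshold``
    (>= threshold for UP, <= 1/threshold for DOWN, either for DIFF). Genes
    with zero control sd are never called.
    """
    model = fit_control_model(study)
    cases = study.case_samples
    if not cases:
        raise ValueError("study has no case samples")
    vals = study.case_values  # genes x cases
    mu = model.mean[:, None]
    sd = model.sd[:, None]
    ok = sd > 0
    z = np.zeros_like(vals)
    np.divide(vals - mu, sd, out=z, where=ok)

    upper = stats.norm.sf(z)
    lower = stats.norm.cdf(z)
    log2_fold = vals - mu  # log2 ratio case / control mean
    log2_thr = np.log2(config.fold_threshold)

    up_call = (upper < config.p_threshold) & (log2_fold >= log2_thr)
    down_call = (lower < config.p_threshold) & (log2_fold <= -log2_thr)
    if config.direction == "UP":
        calls = up_call
    elif config.direction == "DOWN":
        calls = down_call
    else:  # DIFF: two-sided p plus a fold deviation in either direction
        two_sided = np.minimum(1.0, 2.0 * np.minimum(upper, lower))
        calls = (two_sided < config.p_threshold) & (np.abs(log2_fold) >= log2_thr)
    calls &= ok
    return DysregulationMatrix(list(study.genes), list(cases), calls,
                               config.direction)


def matrix_summary(m: DysregulationMatrix) -> dict:
    """Row sums |S_v|, column sums per case, and total call count."""
    inc = m.incidence.astype(int)
    summary = {
        "per_gene": dict(zip(m.genes, inc.sum(axis=1).tolist())),
        "per_case": dict(zip(m.cases, inc.sum(axis=0).tolist())),
        "total": int(inc.sum()),
    }
    return summary
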