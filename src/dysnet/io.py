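"""Reading and writing networks, expression studies, gene sets and results.

File dialects
-------------
* network: two-column whitespace/tab edge list ('#' comments allowed) or SIF
  (``node relation node``);
* expression matrix: TSV, gene rows x sample columns, header row of sample ids;
* labels: two-column TSV mapping sample id -> ``case`` / ``control``;
* probe map: two-column TSV mapping probe id -> gene id;
* gene sets: newline-delimited gene identifiers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("dysnet")

CASE = "case"
CONTROL = "control"


class ParseError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# expression study container
# ---------------------------------------------------------------------------


@dataclass
class ExpressionStudy:
    """A gene x sample log-expression matrix with case/control labels."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    labels: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        missing = [s for s in self.samples if s not in self.labels]
        if missing:
            raise ValueError(f"samples without a label: {missing[:5]}")
        bad = {s: t for s, t in self.labels.items() if t not in (CASE, CONTROL)}
        if bad:
            raise ValueError(f"labels must be '{CASE}' or '{CONTROL}': {bad}")
        if len(self.case_samples) < 1:
            raise ValueError("need at least 1 case sample")
        if len(self.control_samples) < 2:
            raise ValueError("need at least 2 control samples")

    @property
    def case_samples(self) -> list[str]:
        return [s for s in self.samples if self.labels[s] == CASE]

    @property
    def control_samples(self) -> list[str]:
        return [s for s in self.samples if self.labels[s] == CONTROL]

    @property
    def case_values(self) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples) if self.labels[s] == CASE]
        return self.values[:, idx]

    @property
    def control_values(self) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples) if self.labels[s] == CONTROL]
        return self.values[:, idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def has_duplicate_genes(self) -> bool:
        return len(set(self.genes)) != len(self.genes)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_network(path: str | Path, format: str | None = None) -> nx.Graph:
    """Read an undirected simple gene network from an edge-list or SIF file.

    Self-loops are dropped with a warning; duplicate edges are merged. The
    format is inferred from the extension (``.sif``) unless given explicitly.
    """
    path = Path(path)
    if format is None:
        format = "sif" if path.suffix.lower() == ".sif" else "edge-list"
    if format not in ("edge-list", "sif"):
        raise ValueError(f"unknown network format {format!r}")

    g = nx.Graph()
    n_self_loops = 0
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if format == "sif":
                if len(fields) < 3:
                    raise ParseError(
                        f"{path}:{lineno}: SIF line needs 'node relation node'"
                    )
                a, b = fields[0], fields[2]
            else:
                if len(fields) != 2:
                    raise ParseError(
                        f"{path}:{lineno}: edge-list line needs exactly 2 columns"
                    )
                a, b = fields
            n_lines += 1
            if a == b:
                n_self_loops += 1
                continue
            g.add_edge(a, b)
    if n_lines == 0:
        raise ParseError(f"{path}: no edges found")
    if n_self_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_self_loops)
    logger.info(
        "%s: read network with %d nodes, %d edges",
        path, g.number_of_nodes(), g.number_of_edges(),
    )
    return g


def write_network(g: nx.Graph, path: str | Path) -> None:
    """Write a network as a two-column edge list (sorted, reproducible)."""
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{a}\t{b}\n")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column sample -> case/control label file."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'sample<TAB>label'")
            sample, tag = fields
            tag = tag.strip().lower()
            if tag not in (CASE, CONTROL):
                raise ParseError(
                    f"{path}:{lineno}: label must be '{CASE}' or '{CONTROL}'"
                )
            if sample in labels and labels[sample] != tag:
                raise ParseError(f"{path}:{lineno}: sample {sample} labeled twice")
            labels[sample] = tag
    if not labels:
        raise ParseError(f"{path}: empty labels file")
    return labels


def read_expression(
    matrix_path: str | Path,
    labels_path: str | Path,
    *,
    log2_transform: bool = False,
    allow_duplicate_genes: bool = False,
) -> ExpressionStudy:
    """Read a TSV expression matrix plus a sample-label file.

    Values are taken as given (assumed log2 scale) unless ``log2_transform``
    is set, in which case ``log2(x + 1)`` is applied. Duplicate gene rows are
    rejected unless ``allow_duplicate_genes`` (a probe map will collapse them).
    """
    matrix_path = Path(matrix_path)
    try:
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{matrix_path}: {exc}") from exc
    if df.empty:
        raise ParseError(f"{matrix_path}: empty expression matrix")
    non_numeric = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(non_numeric):
        col = non_numeric[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise ParseError(f"{matrix_path}: non-numeric value at gene {row!r}, sample {col!r}")
    values = df.to_numpy(dtype=float)
    genes = [str(g) for g in df.index]
    samples = [str(s) for s in df.columns]

    labels = read_labels(labels_path)
    missing = [s for s in samples if s not in labels]
    if missing:
        raise ParseError(f"{labels_path}: no label for sample(s) {missing[:5]}")

    if len(set(genes)) != len(genes) and not allow_duplicate_genes:
        raise ParseError(
            f"{matrix_path}: duplicate gene rows; supply a probe map to collapse them"
        )
    if log2_transform:
        values = np.log2(values + 1.0)
    study = ExpressionStudy(genes, samples, values, {s: labels[s] for s in samples})
    logger.info(
        "%s: %d genes x %d samples (%d case, %d control)",
        matrix_path, len(genes), len(samples),
        len(study.case_samples), len(study.control_samples),
    )
    return study


def write_expression(study: ExpressionStudy, matrix_path: str | Path,
                     labels_path: str | Path | None = None) -> None:
    study.to_frame().to_csv(matrix_path, sep="\t", float_format="%.6g")
    if labels_path is not None:
        with open(labels_path, "w") as fh:
            for s in study.samples:
                fh.write(f"{s}\t{study.labels[s]}\n")


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Read a two-column probe -> gene mapping table."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'probe<TAB>gene'")
            mapping[fields[0]] = fields[1]
    return mapping


def collapse_probes(study: ExpressionStudy, probe_map: Mapping[str, str]) -> ExpressionStudy:
    """Average probe rows mapping to the same gene (arithmetic mean per sample).

    Probes absent from the map are dropped with a warning. Averaging happens
    on the (log-scale) values as stored.
    """
    rows_by_gene: dict[str, list[int]] = {}
    n_dropped = 0
    for i, probe in enumerate(study.genes):
        gene = probe_map.get(probe)
        if gene is None:
            n_dropped += 1
            continue
        rows_by_gene.setdefault(gene, []).append(i)
    if n_dropped:
        logger.warning("collapse_probes: dropped %d unmapped probe row(s)", n_dropped)
    if not rows_by_gene:
        raise ValueError("no probes mapped to genes; empty result")
    genes = sorted(rows_by_gene)
    values = np.vstack([study.values[rows_by_gene[g]].mean(axis=0) for g in genes])
    return ExpressionStudy(genes, list(study.samples), values, dict(study.labels))


def read_gene_set(path: str | Path) -> set[str]:
    """Read a newline-delimited gene list."""
    with open(path) as fh:
        genes = {line.strip() for line in fh if line.strip() and not line.startswith("#")}
    if not genes:
        raise ParseError(f"{path}: empty gene set")
    return genes


# ---------------------------------------------------------------------------
# result output
# ---------------------------------------------------------------------------


def write_result(dp, path: str | Path, format: str = "json",
                 instance=None) -> None:
    """Write a solved dysregulated pathway as TSV, JSON or GML.

    TSV lists each module gene with the number of cases it is dysregulated
    in; GML stores the induced subgraph with a ``root`` node attribute; JSON
    round-trips every field (see :func:`read_result`).
    """
    from .cover import DPResult  # local import: avoid a cycle

    if not isinstance(dp, DPResult):
        raise TypeError("dp must be a DPResult")
    path = Path(path)
    format = format.lower()
    if format == "json":
        with open(path, "w") as fh:
            json.dump(dp.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("gene\tn_cases_covered\n")
            for v in sorted(dp.nodes):
                n_cov = 0
                if instance is not None and v in instance.cover_sets:
                    n_cov = len(instance.cover_sets[v])
                fh.write(f"{v}\t{n_cov}\n")
    elif format == "gml":
        if instance is None:
            raise ValueError("GML output needs the CoverInstance for topology")
        sub = instance.graph.subgraph(dp.nodes).copy()
        for v in sub.nodes:
            sub.nodes[v]["root"] = 1 if v == dp.root else 0
        nx.write_gml(sub, path)
    else:
        raise ValueError(f"unknown result format {format!r}")


def read_result(path: str | Path):
    """Read a JSON result written by :func:`write_result`."""
    from .cover import DPResult

    with open(path) as fh:
        return DPResult.from_dict(json.load(fh))
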