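"""Core containers for time-series regulatory-network analysis.

The pipeline moves between three representations: replicated expression
measurements (genes x time points x replicates), averaged expression
matrices (genes x time points), and a static directed regulatory network
whose nodes are transcription factors (TFs) or target genes (TGs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

TF = "TF"
TG = "TG"
REGULATES = "regulates"
INTERACTS = "interacts"


@dataclass
class ReplicatedExpression:
    """Expression measurements with replicates.

    ``values`` has shape (n_genes, n_timepoints, n_replicates); time stamps
    are in hours and must be strictly increasing.
    """

    values: np.ndarray
    gene_ids: list[str]
    timepoints: np.ndarray
    replicate_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be genes x timepoints x replicates")
        n_genes, n_tp, n_rep = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length mismatch")
        if len(self.timepoints) != n_tp:
            raise ValueError("timepoints length mismatch")
        if n_rep < 1:
            raise ValueError("need at least one replicate")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.isnan(self.values).any():
            raise ValueError("NaN values are not allowed")
        if not self.replicate_labels:
            self.replicate_labels = [f"rep{r + 1}" for r in range(n_rep)]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[2]


@dataclass
class ExpressionMatrix:
    """Averaged expression, genes x time points."""

    values: np.ndarray
    gene_ids: list[str]
    timepoints: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be genes x timepoints")
        if self.values.shape[0] != len(self.gene_ids):
            raise ValueError("gene_ids length mismatch")
        if self.values.shape[1] != len(self.timepoints):
            raise ValueError("timepoints length mismatch")

    def subset(self, gene_ids: list[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(self.values[rows], list(gene_ids), self.timepoints)


class RegulatoryNetwork:
    """Directed regulatory network with node roles TF / TG.

    Edges carry a ``kind`` attribute: ``regulates`` (TF -> TG) or
    ``interacts`` (TF -> TF).  TGs are sinks: they never appear as edge
    sources.
    """

    def __init__(self) -> None:
        self.graph = nx.DiGraph()

    def add_regulation(self, tf: str, tg: str) -> None:
        self._add_node(tf, TF)
        self._add_node(tg, TG)
        self.graph.add_edge(tf, tg, kind=REGULATES)

    def add_interaction(self, tf_a: str, tf_b: str) -> None:
        self._add_node(tf_a, TF)
        self._add_node(tf_b, TF)
        self.graph.add_edge(tf_a, tf_b, kind=INTERACTS)

    def _add_node(self, node: str, role: str) -> None:
        existing = self.graph.nodes.get(node, {}).get("role")
        if existing is None:
            self.graph.add_node(node, role=role)
        elif existing != role and role == TF:
            # regulator wins over target classification
            self.graph.nodes[node]["role"] = TF

    def role(self, node: str) -> str:
        return self.graph.nodes[node]["role"]

    @property
    def tfs(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["role"] == TF)

    @property
    def tgs(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["role"] == TG)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def regulation_edges(self) -> list[tuple[str, str]]:
        return sorted(
            (u, v) for u, v, d in self.graph.edges(data=True) if d["kind"] == REGULATES
        )

    def interaction_edges(self) -> list[tuple[str, str]]:
        return sorted(
            (u, v) for u, v, d in self.graph.edges(data=True) if d["kind"] == INTERACTS
        )

    def targets_of(self, tf: str) -> set[str]:
        return {
            v
            for _, v, d in self.graph.out_edges(tf, data=True)
            if d["kind"] == REGULATES
        }
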