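"""Shared containers and helpers for the pathway-level tests."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

from ..degs import DEGResult, ExpressionDataset
from ..pathways import PathwayGraph

OK = "ok"
NOT_TESTABLE = "not_testable"
DEGENERATE = "degenerate"


@dataclass
class MethodConfig:
    """Knobs shared by every method; defaults follow the benchmark settings
    (alpha = 0.05, DEG threshold 0.05, 1000 permutations)."""

    n_permutations: int = 1000
    alpha: float = 0.05
    deg_theta: float = 0.05
    seed: int | None = None
    # method-specific knobs
    degraph_energy_fraction: float = 0.2
    clipper_shrinkage: bool = True
    clipper_shrinkage_intensity: float | None = None  # None = estimate
    variance_alpha: float = 0.05  # branch threshold of the two-step tests

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def with_seed(self, seed: int | None) -> "MethodConfig":
        return replace(self, seed=seed)


@dataclass
class PathwayResult:
    pathway_id: str
    method: str
    statistic: float = np.nan
    p_value: float | None = None
    n_nodes: int = 0
    n_measured: int = 0
    n_deg: int = 0
    status: str = OK
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status == OK and self.p_value is None:
            raise ValueError("ok result requires a p-value")
        if self.status != OK:
            self.p_value = None

    @property
    def dep(self) -> bool | None:
        return None if self.p_value is None else bool(self.p_value < 0.05)


def permutation_p(null: np.ndarray, observed: float) -> float:
    """(1 + #{null >= observed}) / (1 + N); never exactly zero."""
    null = np.asarray(null, dtype=float)
    return float((1 + np.sum(null >= observed - 1e-12)) / (1 + null.size))


def measured_node_stats(
    graph: PathwayGraph, degs: DEGResult, measured: set[str]
) -> pd.DataFrame:
    """Node-level DEG status and log fold change for the measured nodes.

    Combined complex/family nodes aggregate their members: a node is a DEG if
    any measured member is, and its logFC is the mean over measured members.
    """
    rows = {}
    for node in graph.measured_nodes(measured):
        ms = [m for m in graph.members(node) if m in measured]
        lfc = float(degs.logfc.loc[ms].mean())
        is_deg = any(m in degs.deg_set for m in ms)
        rows[node] = {"logFC": lfc, "deg": is_deg}
    return pd.DataFrame.from_dict(rows, orient="index")


def node_expression(
    data: ExpressionDataset, graph: PathwayGraph, measured: set[str] | None = None
) -> tuple[list[str], np.ndarray]:
    """Node x sample expression; combined nodes average their measured members."""
    if measured is None:
        measured = set(data.genes)
    nodes = list(graph.measured_nodes(measured))
    loc = data.genes.get_indexer
    mat = np.empty((len(nodes), data.X.shape[1]))
    for i, node in enumerate(nodes):
        ms = [m for m in graph.members(node) if m in measured]
        mat[i] = data.X[loc(ms)].mean(axis=0)
    return nodes, mat


def base_result(method: str, graph: PathwayGraph, measured: set[str], n_deg: int = 0):
    """Common bookkeeping fields for a result under construction."""
    return dict(
        pathway_id=graph.pathway_id,
        method=method,
        n_nodes=graph.n_genes,
        n_measured=len(graph.measured_nodes(measured)),
        n_deg=n_deg,
    )
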