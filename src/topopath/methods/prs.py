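"""Pathway regulation score: downstream-DEG-weighted sum of fold changes.

Every differentially expressed node contributes its |log fold change| times a
topology weight ``w = 1 + (number of distinct DEG nodes reachable from it via
directed paths)``.  Significance is competitive: DEG statuses (with their log
fold changes) are re-assigned uniformly over the measured gene universe and
the pathway score recomputed for each permutation.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from ..degs import DEGResult, ExpressionDataset
from ..pathways import PathwayGraph
from .base import (
    NOT_TESTABLE,
    MethodConfig,
    PathwayResult,
    base_result,
)


def _reachability(graph: PathwayGraph, nodes: list[str]) -> np.ndarray:
    """Boolean matrix R[i, j] = node j reachable from node i (i != j)."""
    D = nx.DiGraph()
    D.add_nodes_from(nodes)
    present = set(nodes)
    for e in graph.edges:
        if e.source in present and e.target in present:
            D.add_edge(e.source, e.target)
            if not e.directed:
                D.add_edge(e.target, e.source)
    idx = {g: i for i, g in enumerate(nodes)}
    R = np.zeros((len(nodes), len(nodes)), dtype=bool)
    for g in nodes:
        for d in nx.descendants(D, g):
            R[idx[g], idx[d]] = True
    return R


def prs(
    data: ExpressionDataset,
    graph: PathwayGraph,
    degs: DEGResult,
    cfg: MethodConfig | None = None,
) -> PathwayResult:
    cfg = cfg or MethodConfig()
    measured = set(data.genes)
    common = base_result("prs", graph, measured)
    nodes = list(graph.measured_nodes(measured))
    if not nodes:
        return PathwayResult(**common, status=NOT_TESTABLE)
    if len(degs.deg_set) == 0:
        return PathwayResult(**common, status=NOT_TESTABLE)

    universe = list(data.genes)
    uni_idx = {g: i for i, g in enumerate(universe)}
    member_idx = [
        np.array([uni_idx[m] for m in graph.members(n) if m in uni_idx], dtype=int)
        for n in nodes
    ]
    n_members = np.array([len(mi) for mi in member_idx], dtype=float)

    abs_lfc = np.abs(degs.logfc.to_numpy())
    deg_genes = sorted(degs.deg_set)
    deg_pos = np.array([uni_idx[g] for g in deg_genes], dtype=int)
    deg_vals = abs_lfc[deg_pos]
    n_deg_all = len(deg_genes)

    R = _reachability(graph, nodes)

    def scores(value_by_gene: np.ndarray) -> np.ndarray:
        """Pathway score for each row of a (n_runs, universe) value field."""
        vals = np.stack(
            [value_by_gene[:, mi].sum(axis=1) / nm for mi, nm in zip(member_idx, n_members)],
            axis=1,
        )
        is_deg = np.stack(
            [(value_by_gene[:, mi] > 0).any(axis=1) for mi in member_idx], axis=1
        )
        w = 1.0 + is_deg.astype(float) @ R.T.astype(float)
        return (vals * w).sum(axis=1)

    obs_field = np.zeros((1, len(universe)))
    obs_field[0, deg_pos] = deg_vals
    observed = float(scores(obs_field)[0])
    n_deg_pw = int(sum((obs_field[0, mi] > 0).any() for mi in member_idx))
    common["n_deg"] = n_deg_pw

    n_perm = cfg.n_permutations
    rng = cfg.rng()
    pos = np.argsort(rng.random((n_perm, len(universe))), axis=1)[:, :n_deg_all]
    null_field = np.zeros((n_perm, len(universe)))
    shuffled = rng.permuted(np.tile(deg_vals, (n_perm, 1)), axis=1)
    np.put_along_axis(null_field, pos, shuffled, axis=1)
    null = scores(null_field)

    p = float((1 + np.sum(null >= observed - 1e-12)) / (1 + n_perm))
    null_mean = float(null.mean())
    normalized = observed / null_mean if null_mean > 0 else np.nan
    return PathwayResult(
        **common,
        statistic=observed,
        p_value=p,
        extras={"normalized_score": normalized, "null_mean": null_mean},
    )
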