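"""Centrality-weighted over-representation analysis.

The pathway score under a centrality ``c`` is the sum of ``w_c`` over the
pathway's differentially expressed nodes.  Six weightings are evaluated
(in/out-degree, betweenness, in/out-reach, equal weight); each gets its own
gene-permutation p-value (random DEG sets of the observed size drawn from the
measured universe) and the pathway p-value is their *uncorrected* minimum,
a convention that inflates the type-I error.
"""

from __future__ import annotations

import numpy as np

from ..degs import DEGResult, ExpressionDataset
from ..pathways import CENTRALITY_NAMES, PathwayGraph, node_centralities
from .base import (
    NOT_TESTABLE,
    MethodConfig,
    PathwayResult,
    base_result,
)


def _induced(graph: PathwayGraph, nodes: list[str]) -> PathwayGraph:
    keep = set(nodes)
    edges = tuple(e for e in graph.edges if e.source in keep and e.target in keep)
    members = {n: graph.members(n) for n in nodes}
    return PathwayGraph(graph.pathway_id, tuple(nodes), edges, graph.provenance, members)


def cepa_ora(
    data: ExpressionDataset,
    graph: PathwayGraph,
    degs: DEGResult,
    cfg: MethodConfig | None = None,
) -> PathwayResult:
    cfg = cfg or MethodConfig()
    measured = set(data.genes)
    common = base_result("cepa", graph, measured)
    nodes = list(graph.measured_nodes(measured))
    if not nodes:
        return PathwayResult(**common, status=NOT_TESTABLE)

    W = node_centralities(_induced(graph, nodes)).to_numpy()  # n_nodes x 6
    universe = list(data.genes)
    uni_idx = {g: i for i, g in enumerate(universe)}
    member_idx = [
        np.array([uni_idx[m] for m in graph.members(n) if m in uni_idx], dtype=int)
        for n in nodes
    ]

    deg_ind = np.zeros(len(universe), dtype=bool)
    for g in degs.deg_set:
        deg_ind[uni_idx[g]] = True
    obs_node_deg = np.array([deg_ind[mi].any() for mi in member_idx], dtype=float)
    observed = obs_node_deg @ W  # one score per centrality
    n_deg_pw = int(obs_node_deg.sum())
    common["n_deg"] = n_deg_pw

    n_deg_all = len(degs.deg_set)
    n_perm = cfg.n_permutations
    rng = cfg.rng()
    pos = np.argsort(rng.random((n_perm, len(universe))), axis=1)[:, :n_deg_all]
    field = np.zeros((n_perm, len(universe)), dtype=bool)
    np.put_along_axis(field, pos, True, axis=1)
    node_deg = np.stack([field[:, mi].any(axis=1) for mi in member_idx], axis=1)
    null = node_deg.astype(float) @ W  # n_perm x 6

    p_c = (1 + (null >= observed[None, :] - 1e-12).sum(axis=0)) / (1 + n_perm)
    overall = float(p_c.min())
    extras = {f"p_{name}": float(p) for name, p in zip(CENTRALITY_NAMES, p_c)}
    extras.update({f"score_{name}": float(s) for name, s in zip(CENTRALITY_NAMES, observed)})
    best = int(np.argmin(p_c))
    return PathwayResult(
        **common,
        statistic=float(observed[best]),
        p_value=overall,
        extras=extras,
    )
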