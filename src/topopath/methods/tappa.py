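"""Topological analysis of pathway expression (per-sample connectivity index).

Expression is z-scored per gene; every sample then receives a Pathway
Connectivity Index

.. math::
   PCI_s = \\frac{1}{|V|} \\sum_{(i,j):\\ A^*_{ij}=1}
           \\operatorname{sgn}(z_{is})\\operatorname{sgn}(z_{js})
           \\sqrt{|z_{is}|\\,|z_{js}|}

summed over the symmetrized adjacency *with self-loops* (unordered pairs).
Differential pathway expression is a two-sided Mann-Whitney test between the
two groups' PCI values.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from ..degs import ExpressionDataset
from ..pathways import PathwayGraph
from .base import (
    NOT_TESTABLE,
    MethodConfig,
    PathwayResult,
    base_result,
    node_expression,
)


def pci_scores(data: ExpressionDataset, graph: PathwayGraph) -> tuple[list[str], np.ndarray]:
    """Per-sample PCI values for one pathway (nodes used, PCI vector)."""
    measured = set(data.genes)
    nodes, X = node_expression(data, graph, measured)
    sd = X.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"{graph.pathway_id}: dropping {int((~keep).sum())} constant node row(s)",
            stacklevel=2,
        )
        nodes = [n for n, k in zip(nodes, keep) if k]
        X = X[keep]
    if len(nodes) == 0:
        return nodes, np.zeros(data.X.shape[1])
    z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    s = np.sign(z) * np.sqrt(np.abs(z))
    idx = {g: i for i, g in enumerate(nodes)}
    M = np.zeros((len(nodes), len(nodes)))
    for e in graph.edges:
        if e.source in idx and e.target in idx and e.source != e.target:
            M[idx[e.source], idx[e.target]] = 1.0
            M[idx[e.target], idx[e.source]] = 1.0
    off = 0.5 * ((M @ s) * s).sum(axis=0)
    diag = np.abs(z).sum(axis=0)
    return nodes, (off + diag) / len(nodes)


def tappa(
    data: ExpressionDataset,
    graph: PathwayGraph,
    degs=None,
    cfg: MethodConfig | None = None,
) -> PathwayResult:
    cfg = cfg or MethodConfig()
    measured = set(data.genes)
    common = base_result("tappa", graph, measured)
    if common["n_measured"] < 2 or data.n1 < 2 or data.n2 < 2:
        return PathwayResult(**common, status=NOT_TESTABLE)
    nodes, pci = pci_scores(data, graph)
    if len(nodes) < 2:
        return PathwayResult(**common, status=NOT_TESTABLE)
    g1 = pci[data.group_columns(1)]
    g2 = pci[data.group_columns(2)]
    has_ties = len(np.unique(pci)) < pci.size
    method = "exact" if (len(g1) + len(g2) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method=method)
    return PathwayResult(
        **common,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        extras={"pci_mean_group1": float(g1.mean()), "pci_mean_group2": float(g2.mean())},
    )
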