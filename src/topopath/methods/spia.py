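"""Signalling-pathway impact analysis (perturbation propagation).

Each differentially expressed gene carries its observed log fold change
``dE``; the signal propagates along signed interactions, every gene passing
its perturbation ``PF`` to downstream neighbours diluted by its number of
signed out-edges.  In matrix form ``PF = dE + B PF`` with
``B[i, j] = sign(j -> i) / N_ds(j)``, solved as ``(I - B) PF = dE``.  The net
topology-attributable perturbation ``Acc = PF - dE`` sums to the pathway score
``tA``.  Significance combines two independent one-sided probabilities: a
hypergeometric over-representation p-value ``pNDE`` and a bootstrap
perturbation p-value ``pPERT`` (observed DEG log fold changes placed on random
pathway genes), merged as ``pG = c - c ln(c)`` with ``c = pNDE * pPERT``.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ..degs import DEGResult, ExpressionDataset
from ..pathways import PathwayGraph
from .base import (
    DEGENERATE,
    NOT_TESTABLE,
    MethodConfig,
    PathwayResult,
    base_result,
    measured_node_stats,
)


def signed_adjacency(graph: PathwayGraph, nodes: list[str]) -> np.ndarray:
    """Normalised signed adjacency B with B[i,j] = sign(j->i)/N_ds(j)."""
    idx = {g: i for i, g in enumerate(nodes)}
    p = len(nodes)
    raw = np.zeros((p, p))
    for e in graph.edges:
        if e.sign == 0:
            continue
        if e.source in idx and e.target in idx:
            raw[idx[e.target], idx[e.source]] += e.sign
            if not e.directed:
                raw[idx[e.source], idx[e.target]] += e.sign
    n_ds = np.abs(np.sign(raw)).sum(axis=0)  # signed out-degree per column
    B = np.divide(raw, n_ds, out=np.zeros_like(raw), where=n_ds > 0)
    return B


def accumulation(B: np.ndarray, delta_e: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve (I - B) PF = dE; returns (PF, Acc = PF - dE)."""
    eye = np.eye(B.shape[0])
    pf = np.linalg.solve(eye - B, delta_e)
    return pf, pf - delta_e


def spia(
    data: ExpressionDataset,
    graph: PathwayGraph,
    degs: DEGResult,
    cfg: MethodConfig | None = None,
) -> PathwayResult:
    cfg = cfg or MethodConfig()
    measured = set(data.genes)
    common = base_result("spia", graph, measured)
    nodes = list(graph.measured_nodes(measured))
    if not nodes:
        return PathwayResult(**common, status=NOT_TESTABLE)

    stats_tbl = measured_node_stats(graph, degs, measured)
    deg_mask = stats_tbl["deg"].to_numpy()
    n_deg_pw = int(deg_mask.sum())
    common["n_deg"] = n_deg_pw

    # over-representation component over the measured universe
    universe = len(measured)
    n_deg_all = len(degs.deg_set)
    n_pw = len(nodes)
    if n_deg_all == 0:
        return PathwayResult(
            **common, statistic=0.0, p_value=1.0,
            extras={"tA": 0.0, "pNDE": 1.0, "pPERT": None, "pG": 1.0},
        )
    p_nde = float(stats.hypergeom.sf(n_deg_pw - 1, universe, n_deg_all, n_pw))

    B = signed_adjacency(graph, nodes)
    if not B.any():
        # no signed interactions: the perturbation component is undefined
        # and the test reduces to over-representation alone
        return PathwayResult(
            **common, statistic=0.0, p_value=p_nde,
            extras={"tA": 0.0, "pNDE": p_nde, "pPERT": None, "pG": p_nde},
        )
    eye = np.eye(len(nodes))
    try:
        inv = np.linalg.inv(eye - B)
    except np.linalg.LinAlgError:
        return PathwayResult(**common, status=DEGENERATE)
    if not np.isfinite(inv).all() or np.abs(inv).max() > 1e12:
        return PathwayResult(**common, status=DEGENERATE)

    delta_e = np.where(deg_mask, stats_tbl["logFC"].to_numpy(), 0.0)
    pf = inv @ delta_e
    acc = pf - delta_e
    t_a = float(acc.sum())

    extras = {"tA": t_a, "pNDE": p_nde}
    if n_deg_pw == 0:
        p_pert = 1.0
    else:
        rng = cfg.rng()
        all_de = degs.logfc.loc[sorted(degs.deg_set)].to_numpy()
        n_boot = cfg.n_permutations
        # place bootstrap DEG log fold changes on random pathway positions
        pos = np.argsort(rng.random((n_boot, len(nodes))), axis=1)[:, :n_deg_pw]
        vals = rng.choice(all_de, size=(n_boot, n_deg_pw), replace=True)
        de_b = np.zeros((n_boot, len(nodes)))
        np.put_along_axis(de_b, pos, vals, axis=1)
        null = ((inv @ de_b.T) - de_b.T).sum(axis=0)
        med = float(np.median(null))
        exceed = np.sum(np.abs(null - med) >= np.abs(t_a - med) - 1e-12)
        p_pert = float((1 + exceed) / (1 + n_boot))
    c = p_nde * p_pert
    p_g = float(c - c * np.log(c)) if c > 0 else 0.0
    p_g = min(p_g, 1.0)
    extras.update({"pPERT": p_pert, "pG": p_g})
    return PathwayResult(**common, statistic=t_a, p_value=p_g, extras=extras)
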