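"""Dispatch a named method over a pathway collection."""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ..degs import DEGResult, ExpressionDataset, call_degs, moderated_t
from ..pathways import PathwayGraph, filter_pathways
from .base import MethodConfig, PathwayResult
from .cepa import cepa_ora
from .degraph import degraph
from .ggm import clipper, topology_gsa
from .prs import prs
from .spia import spia
from .tappa import tappa

METHODS: dict[str, Callable] = {
    "spia": spia,
    "prs": prs,
    "cepa": cepa_ora,
    "tappa": tappa,
    "topologygsa": topology_gsa,
    "clipper": clipper,
    "degraph": degraph,
}

ORA_METHODS = ("spia", "prs", "cepa")


def run_method(
    name: str,
    data: ExpressionDataset,
    pathways: Sequence[PathwayGraph],
    cfg: MethodConfig | None = None,
    degs: DEGResult | None = None,
    apply_filter: bool = True,
) -> list[PathwayResult]:
    """Run one method on every retained pathway.

    DEGs are computed once (moderated t at ``cfg.deg_theta``) when an ORA
    method needs them and none are supplied.  Each pathway gets a seed derived
    deterministically from ``cfg.seed`` and its position, so the result table
    is reproducible bit-for-bit for a fixed input.
    """
    if name not in METHODS:
        raise ValueError(f"unknown method {name!r}; choose from {sorted(METHODS)}")
    cfg = cfg or MethodConfig()
    fn = METHODS[name]
    if apply_filter:
        pathways = filter_pathways(pathways, set(data.genes))
    if degs is None and name in ORA_METHODS:
        degs = call_degs(moderated_t(data), cfg.deg_theta)
    results = []
    ss = np.random.SeedSequence(cfg.seed if cfg.seed is not None else 0)
    child_seeds = ss.spawn(len(pathways))
    for graph, child in zip(pathways, child_seeds):
        sub = cfg.with_seed(int(child.generate_state(1)[0] % (2**31)))
        res = fn(data, graph, degs=degs, cfg=sub)
        if degs is not None and res.n_deg == 0 and name not in ORA_METHODS:
            res.n_deg = sum(
                1 for n in graph.measured_nodes(set(data.genes))
                if any(m in degs.deg_set for m in graph.members(n))
            )
        res.extras.setdefault("seed", sub.seed)
        results.append(res)
    return results


def results_table(results: Sequence[PathwayResult], alpha: float = 0.05) -> pd.DataFrame:
    """Tidy result table, ordered by (method, pathway_id)."""
    import json

    rows = []
    for r in results:
        rows.append(
            {
                "method": r.method,
                "pathway_id": r.pathway_id,
                "n_nodes": r.n_nodes,
                "n_measured": r.n_measured,
                "n_deg": r.n_deg,
                "statistic": r.statistic,
                "p_value": np.nan if r.p_value is None else r.p_value,
                "dep": int(r.p_value is not None and r.p_value < alpha),
                "status": r.status,
                "extras": json.dumps(r.extras, default=str, sort_keys=True),
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["method", "pathway_id"], kind="mergesort").reset_index(drop=True)
    return df
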