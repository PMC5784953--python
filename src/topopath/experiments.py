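"""The eight controlled benchmark experiments and their evaluation metrics.

Each experiment is a pure function of (inputs, config, seed) producing an
:class:`ExperimentReport` with long-format rows plus summary tables that are
recomputable from the rows.  The experiments probe, in order: sensitivity to
sample size / pathway size / DEG threshold (ex1), type-I error under null
relabelings (ex2), the influence of overexpressing single genes (ex3), gene
sets (ex4) and topological motifs (ex5), target-pathway recovery (ex6), the
value of the topology itself via edge ablation (ex7), and the effect of the
topology pre-processing convention (ex8).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .degs import ExpressionDataset, call_degs, moderated_t
from .methods import MethodConfig, PathwayResult, run_method
from .methods.runner import ORA_METHODS
from .pathways import (
    GPT,
    METHOD_MSPT,
    PathwayGraph,
    RawPathway,
    enumerate_motifs,
    preprocess_topology,
    strip_interactions,
)
from .synthetic import (
    PerturbationSpec,
    SyntheticConfig,
    generate_base_dataset,
    induce_shift,
    null_relabel,
    subsample,
)

INFLUENCE_BINS = (
    (0.0, 0.2, "very low"),
    (0.2, 0.4, "low"),
    (0.4, 0.6, "medium"),
    (0.6, 0.8, "high"),
    (0.8, 1.0 + 1e-12, "very high"),
)


@dataclass
class ExperimentReport:
    experiment: str
    rows: pd.DataFrame
    summary: dict[str, pd.DataFrame] = field(default_factory=dict)
    config: dict = field(default_factory=dict)


@dataclass
class InfluenceProfile:
    """Pooled influence of one perturbation target (gene, set or motif)."""

    target: str
    proportion: float
    category: str
    per_delta: pd.Series  # index delta -> DEP proportion
    method: str = ""


# ---------------------------------------------------------------------------
# metrics


def dep_proportion(results: Iterable[PathwayResult] | Iterable[float], alpha: float = 0.05) -> float:
    """Fraction of testable results with p < alpha (not-testable rows excluded)."""
    ps = []
    skipped = 0
    for r in results:
        if isinstance(r, PathwayResult):
            if r.p_value is None:
                skipped += 1
                continue
            ps.append(r.p_value)
        else:
            if r is None or (isinstance(r, float) and np.isnan(r)):
                skipped += 1
                continue
            ps.append(float(r))
    if not ps:
        warnings.warn("no testable results; DEP proportion undefined")
        return float("nan")
    return float(np.mean(np.asarray(ps) < alpha))


def categorize_influence(proportion: float) -> str:
    """Map a DEP proportion to the five influence categories."""
    if not 0.0 <= proportion <= 1.0:
        raise ValueError("proportion must lie in [0, 1]")
    for lo, hi, name in INFLUENCE_BINS:
        if lo <= proportion < hi:
            return name
    return "very high"


def dense_rank(p_values: Sequence[float]) -> np.ndarray:
    """Tie-aware rank: lowest p-value gets rank 1, equal p-values share a
    rank, and the rank increments by one between distinct p-values."""
    arr = np.asarray(list(p_values), dtype=float)
    if arr.size == 0:
        return np.array([], dtype=int)
    return stats.rankdata(arr, method="dense").astype(int)


def median_lower(values: Iterable[float]) -> float:
    """Median with the lower-interpolation convention for even counts."""
    arr = np.sort(np.asarray(list(values), dtype=float))
    if arr.size == 0:
        return float("nan")
    return float(arr[(arr.size - 1) // 2])


# ---------------------------------------------------------------------------
# shared plumbing


def _result_rows(results: Sequence[PathwayResult], alpha: float, **params) -> list[dict]:
    rows = []
    for r in results:
        rows.append(
            dict(
                method=r.method,
                pathway_id=r.pathway_id,
                n_nodes=r.n_nodes,
                p_value=np.nan if r.p_value is None else r.p_value,
                status=r.status,
                dep=int(r.p_value is not None and r.p_value < alpha),
                **params,
            )
        )
    return rows


def _spawn_seed(base: int | None, *keys: int) -> int:
    ss = np.random.SeedSequence([0 if base is None else base, *keys])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# experiment 1: sample size / pathway size / DEG threshold


def ex1_sample_size(
    data: ExpressionDataset,
    pathways: Sequence[PathwayGraph],
    methods: Sequence[str],
    fractions: Sequence[float] = tuple(np.round(np.arange(0.05, 1.0, 0.05), 2)),
    n_subsets: int = 20,
    thresholds: Sequence[float] = (0.05, 0.01, 0.001),
    cfg: MethodConfig | None = None,
    size_split: int = 35,
) -> ExperimentReport:
    """Sweep the sample fraction (stratified subsampling) and, for ORA
    methods, the DEG threshold; summarise DEP proportions and per-stratum
    median p-values."""
    cfg = cfg or MethodConfig()
    rows: list[dict] = []
    for fi, frac in enumerate(fractions):
        for rep in range(n_subsets):
            seed = _spawn_seed(cfg.seed, 1, fi, rep)
            try:
                sub = subsample(data, frac, seed)
            except ValueError as err:
                warnings.warn(f"fraction {frac} skipped: {err}")
                break
            base_degs = moderated_t(sub)
            for method in methods:
                thetas = thresholds if method in ORA_METHODS else (cfg.deg_theta,)
                for theta in thetas:
                    degs = call_degs(base_degs, theta)
                    res = run_method(
                        method, sub, pathways, cfg.with_seed(seed), degs=degs,
                        apply_filter=False,
                    )
                    rows.extend(
                        _result_rows(
                            res, cfg.alpha,
                            fraction=frac, replicate=rep, theta=theta,
                            n_samples=sub.X.shape[1],
                        )
                    )
    df = pd.DataFrame(rows)
    summary: dict[str, pd.DataFrame] = {}
    if not df.empty:
        at_default = df[df["theta"] == cfg.deg_theta]
        prop = (
            at_default.groupby(["method", "fraction", "replicate"])["dep"]
            .mean()
            .groupby(["method", "fraction"])
            .median()
            .rename("median_dep_proportion")
            .reset_index()
        )
        summary["dep_by_fraction"] = prop
        strata = at_default.assign(
            stratum=np.where(at_default["n_nodes"] < size_split, "small", "large")
        )
        summary["median_p_by_stratum"] = (
            strata.groupby(["method", "fraction", "stratum"])["p_value"]
            .apply(median_lower)
            .rename("median_p")
            .reset_index()
        )
        ora = df[df["method"].isin(ORA_METHODS)]
        if not ora.empty:
            summary["dep_by_threshold"] = (
                ora.groupby(["method", "fraction", "theta", "replicate"])["dep"]
                .mean()
                .groupby(["method", "fraction", "theta"])
                .median()
                .rename("median_dep_proportion")
                .reset_index()
            )
    return ExperimentReport(
        "ex1", df, summary,
        dict(fractions=list(fractions), n_subsets=n_subsets, thresholds=list(thresholds)),
    )


# ---------------------------------------------------------------------------
# experiment 2: type I error


def ex2_type1(
    data: ExpressionDataset,
    pathways: Sequence[PathwayGraph],
    methods: Sequence[str],
    n_relabel: int = 50,
    cfg: MethodConfig | None = None,
) -> ExperimentReport:
    """Null hypotheses built by random group relabelings of a null dataset;
    reports per-method rejection proportions and 20-bin p-value histograms."""
    cfg = cfg or MethodConfig()
    rows: list[dict] = []
    for rep in range(n_relabel):
        seed = _spawn_seed(cfg.seed, 2, rep)
        null = null_relabel(data, seed)
        degs = call_degs(moderated_t(null), cfg.deg_theta)
        for method in methods:
            res = run_method(
                method, null, pathways, cfg.with_seed(seed), degs=degs,
                apply_filter=False,
            )
            rows.extend(_result_rows(res, cfg.alpha, replicate=rep))
    df = pd.DataFrame(rows)
    ok = df[df["status"] == "ok"]
    rej = (
        ok.groupby("method")
        .agg(n_tests=("dep", "size"), n_rejected=("dep", "sum"))
        .assign(proportion=lambda t: t["n_rejected"] / t["n_tests"])
        .reset_index()
    )
    bins = np.linspace(0.0, 1.0, 21)
    hists = []
    for method, grp in ok.groupby("method"):
        counts, _ = np.histogram(grp["p_value"].to_numpy(), bins=bins)
        for b, c in enumerate(counts):
            hists.append(dict(method=method, bin=b, lo=bins[b], hi=bins[b + 1], count=int(c)))
    return ExperimentReport(
        "ex2", df,
        {"rejection": rej, "p_histogram": pd.DataFrame(hists)},
        dict(n_relabel=n_relabel, alpha=cfg.alpha),
    )


# ---------------------------------------------------------------------------
# influence machinery shared by experiments 3-5


def _influence_scan(
    data_cfg: SyntheticConfig,
    pathway: PathwayGraph,
    method: str | Sequence[str],
    targets: Mapping[str, tuple[str, ...]],
    deltas: Sequence[float],
    n_datasets: int,
    cfg: MethodConfig,
    experiment: str,
) -> ExperimentReport:
    """Shared loop: shift each target's genes by each delta in each replicate
    dataset and record whether the pathway is called differentially expressed.

    Base datasets (and the per-dataset DEG calls) are shared across targets,
    deltas and methods at a matched replicate — a paired design that reduces
    Monte-Carlo variance.
    """
    methods = [method] if isinstance(method, str) else list(method)
    rows: list[dict] = []
    for rep in range(n_datasets):
        base = generate_base_dataset(
            SyntheticConfig(**{**data_cfg.__dict__, "seed": _spawn_seed(data_cfg.seed, 3, rep)})
        )
        for delta in deltas:
            for name, genes in targets.items():
                shifted = induce_shift(base, PerturbationSpec(tuple(genes), float(delta), 1))
                run_seed = _spawn_seed(cfg.seed, 4, rep, int(round(delta * 1000)))
                degs = (
                    call_degs(moderated_t(shifted), cfg.deg_theta)
                    if any(m in ORA_METHODS for m in methods)
                    else None
                )
                for m in methods:
                    res = run_method(
                        m, shifted, [pathway], cfg.with_seed(run_seed),
                        degs=degs, apply_filter=False,
                    )[0]
                    rows.append(
                        dict(
                            method=m,
                            pathway_id=pathway.pathway_id,
                            target=name,
                            delta=float(delta),
                            replicate=rep,
                            p_value=np.nan if res.p_value is None else res.p_value,
                            status=res.status,
                            dep=int(res.p_value is not None and res.p_value < cfg.alpha),
                        )
                    )
    df = pd.DataFrame(rows)
    ok = df[df["status"] == "ok"]
    profiles = (
        ok.groupby(["method", "target"])["dep"].mean().rename("proportion").reset_index()
    )
    profiles["category"] = profiles["proportion"].map(categorize_influence)
    curve = (
        ok.groupby(["method", "target", "delta"])["dep"]
        .mean().rename("proportion").reset_index()
    )
    pooled = (
        ok.groupby(["method", "delta"])["dep"].mean().rename("proportion").reset_index()
    )
    return ExperimentReport(
        experiment, df,
        {"influence": profiles, "per_delta": curve, "pooled_curve": pooled},
        dict(method=methods, deltas=list(map(float, deltas)), n_datasets=n_datasets),
    )


def influence_profiles(report: ExperimentReport) -> list[InfluenceProfile]:
    out = []
    curve = report.summary["per_delta"]
    for _, row in report.summary["influence"].iterrows():
        sel = (curve["target"] == row["target"]) & (curve["method"] == row["method"])
        pc = curve[sel].set_index("delta")["proportion"]
        out.append(
            InfluenceProfile(
                row["target"], float(row["proportion"]), row["category"], pc, row["method"]
            )
        )
    return out


DEFAULT_DELTAS = tuple(np.round(np.arange(0.1, 2.01, 0.1), 1))


def ex3_single_gene(
    data_cfg: SyntheticConfig,
    pathway: PathwayGraph,
    method: str | Sequence[str],
    deltas: Sequence[float] = DEFAULT_DELTAS,
    n_datasets: int = 200,
    cfg: MethodConfig | None = None,
    genes: Sequence[str] | None = None,
) -> ExperimentReport:
    """Influence of overexpressing each single gene (node) of a pathway."""
    cfg = cfg or MethodConfig()
    universe = [f"g{i:05d}" for i in range(data_cfg.n_genes)]
    measured = set(universe)
    nodes = genes if genes is not None else pathway.measured_nodes(measured)
    targets = {n: tuple(m for m in pathway.members(n) if m in measured) for n in nodes}
    targets = {n: ms for n, ms in targets.items() if ms}
    return _influence_scan(
        data_cfg, pathway, method, targets, deltas, n_datasets, cfg, "ex3"
    )


def ex4_gene_sets(
    data_cfg: SyntheticConfig,
    pathway: PathwayGraph,
    method: str | Sequence[str],
    set_sizes: Sequence[int] = (2, 3, 4, 5),
    n_sets: int = 10,
    deltas: Sequence[float] = DEFAULT_DELTAS,
    n_datasets: int = 200,
    cfg: MethodConfig | None = None,
    single_gene_report: ExperimentReport | None = None,
) -> ExperimentReport:
    """Influence of overexpressing random gene sets of sizes 2-5; pairs each
    set's influence with the sum of its members' single-gene influences."""
    cfg = cfg or MethodConfig()
    universe = [f"g{i:05d}" for i in range(data_cfg.n_genes)]
    measured = set(universe)
    nodes = list(pathway.measured_nodes(measured))
    rng = np.random.default_rng(_spawn_seed(cfg.seed, 5))
    targets: dict[str, tuple[str, ...]] = {}
    membership: dict[str, tuple[str, ...]] = {}
    for size in set_sizes:
        if size > len(nodes):
            warnings.warn(f"set size {size} exceeds measured genes; skipped")
            continue
        for s in range(n_sets):
            chosen = tuple(sorted(rng.choice(nodes, size=size, replace=False)))
            name = f"set{size}_{s:02d}"
            gene_ids: list[str] = []
            for node in chosen:
                gene_ids.extend(m for m in pathway.members(node) if m in measured)
            targets[name] = tuple(gene_ids)
            membership[name] = chosen
    rep = _influence_scan(data_cfg, pathway, method, targets, deltas, n_datasets, cfg, "ex4")
    rep.rows["set_size"] = rep.rows["target"].map(lambda t: len(membership[t]))
    infl = rep.summary["influence"].copy()
    infl["set_size"] = infl["target"].map(lambda t: len(membership[t]))
    infl["members"] = infl["target"].map(lambda t: ";".join(membership[t]))
    if single_gene_report is not None:
        single = single_gene_report.summary["influence"].set_index(["method", "target"])[
            "proportion"
        ]
        infl["member_influence_sum"] = infl.apply(
            lambda row: float(
                sum(single.get((row["method"], m), np.nan) for m in membership[row["target"]])
            ),
            axis=1,
        )
    rep.summary["influence"] = infl
    rep.config.update(dict(set_sizes=list(set_sizes), n_sets=n_sets))
    return rep


def ex5_motifs(
    data_cfg: SyntheticConfig,
    pathway: PathwayGraph,
    method: str | Sequence[str],
    k_values: Sequence[int] = (3, 4, 5),
    deltas: Sequence[float] = DEFAULT_DELTAS,
    n_datasets: int = 200,
    cfg: MethodConfig | None = None,
    max_instances_per_class: int = 5,
    gene_set_report: ExperimentReport | None = None,
) -> ExperimentReport:
    """Influence of overexpressing connected topological motifs of 3-5 genes,
    grouped by isomorphism class, contrasted against size-matched random
    gene sets when a gene-set report is provided."""
    cfg = cfg or MethodConfig()
    rng = np.random.default_rng(_spawn_seed(cfg.seed, 6))
    targets: dict[str, tuple[str, ...]] = {}
    klass: dict[str, str] = {}
    for k in k_values:
        if pathway.n_genes < k:
            continue
        instances = enumerate_motifs(pathway, k)
        by_class: dict[str, list] = {}
        for inst in instances:
            by_class.setdefault(inst.isomorphism_class, []).append(inst)
        for cls, insts in sorted(by_class.items()):
            if len(insts) > max_instances_per_class:
                chosen = rng.choice(len(insts), size=max_instances_per_class, replace=False)
                insts = [insts[i] for i in sorted(chosen)]
            for i, inst in enumerate(insts):
                name = f"motif{k}_{cls.split(':')[1]}_{i:02d}"
                gene_ids: list[str] = []
                for node in sorted(inst.genes):
                    gene_ids.extend(pathway.members(node))
                targets[name] = tuple(gene_ids)
                klass[name] = cls
    rep = _influence_scan(data_cfg, pathway, method, targets, deltas, n_datasets, cfg, "ex5")
    rep.rows["motif_class"] = rep.rows["target"].map(klass)
    rep.rows["motif_size"] = rep.rows["motif_class"].map(lambda c: int(c.split(":")[0]))
    infl = rep.summary["influence"].copy()
    infl["motif_class"] = infl["target"].map(klass)
    infl["motif_size"] = infl["motif_class"].map(lambda c: int(c.split(":")[0]))
    rep.summary["influence"] = infl
    rep.summary["by_class"] = (
        rep.rows[rep.rows["status"] == "ok"]
        .groupby(["motif_class", "delta"])["dep"].mean().rename("proportion").reset_index()
    )
    if gene_set_report is not None:
        sets = gene_set_report.summary["influence"]
        contrast = []
        for size in sorted(set(infl["motif_size"])):
            m_prop = infl.loc[infl["motif_size"] == size, "proportion"]
            s_prop = sets.loc[sets["set_size"] == size, "proportion"]
            if len(m_prop) and len(s_prop):
                contrast.append(
                    dict(
                        size=size,
                        motif_mean_influence=float(m_prop.mean()),
                        set_mean_influence=float(s_prop.mean()),
                    )
                )
        rep.summary["motif_vs_set"] = pd.DataFrame(contrast)
    rep.config.update(dict(k_values=list(k_values)))
    return rep


# ---------------------------------------------------------------------------
# experiment 6: target pathway ranks


def ex6_target_rank(
    results_per_dataset: Sequence[Sequence[PathwayResult]],
    target_ids: Sequence[str],
) -> ExperimentReport:
    """Dense ranks and p-values of designated target pathways across datasets."""
    rows = []
    for d, results in enumerate(results_per_dataset):
        tested = [r for r in results if r.p_value is not None]
        ranks = dense_rank([r.p_value for r in tested])
        rank_of = {r.pathway_id: int(rk) for r, rk in zip(tested, ranks)}
        p_of = {r.pathway_id: r.p_value for r in tested}
        status_of = {r.pathway_id: r.status for r in results}
        for t in target_ids:
            rows.append(
                dict(
                    dataset=d,
                    target=t,
                    p_value=p_of.get(t, np.nan),
                    rank=rank_of.get(t, np.nan),
                    status=status_of.get(t, "missing"),
                    n_tested=len(tested),
                )
            )
    df = pd.DataFrame(rows)
    ok = df[df["status"] == "ok"]
    summary = (
        ok.groupby("target")
        .agg(
            median_p=("p_value", median_lower),
            median_rank=("rank", median_lower),
            n_tested=("dataset", "size"),
        )
        .reset_index()
    )
    summary["n_datasets"] = len(results_per_dataset)
    return ExperimentReport("ex6", df, {"targets": summary}, dict(targets=list(target_ids)))


# ---------------------------------------------------------------------------
# experiments 7-8: ablation and pre-processing


def ex7_ablation(
    data: ExpressionDataset,
    pathways: Sequence[PathwayGraph],
    methods: Sequence[str],
    cfg: MethodConfig | None = None,
) -> ExperimentReport:
    """Run every method on the full topology and on its edge-stripped variant
    with shared seeds; report paired p-values."""
    cfg = cfg or MethodConfig()
    degs = call_degs(moderated_t(data), cfg.deg_theta)
    rows: list[dict] = []
    for variant, pws in (
        ("gpt", list(pathways)),
        ("nogpt", [strip_interactions(g) for g in pathways]),
    ):
        for method in methods:
            res = run_method(method, data, pws, cfg, degs=degs, apply_filter=False)
            rows.extend(_result_rows(res, cfg.alpha, variant=variant))
    df = pd.DataFrame(rows)
    paired = df.pivot_table(
        index=["method", "pathway_id"], columns="variant", values="p_value",
        aggfunc="first",
    ).reset_index()
    paired["delta_p"] = paired["nogpt"] - paired["gpt"]
    return ExperimentReport("ex7", df, {"paired": paired}, {})


def ex8_preprocessing(
    data: ExpressionDataset,
    raw_pathways: Sequence[RawPathway],
    methods: Sequence[str],
    cfg: MethodConfig | None = None,
) -> ExperimentReport:
    """Contrast graphite-style (GPT) pre-processing with each method's own
    convention (MSPT); methods without one (TAPPA) run on GPT only."""
    cfg = cfg or MethodConfig()
    degs = call_degs(moderated_t(data), cfg.deg_theta)
    rows: list[dict] = []
    for method in methods:
        variants = {"gpt": [preprocess_topology(r, GPT) for r in raw_pathways]}
        mspt = METHOD_MSPT.get(method)
        if mspt is not None:
            variants["mspt"] = [preprocess_topology(r, mspt) for r in raw_pathways]
        for variant, pws in variants.items():
            res = run_method(method, data, pws, cfg, degs=degs, apply_filter=False)
            rows.extend(_result_rows(res, cfg.alpha, variant=variant))
    df = pd.DataFrame(rows)
    paired = df.pivot_table(
        index=["method", "pathway_id"], columns="variant", values="p_value",
        aggfunc="first",
    ).reset_index()
    return ExperimentReport("ex8", df, {"paired": paired}, {})
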