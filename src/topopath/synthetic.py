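"""Synthetic expression data and toy pathway fixtures.

The generator emulates a microarray-style breast-tumour cohort on the log2
scale: per-gene means and standard deviations are drawn from configurable
distributions, genes are organised into equicorrelated blocks (co-expression
modules), and the two clinical groups are drawn from the *same* multivariate
normal — any group effect is injected afterwards with
:func:`induce_shift`, which makes the perturbation ground truth exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .degs import ExpressionDataset
from .pathways import RawEdge, RawNode, RawPathway


@dataclass
class SyntheticConfig:
    """Defaults approximate an unbalanced two-group tumour cohort on a
    medium-density platform, scaled to desk size."""

    n_genes: int = 2000
    n1: int = 120
    n2: int = 60
    mean_loc: float = 7.0
    mean_scale: float = 2.0
    sd_loc: float = 0.5
    sd_scale: float = 0.25
    sd_floor: float = 0.1
    block_size: int = 20
    block_rho: float = 0.2
    seed: int = 0


@dataclass(frozen=True)
class PerturbationSpec:
    """Additive log2 shift delta on gene set I for one group's samples."""

    genes: tuple[str, ...]
    delta: float
    group: int = 1

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("perturbation needs a non-empty gene set")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.group not in (1, 2):
            raise ValueError("target group must be 1 or 2")


def generate_base_dataset(cfg: SyntheticConfig | None = None) -> ExpressionDataset:
    """Draw a null two-group dataset (no group effect).

    Within each consecutive block of ``block_size`` genes the pairwise
    correlation is ``block_rho``, realised through a shared block factor:
    ``x = sqrt(rho) * u_block + sqrt(1 - rho) * eps``.
    """
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    rho = cfg.block_rho
    if not 0.0 <= rho < 1.0:
        clipped = min(max(rho, 0.0), 0.99)
        warnings.warn(f"block_rho {rho} outside [0, 1); clipped to {clipped}")
        rho = clipped
    n = cfg.n1 + cfg.n2
    p = cfg.n_genes
    means = rng.normal(cfg.mean_loc, cfg.mean_scale, size=p)
    sds = np.abs(rng.normal(cfg.sd_loc, cfg.sd_scale, size=p)) + cfg.sd_floor
    eps = rng.standard_normal((p, n))
    if rho > 0:
        blocks = np.arange(p) // cfg.block_size
        u = rng.standard_normal((blocks.max() + 1, n))
        z = np.sqrt(rho) * u[blocks] + np.sqrt(1.0 - rho) * eps
    else:
        z = eps
    X = means[:, None] + sds[:, None] * z
    genes = pd.Index([f"g{i:05d}" for i in range(p)], name="gene")
    samples = pd.Index([f"s{i:04d}" for i in range(n)], name="sample")
    y = np.array([1] * cfg.n1 + [2] * cfg.n2)
    return ExpressionDataset(X, genes, samples, y)


def induce_shift(data: ExpressionDataset, spec: PerturbationSpec) -> ExpressionDataset:
    """Add ``delta`` to the target group's samples for the genes in ``spec``.

    Every other entry is bit-identical to the input.
    """
    missing = [g for g in spec.genes if g not in data.genes]
    if missing:
        raise KeyError(f"unknown gene(s) in perturbation: {missing}")
    out = data.copy()
    rows = data.genes.get_indexer(list(spec.genes))
    cols = data.group_columns(spec.group)
    out.X[np.ix_(rows, cols)] += spec.delta
    return out


def null_relabel(data: ExpressionDataset, seed: int) -> ExpressionDataset:
    """Permute group labels uniformly at random, preserving group sizes."""
    rng = np.random.default_rng(seed)
    y = rng.permutation(data.y)
    return ExpressionDataset(data.X, data.genes, data.samples, y)


def subsample(data: ExpressionDataset, fraction: float, seed: int) -> ExpressionDataset:
    """Per-group subsample without replacement (floor(fraction * size) each)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for group in (1, 2):
        cols = data.group_columns(group)
        k = int(np.floor(fraction * len(cols)))
        if k < 2:
            raise ValueError(
                f"fraction {fraction} leaves group {group} with {k} < 2 samples"
            )
        keep.extend(sorted(rng.choice(cols, size=k, replace=False)))
    keep = sorted(keep)
    return ExpressionDataset(
        data.X[:, keep], data.genes, data.samples[keep], data.y[keep]
    )


# ---------------------------------------------------------------------------
# toy pathway fixtures


def _gene_nodes(ids: list[str]) -> list[RawNode]:
    return [RawNode(g, "gene") for g in ids]


def toy_pathway_suite(seed: int = 0, universe: list[str] | None = None) -> list[RawPathway]:
    """Deterministic fixtures covering the structures the methods exercise.

    Gene ids default to the synthetic universe naming (g00000, g00001, ...),
    so the fixtures line up with :func:`generate_base_dataset` output.
    """
    if universe is None:
        universe = [f"g{i:05d}" for i in range(2000)]
    g = universe

    def genes(lo: int, hi: int) -> list[str]:
        return g[lo:hi]

    suite: list[RawPathway] = []
    # 1. ten-gene activation cascade: positions differ in downstream reach
    ids = genes(0, 10)
    suite.append(
        RawPathway(
            "chain",
            _gene_nodes(ids),
            [RawEdge(ids[i], ids[i + 1], True, "activation") for i in range(9)],
        )
    )
    # 2. star: hub activates four leaves
    ids = genes(10, 15)
    suite.append(
        RawPathway(
            "star",
            _gene_nodes(ids),
            [RawEdge(ids[0], leaf, True, "activation") for leaf in ids[1:]],
        )
    )
    # 3. directed triangle (feedback loop)
    ids = genes(15, 18)
    suite.append(
        RawPathway(
            "triangle",
            _gene_nodes(ids),
            [
                RawEdge(ids[0], ids[1], True, "activation"),
                RawEdge(ids[1], ids[2], True, "activation"),
                RawEdge(ids[2], ids[0], True, "inhibition"),
            ],
        )
    )
    # 4. co-parent DAG: A -> C <- B, C -> D  (moralization adds exactly A-B)
    ids = genes(18, 22)
    suite.append(
        RawPathway(
            "coparent",
            _gene_nodes(ids),
            [
                RawEdge(ids[0], ids[2], True, "activation"),
                RawEdge(ids[1], ids[2], True, "inhibition"),
                RawEdge(ids[2], ids[3], True, "activation"),
            ],
        )
    )
    # 5. complex node: {X1, X2} complex activates C, upstream activator A
    ids = genes(22, 26)  # A, X1, X2, C
    suite.append(
        RawPathway(
            "complex",
            [
                RawNode(ids[0], "gene"),
                RawNode("cpx", "complex", (ids[1], ids[2])),
                RawNode(ids[3], "gene"),
            ],
            [
                RawEdge(ids[0], "cpx", True, "activation"),
                RawEdge("cpx", ids[3], True, "activation"),
            ],
        )
    )
    # 6. family node: {F1, F2} family inhibits T
    ids = genes(26, 29)  # F1, F2, T
    suite.append(
        RawPathway(
            "family",
            [
                RawNode("fam", "family", (ids[0], ids[1])),
                RawNode(ids[2], "gene"),
            ],
            [RawEdge("fam", ids[2], True, "inhibition")],
        )
    )
    # 7. compound bridge: A -> compound -> B
    ids = genes(29, 31)
    suite.append(
        RawPathway(
            "compound_bridge",
            [
                RawNode(ids[0], "gene"),
                RawNode("cmp", "compound"),
                RawNode(ids[1], "gene"),
            ],
            [
                RawEdge(ids[0], "cmp", True, "activation"),
                RawEdge("cmp", ids[1], True, "activation"),
            ],
        )
    )
    # 8. 30-gene random DAG (edges only forward in gene order)
    rng = np.random.default_rng(seed)
    ids = genes(31, 61)
    edges = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if rng.random() < 0.12:
                itype = "activation" if rng.random() < 0.75 else "inhibition"
                edges.append(RawEdge(ids[i], ids[j], True, itype))
    suite.append(RawPathway("random_dag30", _gene_nodes(ids), edges))
    return suite


#: default size mix for the toy collection: small pathways dominate, as in
#: curated databases after the 150-gene filter
DEFAULT_TOY_SIZES = (10, 12, 15, 18, 20, 22, 25, 28, 30, 14, 10, 16, 24, 12, 20, 26, 15, 18, 22, 30)


def toy_pathway_collection(
    sizes: tuple[int, ...] = DEFAULT_TOY_SIZES,
    seed: int = 0,
    universe: list[str] | None = None,
    start: int = 100,
) -> list[RawPathway]:
    """A disjoint collection of random-DAG pathways for calibration studies.

    Each pathway is a forward-ordered random DAG with mean out-degree about 2
    (edge probability 2/size), mixing activating and inhibiting interactions
    3:1.  Pathways use disjoint gene blocks starting at ``start``.
    """
    if universe is None:
        universe = [f"g{i:05d}" for i in range(2000)]
    rng = np.random.default_rng(seed)
    out = []
    lo = start
    for k, size in enumerate(sizes):
        ids = universe[lo : lo + size]
        lo += size
        if len(ids) < size:
            raise ValueError("universe too small for requested pathway sizes")
        edges = []
        for i in range(size):
            for j in range(i + 1, size):
                if rng.random() < 2.0 / size:
                    itype = "activation" if rng.random() < 0.75 else "inhibition"
                    edges.append(RawEdge(ids[i], ids[j], True, itype))
        out.append(RawPathway(f"toy{k:02d}", _gene_nodes(ids), edges))
    return out
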