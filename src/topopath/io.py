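"""Readers and writers: expression/label TSVs, pathway tables, GMT, results.

All writers emit UTF-8, Unix newlines, '.' decimal separators; readers
validate and reject malformed input rather than coercing it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .degs import ExpressionDataset
from .pathways import RawEdge, RawNode, RawPathway


class DataFormatError(ValueError):
    pass


@dataclass
class RunConfig:
    """One analysis run: methods, topology variant and test settings."""

    methods: list[str] = field(default_factory=lambda: ["spia"])
    topology: str = "gpt"  # gpt | nogpt | mspt
    alpha: float = 0.05
    deg_theta: float = 0.05
    n_permutations: int = 1000
    seed: int = 0
    expression: str | None = None
    labels: str | None = None
    pathway_nodes: str | None = None
    pathway_edges: str | None = None
    gmt: str | None = None
    out_dir: str = "."

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


# ---------------------------------------------------------------------------
# expression


def read_expression(expr_path: str | Path, labels_path: str | Path) -> ExpressionDataset:
    """Load a genes-x-samples log2 TSV plus a sample -> group label TSV.

    The label file's sample order dictates the column order of the matrix.
    """
    df = pd.read_csv(expr_path, sep="\t", index_col=0)
    if not df.index.is_unique:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise DataFormatError(f"duplicated gene id(s): {dup}")
    bad = df.columns[~df.apply(lambda c: pd.api.types.is_numeric_dtype(c))]
    if len(bad):
        for col in bad:
            row = df[col][pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise DataFormatError(f"non-numeric cell at gene {row!r}, sample {col!r}")
    labels = read_labels(labels_path)
    missing = [s for s in df.columns if s not in labels]
    if missing:
        raise DataFormatError(f"samples without labels: {missing}")
    order = [s for s in labels if s in df.columns]
    absent = [s for s in labels if s not in df.columns]
    if absent:
        raise DataFormatError(f"labelled samples missing from matrix: {absent}")
    df = df[order]
    y = np.array([labels[s] for s in order])
    return ExpressionDataset(df.to_numpy(float), df.index, pd.Index(order), y)


def read_labels(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], dtype=str)
    out: dict[str, int] = {}
    for _, row in df.iterrows():
        if row["group"] not in ("1", "2"):
            raise DataFormatError(
                f"label for sample {row['sample']!r} must be 1 or 2, got {row['group']!r}"
            )
        out[str(row["sample"])] = int(row["group"])
    return out


def write_expression(data: ExpressionDataset, expr_path: str | Path, labels_path: str | Path) -> None:
    df = pd.DataFrame(data.X, index=data.genes, columns=data.samples)
    df.to_csv(expr_path, sep="\t")
    with open(labels_path, "w") as fh:
        for s, g in zip(data.samples, data.y):
            fh.write(f"{s}\t{g}\n")


# ---------------------------------------------------------------------------
# pathways


def read_pathways(nodes_path: str | Path, edges_path: str | Path) -> list[RawPathway]:
    """Parse the node/edge TSV pair into validated raw pathways."""
    nodes = pd.read_csv(nodes_path, sep="\t", dtype=str).fillna("")
    edges = pd.read_csv(edges_path, sep="\t", dtype=str).fillna("")
    need_n = {"pathway_id", "node_id", "kind", "members"}
    need_e = {"pathway_id", "source", "target", "directed", "interaction_type"}
    if not need_n <= set(nodes.columns):
        raise DataFormatError(f"node table needs columns {sorted(need_n)}")
    if not need_e <= set(edges.columns):
        raise DataFormatError(f"edge table needs columns {sorted(need_e)}")
    out = []
    for pid, ngrp in nodes.groupby("pathway_id", sort=False):
        raw_nodes = [
            RawNode(
                r["node_id"], r["kind"],
                tuple(m for m in r["members"].split(";") if m),
            )
            for _, r in ngrp.iterrows()
        ]
        egrp = edges[edges["pathway_id"] == pid]
        raw_edges = []
        for _, r in egrp.iterrows():
            if r["directed"] not in ("0", "1"):
                raise DataFormatError(f"{pid}: directed flag must be 0/1")
            raw_edges.append(
                RawEdge(r["source"], r["target"], r["directed"] == "1", r["interaction_type"])
            )
        out.append(RawPathway(pid, raw_nodes, raw_edges))
    return out


def write_pathways(pathways: Sequence[RawPathway], nodes_path: str | Path, edges_path: str | Path) -> None:
    nrows, erows = [], []
    for p in pathways:
        for n in p.nodes:
            nrows.append(
                dict(pathway_id=p.pathway_id, node_id=n.node_id, kind=n.kind,
                     members=";".join(n.members))
            )
        for e in p.edges:
            erows.append(
                dict(pathway_id=p.pathway_id, source=e.source, target=e.target,
                     directed=int(e.directed), interaction_type=e.interaction_type)
            )
    pd.DataFrame(nrows).to_csv(nodes_path, sep="\t", index=False)
    pd.DataFrame(erows, columns=["pathway_id", "source", "target", "directed", "interaction_type"]).to_csv(
        edges_path, sep="\t", index=False
    )


def read_gmt(path: str | Path) -> list[RawPathway]:
    """GMT gene sets as edgeless, gene-only pathways."""
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise DataFormatError(f"GMT line {ln}: need name, description and >=1 gene")
        name, _desc, *genes = parts
        genes = [g for g in genes if g]
        if not genes:
            raise DataFormatError(f"GMT line {ln}: no genes")
        out.append(RawPathway(name, [RawNode(g, "gene") for g in genes], []))
    return out


def write_results(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: f"{v:.6g}" if pd.notna(v) else "")
    out.to_csv(path, sep="\t", index=False)


def write_manifest(path: str | Path, **payload) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
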