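"""Pathway graphs: data model, topology pre-processing and graph algorithms.

Pathway databases describe signalling as a network whose nodes may be genes,
multi-subunit protein complexes, gene families or small chemical compounds,
with typed, signed, possibly directed interactions.  Analysis methods expect a
plain gene-level graph ``G = (V, E)``, so raw topologies must be *pre-processed*.
Two conventions are supported:

* **GPT** ("graphite-style"): complexes are expanded into their member genes
  connected pairwise by neutral undirected edges, family members each inherit
  the family's edges, and compound nodes are removed with their incident
  interactions bridged transitively (A -> compound -> B becomes A -> B).
* **MSPT** ("method-specific"): the conventions of the original method
  implementations — combined complex/family nodes (PRS, CePa), expansion
  without within-complex edges (DEGraph), or dropping compound-mediated
  interactions instead of bridging them (SPIA).

Stripping every interaction (the ``NOGPT`` provenance) yields the edgeless
gene-set view used by non-topological method variants.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

NODE_KINDS = frozenset({"gene", "complex", "family", "compound"})

#: Interaction-type -> sign mapping.  Activating chemistry propagates a
#: positive signal, inhibitory chemistry a negative one; physical or
#: unspecified association is neutral (sign 0).
SIGN_MAP: Mapping[str, int] = {
    "activation": +1,
    "expression": +1,
    "phosphorylation": +1,
    "inhibition": -1,
    "repression": -1,
    "dephosphorylation": -1,
    "binding": 0,
    "association": 0,
    "indirect": 0,
    "neutral": 0,
    "compound_bridged": 0,
}

#: Topology pre-processing strategies.
GPT = "gpt"
MSPT_COMBINED = "mspt_combined"   # PRS / CePa: complexes & families stay one node
MSPT_DEGRAPH = "mspt_degraph"     # expansion without within-complex edges
MSPT_SPIA = "mspt_spia"           # compound-mediated edges dropped, not bridged
STRATEGIES = (GPT, MSPT_COMBINED, MSPT_DEGRAPH, MSPT_SPIA)

#: Which MSPT convention each method's original implementation uses.
#: ``None`` means the method has no separate convention (GPT is used as-is).
METHOD_MSPT: Mapping[str, str | None] = {
    "spia": MSPT_SPIA,
    "prs": MSPT_COMBINED,
    "cepa": MSPT_COMBINED,
    "tappa": None,
    "topologygsa": GPT,
    "clipper": GPT,
    "degraph": MSPT_DEGRAPH,
}


class PathwayError(ValueError):
    """Invalid pathway structure or unknown interaction vocabulary."""


@dataclass(frozen=True)
class RawNode:
    node_id: str
    kind: str
    members: tuple[str, ...] = ()


@dataclass(frozen=True)
class RawEdge:
    source: str
    target: str
    directed: bool
    interaction_type: str


@dataclass
class RawPathway:
    """A pathway as delivered by a database, before gene-level pre-processing."""

    pathway_id: str
    nodes: list[RawNode]
    edges: list[RawEdge]

    def __post_init__(self) -> None:
        ids = [n.node_id for n in self.nodes]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PathwayError(f"{self.pathway_id}: duplicate node ids {dup}")
        known = set(ids)
        for n in self.nodes:
            if n.kind not in NODE_KINDS:
                raise PathwayError(f"{self.pathway_id}: unknown node kind {n.kind!r}")
            if n.kind in ("complex", "family") and len(n.members) < 2:
                raise PathwayError(
                    f"{self.pathway_id}: {n.kind} node {n.node_id!r} needs >=2 members"
                )
            if n.kind in ("gene", "compound") and n.members:
                raise PathwayError(
                    f"{self.pathway_id}: {n.kind} node {n.node_id!r} must not list members"
                )
        for e in self.edges:
            if e.source not in known or e.target not in known:
                raise PathwayError(
                    f"{self.pathway_id}: edge {e.source}->{e.target} references undeclared node"
                )
            if e.interaction_type not in SIGN_MAP:
                raise PathwayError(
                    f"{self.pathway_id}: unknown interaction type {e.interaction_type!r}"
                )


@dataclass(frozen=True)
class Edge:
    """Gene-level interaction with a sign derived from its type."""

    source: str
    target: str
    directed: bool
    interaction_type: str

    @property
    def sign(self) -> int:
        return SIGN_MAP[self.interaction_type]


@dataclass
class PathwayGraph:
    """Gene-level interaction network of one pathway.

    ``genes`` is the ordered vertex set V; ``edges`` the signed, typed edge
    list E.  Under the ``MSPT_COMBINED`` convention a "gene" may stand for a
    combined complex/family node; ``node_members`` maps every node to the
    underlying gene ids (a singleton for plain genes).
    """

    pathway_id: str
    genes: tuple[str, ...]
    edges: tuple[Edge, ...]
    provenance: str = "GPT"
    node_members: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vs = set(self.genes)
        for e in self.edges:
            if e.source not in vs or e.target not in vs:
                raise PathwayError(
                    f"{self.pathway_id}: edge endpoint outside vertex set"
                )
        if not self.node_members:
            self.node_members = {g: (g,) for g in self.genes}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def members(self, node: str) -> tuple[str, ...]:
        return self.node_members.get(node, (node,))

    def all_member_genes(self) -> set[str]:
        out: set[str] = set()
        for g in self.genes:
            out.update(self.members(g))
        return out

    def to_digraph(self) -> nx.MultiDiGraph:
        """Expanded directed view: undirected edges become two opposite arcs."""
        G = nx.MultiDiGraph()
        G.add_nodes_from(self.genes)
        for e in self.edges:
            G.add_edge(e.source, e.target, sign=e.sign, interaction_type=e.interaction_type)
            if not e.directed:
                G.add_edge(e.target, e.source, sign=e.sign, interaction_type=e.interaction_type)
        return G

    def to_undirected(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(self.genes)
        G.add_edges_from((e.source, e.target) for e in self.edges)
        return G

    def measured_nodes(self, measured_genes: set[str]) -> tuple[str, ...]:
        """Nodes with at least one measured member gene."""
        return tuple(
            g for g in self.genes if any(m in measured_genes for m in self.members(g))
        )


# ---------------------------------------------------------------------------
# pre-processing


def _bridge_compounds(
    nodes: dict[str, RawNode], edges: list[RawEdge], pathway_id: str
) -> list[RawEdge]:
    """Remove compound nodes, transitively bridging their incident edges.

    A -> compound -> B becomes A -> B.  The bridged edge inherits the type of
    the constituent edge whose far endpoint is not a compound (preferring the
    outgoing side); a bridge is directed only if both constituents are.
    Cycles that involve only compounds are dropped with a warning.
    """
    compounds = {nid for nid, n in nodes.items() if n.kind == "compound"}
    if not compounds:
        return edges
    work = list(edges)
    for c in sorted(compounds):
        incoming = [e for e in work if e.target == c or (not e.directed and e.source == c)]
        outgoing = [e for e in work if e.source == c or (not e.directed and e.target == c)]
        work = [e for e in work if c not in (e.source, e.target)]
        for ein in incoming:
            u = ein.source if ein.target == c else ein.target
            for eout in outgoing:
                v = eout.target if eout.source == c else eout.source
                if u == v or u == c or v == c:
                    continue
                if v in compounds and u not in compounds:
                    itype = ein.interaction_type
                elif nodes[v].kind != "compound":
                    itype = eout.interaction_type
                else:
                    itype = eout.interaction_type
                work.append(RawEdge(u, v, ein.directed and eout.directed, itype))
        # self-referential leftovers indicate a compound-only cycle
        loops = [e for e in work if e.source == e.target]
        if loops:
            warnings.warn(
                f"{pathway_id}: dropping {len(loops)} compound-only cycle edge(s)",
                stacklevel=2,
            )
            work = [e for e in work if e.source != e.target]
    # deduplicate
    seen: set[tuple] = set()
    out = []
    for e in work:
        key = (e.source, e.target, e.directed, e.interaction_type)
        if key not in seen:
            seen.add(key)
            out.append(e)
    return out


def preprocess_topology(raw: RawPathway, strategy: str = GPT) -> PathwayGraph:
    """Convert a raw pathway into a gene-level :class:`PathwayGraph`.

    Parameters
    ----------
    raw : RawPathway
    strategy : str
        One of ``gpt``, ``mspt_combined``, ``mspt_degraph``, ``mspt_spia``.
    """
    if strategy not in STRATEGIES:
        raise PathwayError(f"unknown pre-processing strategy {strategy!r}")
    nodes = {n.node_id: n for n in raw.nodes}

    if strategy == MSPT_SPIA:
        # compound-mediated interactions are dropped, not bridged
        compounds = {nid for nid, n in nodes.items() if n.kind == "compound"}
        edges = [e for e in raw.edges if e.source not in compounds and e.target not in compounds]
    else:
        edges = _bridge_compounds(nodes, list(raw.edges), raw.pathway_id)
    nodes = {nid: n for nid, n in nodes.items() if n.kind != "compound"}

    if strategy == MSPT_COMBINED:
        genes = tuple(nodes)
        members = {
            nid: (n.members if n.kind in ("complex", "family") else (nid,))
            for nid, n in nodes.items()
        }
        out_edges = tuple(
            Edge(e.source, e.target, e.directed, e.interaction_type) for e in edges
        )
        return PathwayGraph(raw.pathway_id, genes, out_edges, "MSPT", members)

    # expansion strategies: every node becomes its member genes
    expansion: dict[str, tuple[str, ...]] = {}
    for nid, n in nodes.items():
        expansion[nid] = n.members if n.kind in ("complex", "family") else (nid,)
    gene_order: list[str] = []
    for nid in nodes:
        for g in expansion[nid]:
            if g not in gene_order:
                gene_order.append(g)

    out: list[Edge] = []
    seen: set[tuple] = set()

    def add(src: str, dst: str, directed: bool, itype: str) -> None:
        if src == dst:
            return
        key = (src, dst, directed, itype)
        ukey = (dst, src, directed, itype)
        if key in seen or (not directed and ukey in seen):
            return
        seen.add(key)
        out.append(Edge(src, dst, directed, itype))

    for e in edges:
        for src in expansion[e.source]:
            for dst in expansion[e.target]:
                add(src, dst, e.directed, e.interaction_type)
    if strategy == GPT:
        # within-complex neutral undirected edges among subunits
        for nid, n in nodes.items():
            if n.kind == "complex":
                for a, b in itertools.combinations(n.members, 2):
                    add(a, b, False, "binding")

    provenance = "GPT" if strategy == GPT else "MSPT"
    return PathwayGraph(raw.pathway_id, tuple(gene_order), tuple(out), provenance)


def strip_interactions(g: PathwayGraph) -> PathwayGraph:
    """Edgeless (non-topological, ``NOGPT``) variant with the same gene set."""
    return PathwayGraph(g.pathway_id, g.genes, (), "NOGPT", dict(g.node_members))


def filter_pathways(
    pathways: Sequence[PathwayGraph],
    measured_genes: Iterable[str],
    max_genes: int = 150,
    min_measured: int = 2,
) -> list[PathwayGraph]:
    """Drop pathways with more than ``max_genes`` nodes or with fewer than
    ``min_measured`` nodes carrying expression data.  Order is preserved."""
    measured = set(measured_genes)
    kept = []
    for g in pathways:
        if g.n_genes > max_genes:
            continue
        if len(g.measured_nodes(measured)) < min_measured:
            continue
        kept.append(g)
    return kept


# ---------------------------------------------------------------------------
# centralities

CENTRALITY_NAMES = (
    "in_degree",
    "out_degree",
    "betweenness",
    "in_reach",
    "out_reach",
    "equal_weight",
)


def node_centralities(g: PathwayGraph) -> pd.DataFrame:
    """Centrality table with one row per node.

    Degrees count directed arcs (an undirected edge contributes to both
    directions); betweenness is unnormalised shortest-path betweenness on the
    directed view; ``in_reach(v)`` is the longest finite shortest-path
    distance into v (``out_reach`` symmetric); ``equal_weight`` is 1.
    """
    D = nx.DiGraph(g.to_digraph())  # collapse parallel arcs for path algorithms
    M = g.to_digraph()
    rows = {}
    btw = nx.betweenness_centrality(D, normalized=False) if g.edges else {}
    spl = dict(nx.all_pairs_shortest_path_length(D)) if g.edges else {}
    for v in g.genes:
        in_reach = 0
        out_reach = 0
        for u in g.genes:
            if u == v:
                continue
            du = spl.get(u, {}).get(v)
            if du is not None:
                in_reach = max(in_reach, du)
            dv = spl.get(v, {}).get(u)
            if dv is not None:
                out_reach = max(out_reach, dv)
        rows[v] = {
            "in_degree": M.in_degree(v) if g.edges else 0,
            "out_degree": M.out_degree(v) if g.edges else 0,
            "betweenness": btw.get(v, 0.0),
            "in_reach": float(in_reach),
            "out_reach": float(out_reach),
            "equal_weight": 1.0,
        }
    tbl = pd.DataFrame.from_dict(rows, orient="index").reindex(list(g.genes))
    return tbl[list(CENTRALITY_NAMES)]


# ---------------------------------------------------------------------------
# decomposable-model machinery


@dataclass
class CliqueDecomposition:
    """Chordal cover of a pathway with an ordered clique/separator sequence.

    The sequence satisfies the running-intersection property, so the cliques
    support closed-form decomposable Gaussian-graphical-model estimation.
    """

    graph: nx.Graph
    cliques: list[frozenset]
    separators: list[frozenset]

    @property
    def max_clique_size(self) -> int:
        return max((len(c) for c in self.cliques), default=0)


def _break_cycles(D: nx.DiGraph, pathway_id: str) -> nx.DiGraph:
    """Remove the lexicographically-last edge of each directed cycle."""
    D = D.copy()
    removed = []
    while True:
        try:
            cycle = nx.find_cycle(D, orientation="original")
        except nx.NetworkXNoCycle:
            break
        edge = max((u, v) for u, v, *_ in cycle)
        D.remove_edge(*edge)
        removed.append(edge)
    if removed:
        logger.info("%s: removed %d edge(s) to break directed cycles", pathway_id, len(removed))
    return D


def _min_fill_triangulate(G: nx.Graph) -> nx.Graph:
    """Deterministic min-fill triangulation (lexicographic tie-break)."""
    H = G.copy()
    chordal = G.copy()
    while H:
        best, best_fill = None, None
        for v in sorted(H.nodes):
            nbrs = list(H.neighbors(v))
            fill = [
                (a, b)
                for a, b in itertools.combinations(sorted(nbrs), 2)
                if not H.has_edge(a, b)
            ]
            if best_fill is None or len(fill) < len(best_fill):
                best, best_fill = v, fill
        for a, b in best_fill:
            H.add_edge(a, b)
            chordal.add_edge(a, b)
        H.remove_node(best)
    return chordal


def _rip_order(chordal: nx.Graph) -> tuple[list[frozenset], list[frozenset]]:
    """Order maximal cliques to satisfy the running-intersection property."""
    cliques = [frozenset(c) for c in nx.chordal_graph_cliques(chordal)]
    if not cliques:
        return [], []
    J = nx.Graph()
    J.add_nodes_from(range(len(cliques)))
    for i, j in itertools.combinations(range(len(cliques)), 2):
        w = len(cliques[i] & cliques[j])
        if w > 0:
            J.add_edge(i, j, weight=w)
    tree = nx.maximum_spanning_tree(J) if J.number_of_edges() else J
    order: list[int] = []
    seen: set[int] = set()
    # deterministic traversal: start from the clique with the smallest sorted label
    for root in sorted(range(len(cliques)), key=lambda i: sorted(cliques[i])):
        if root in seen:
            continue
        for node in nx.bfs_tree(tree, root):
            if node not in seen:
                seen.add(node)
                order.append(node)
    ordered = [cliques[i] for i in order]
    separators = []
    covered: set = set()
    for c in ordered:
        separators.append(frozenset(c & covered))
        covered |= c
    return ordered, separators


def decompose_to_cliques(g: PathwayGraph, measured_genes: Iterable[str]) -> CliqueDecomposition:
    """Moralize, triangulate and decompose the measured part of a pathway.

    Directed cycles are first broken (lexicographically-last edge of each
    cycle removed); the moral graph marries co-parents and drops directions;
    min-fill triangulation then yields a chordal graph whose maximal cliques
    are emitted in running-intersection order.
    """
    measured = set(measured_genes) & set(g.genes)
    D = nx.DiGraph()
    D.add_nodes_from(measured)
    U = nx.Graph()
    U.add_nodes_from(measured)
    for e in g.edges:
        if e.source not in measured or e.target not in measured:
            continue
        if e.directed:
            D.add_edge(e.source, e.target)
        else:
            U.add_edge(e.source, e.target)
    D = _break_cycles(D, g.pathway_id)
    moral = nx.Graph()
    moral.add_nodes_from(measured)
    moral.add_edges_from(D.edges)
    moral.add_edges_from(U.edges)
    for v in D.nodes:
        parents = sorted(D.predecessors(v))
        moral.add_edges_from(itertools.combinations(parents, 2))
    chordal = _min_fill_triangulate(moral)
    cliques, separators = _rip_order(chordal)
    return CliqueDecomposition(chordal, cliques, separators)


def measured_components(
    g: PathwayGraph, measured_genes: Iterable[str]
) -> list[tuple[str, ...]]:
    """Weakly-connected components of the measured-gene induced subgraph,
    sorted by decreasing size then lexicographic first gene."""
    measured = set(measured_genes) & set(g.genes)
    U = nx.Graph()
    U.add_nodes_from(measured)
    for e in g.edges:
        if e.source in measured and e.target in measured:
            U.add_edge(e.source, e.target)
    comps = [tuple(sorted(c)) for c in nx.connected_components(U)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


# ---------------------------------------------------------------------------
# motifs


@dataclass(frozen=True)
class MotifInstance:
    genes: frozenset
    isomorphism_class: str
    size: int


def _canonical_form(D: nx.DiGraph, nodes: Sequence[str]) -> str:
    """Canonical certificate of a small induced digraph: minimal adjacency
    bitstring over all node permutations (feasible for k <= 5)."""
    k = len(nodes)
    best = None
    for perm in itertools.permutations(range(k)):
        relabel = {nodes[i]: perm[i] for i in range(k)}
        bits = 0
        for u, v in D.edges:
            bits |= 1 << (relabel[u] * k + relabel[v])
        if best is None or bits < best:
            best = bits
    return f"{k}:{best:0{k * k}b}"


def enumerate_motifs(g: PathwayGraph, k: int) -> list[MotifInstance]:
    """All size-``k`` gene subsets whose induced directed subgraph is weakly
    connected, labelled by digraph-isomorphism class (signs ignored)."""
    if k not in (3, 4, 5):
        raise ValueError("motif size must be 3, 4 or 5")
    if g.n_genes < k:
        raise ValueError(f"pathway has fewer than {k} genes")
    D = nx.DiGraph()
    D.add_nodes_from(g.genes)
    for e in g.edges:
        D.add_edge(e.source, e.target)
        if not e.directed:
            D.add_edge(e.target, e.source)
    # restrict the subset scan to connected neighbourhoods
    out = []
    for subset in itertools.combinations(sorted(g.genes), k):
        sub = D.subgraph(subset)
        if sub.number_of_edges() == 0:
            continue
        if not nx.is_weakly_connected(sub):
            continue
        out.append(
            MotifInstance(frozenset(subset), _canonical_form(sub, subset), k)
        )
    return out
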