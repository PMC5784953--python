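# topopath

Topology-based pathway analysis for two-group gene expression studies, with a
controlled benchmarking harness.

Given a log2 expression matrix `X` (genes × samples), group labels
`y ∈ {1, 2}` and a collection of pathway topologies — signed, typed, possibly
directed interaction graphs `G = (V, E)` — each method assigns every pathway a
test statistic and a p-value for the null hypothesis that the pathway's
expression does not differ between the groups. Seven methods that use the
topology in fundamentally different ways are implemented on one shared graph
model:

| method | idea | null model |
|---|---|---|
| `spia` | propagate DEG log fold changes along signed edges, `(I − B)·PF = ΔE`; combine the net accumulation with a hypergeometric over-representation p | gene permutation |
| `prs` | sum DEG \|logFC\| weighted by `1 + #downstream DEGs` | gene permutation |
| `cepa` | DEG sum under six centrality weightings; overall p = min over centralities | gene permutation |
| `tappa` | per-sample Pathway Connectivity Index (signed quadratic form over the adjacency); Mann–Whitney between groups | rank test |
| `topologygsa` | moralize/triangulate the DAG, fit decomposable Gaussian graphical models per group, two-step covariance-then-mean Hotelling `T²` | sample permutation |
| `clipper` | same two-step scheme with James–Stein shrinkage covariances, so it tolerates cliques wider than the sample count | sample permutation |
| `degraph` | project each connected component on its first `k` graph-Laplacian eigenvectors (graph Fourier), Hotelling `T²` with an exact F transform | F distribution |

ORA methods call differentially expressed genes first with an
empirical-Bayes moderated t-test (posterior variance
`s̃² = (d0·s0² + d·s²)/(d0 + d)`, hyperparameters by trigamma moment
matching on `log s²`).

The package also ships a synthetic-data generator (VDX-like log2 cohort:
per-gene means and variances, equicorrelated co-expression blocks, exact
additive perturbations) and the eight controlled experiments used to compare
the methods: sample-size/pathway-size/DEG-threshold sweeps, type-I error under
null relabelings, single-gene/gene-set/motif overexpression influence,
target-pathway ranking, topology ablation and pre-processing contrasts.

## Worked example

```python
import topopath as tp
from topopath.methods import MethodConfig

universe = [f"g{i:05d}" for i in range(1000)]
chain = tp.preprocess_topology(
    next(p for p in tp.toy_pathway_suite(universe=universe) if p.pathway_id == "chain")
)
rep = tp.ex3_single_gene(
    tp.SyntheticConfig(n_genes=1000, n1=60, n2=30, seed=3),
    chain, "spia", deltas=[0.5, 1.0, 2.0], n_datasets=10,
    cfg=MethodConfig(n_permutations=100, seed=1),
)
print(rep.summary["influence"][["target", "proportion", "category"]])
```

prints (the ten genes of an activation cascade, upstream first):

```
target  proportion  category
g00000    0.900000 very high
g00001    0.733333      high
g00002    0.600000      high
g00003    0.500000    medium
g00004    0.333333       low
...
g00009    0.100000  very low
```

`proportion` is the gene's *influence*: the fraction of simulation runs
(pooled over induced shifts and replicate datasets) in which overexpressing
that single gene makes the whole pathway test significant at p < 0.05. For
the propagation-based test the influence decays along the cascade — a gene
perturbs the pathway in proportion to what lies downstream of it — which is
exactly the topological signature that distinguishes these methods from
plain enrichment.

The `examples/` directory has one short script per capability (running all
methods, type-I calibration, influence profiling, topology ablation,
pre-processing conventions); each prints the numbers it computes and a line
on how to read them. A thin CLI mirrors the file-based workflows:
`topopath simulate`, `topopath run`, `topopath experiment ex2|ex7|ex8`,
`topopath report`.

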