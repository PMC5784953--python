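# Methods

This note records the statistical models implemented in `topopath`, the
conventions chosen where the original method descriptions leave room, and
what the synthetic benchmarks do and do not establish.

## Pathway graph model

A pathway is a graph `G = (V, E)` whose vertices are gene products and whose
edges carry a type from a controlled vocabulary and a direction flag. Types
map to signs: activation/expression/phosphorylation → +1,
inhibition/repression/dephosphorylation → −1, binding/association/indirect →
0 (neutral). Raw database pathways may also contain multi-subunit complexes,
gene families and chemical-compound nodes; these are resolved by a
pre-processing convention:

* **GPT** (graphite-style): complexes expand to their member genes joined
  pairwise by neutral undirected edges; family members each inherit the
  family's edges; compound nodes are removed and their incident interactions
  bridged transitively (`A → compound → B` becomes `A → B`, the bridge
  inheriting the type of the constituent edge on the gene side and a
  direction only if both constituents are directed). Compound-only cycles
  are dropped with a warning. The exact bridging rules of the upstream
  curation tools are not published in detail; this is a declared
  approximation and is isolated in one function.
* **MSPT** (method-specific): combined complex/family nodes for the
  score-based methods that historically used them (`prs`, `cepa`); expansion
  *without* within-complex edges for the graph-Fourier test; compound edges
  dropped rather than bridged for the propagation test. A combined node is
  "measured" if any member is; its log fold change is the mean over measured
  members and it is a DEG if any member is.
* **NOGPT**: the same vertex set with every interaction removed — the
  non-topological ablation variant.

Pathways with more than 150 genes or fewer than 2 measured genes are
filtered out. All methods operate on the subgraph induced by the measured
genes; edges through unmeasured genes are not contracted.

## Gene-level statistics

Differential expression uses the empirical-Bayes moderated t-test: gene-wise
pooled variances `s²` with `d` degrees of freedom are shrunk toward a prior
`s0²` with `d0` prior degrees of freedom fitted by moment matching on
`log s²` (digamma/trigamma moments, Newton trigamma inversion; `d0 = ∞` when
the log-variance spread does not exceed chi-square noise). The implementation
reproduces the reference R implementation to machine precision on shared
input (checked in the test suite through `Rscript`). DEGs are called at raw
p < θ, default θ = 0.05; no multiple-testing correction is applied anywhere,
matching the benchmark's convention of raw α for genes and pathways alike.

## The seven pathway tests

**spia.** DEG log fold changes `ΔE` propagate through the signed adjacency
`B[i,j] = sign(j→i)/N_ds(j)` (`N_ds` = signed out-degree); `PF` solves
`(I − B)PF = ΔE` by direct linear solve, and `tA = Σ(PF − ΔE)`. `pPERT` is a
bootstrap: the observed DEG log fold changes are placed on random pathway
positions (values resampled with replacement) and the two-sided tail around
the null median is counted. `pNDE` is the hypergeometric upper tail of the
pathway's DEG count in the measured universe. They combine as
`pG = c − c·ln c`, `c = pNDE·pPERT` (Fisher combination of two uniforms). A
graph with no signed edges has no perturbation component, and `pG = pNDE`.
A numerically singular `I − B` is reported as degenerate, not damped.

**prs.** Score `Σ |logFC(g)|·w(g)` over pathway DEG nodes with
`w(g) = 1 + #{distinct DEG nodes reachable from g}`. The null permutes the
DEG labels (carrying their log fold changes) uniformly over the measured
universe; weights are recomputed per permutation. The score normalised by the
null mean is reported alongside the permutation p-value.

**cepa.** Six node weightings (in/out-degree, betweenness, in/out-reach,
equal weight; reach = longest finite shortest-path distance). Each centrality
gets its own gene-permutation p (random DEG sets of the observed size) and
the pathway p is their **uncorrected minimum**. This deliberately reproduces
the original method's inflated type-I error, which the benchmarks measure.

**tappa.** Per-gene z-scores across all samples; per-sample Pathway
Connectivity Index `PCI = (Σ_{A*ij=1} sgn(z_i)sgn(z_j)√(|z_i z_j|))/|V|`
over the symmetrized adjacency with self-loops (unordered pairs). Groups are
compared with a two-sided Mann–Whitney test (exact when `n ≤ 20` without
ties, tie-corrected normal approximation otherwise). The original
publication's normalisation is not printed in full; per-gene z-scoring is the
declared reconstruction and the main reconstruction risk for this method.

**topologygsa / clipper.** The pathway DAG (directed cycles broken by
removing the lexicographically last edge of each cycle) is moralized,
triangulated with deterministic min-fill (lexicographic tie-break), and its
maximal cliques ordered to satisfy running intersection. The
graph-constrained covariance MLE then has the closed form
`K = Σ_C [S_C⁻¹]⁰ − Σ_S [S_S⁻¹]⁰`. Step 1 tests covariance equality with the
likelihood-ratio statistic `n·logdet Σ̂_pooled − n1·logdet Σ̂1 − n2·logdet Σ̂2`;
step 2 tests means with the pooled-concentration Hotelling `T²` if step 1
accepts (at 0.05), otherwise a Behrens–Fisher form
`d'(Σ̂1/n1 + Σ̂2/n2)⁻¹d`. Both p-values come from sample-label permutation,
evaluated for all permutations in one batched linear-algebra pass.
`topologygsa` uses raw MLE covariances and is not testable unless both
groups have more samples than the largest clique. `clipper` shrinks
off-diagonal covariance entries toward zero with the James–Stein/
Schäfer–Strimmer intensity (estimated per covariance from the variance of
the centred cross-products), so it runs where the raw MLE is singular; with
the intensity forced to zero it reduces exactly to `topologygsa`.

**degraph.** Per measured connected component, the Laplacian `L = D − A` of
the symmetrized unweighted graph is eigendecomposed; samples are projected
onto the `k = max(1, ⌈0.2·m⌉)` smoothest eigenvectors (configurable
fraction), and the classical two-sample Hotelling `T²` is applied in the
projected space with its exact F transform, `F(k, n1+n2−k−1)`. The pathway
p-value Bonferroni-aggregates the component p-values. With no edges every
gene is its own component and the procedure reduces to per-gene t-tests with
Bonferroni; with `k = m` it is rotation-invariant and equals the classical
Hotelling test.

Permutation p-values use `(1 + #{null ≥ observed})/(1 + N)` throughout and
are therefore never exactly zero. The default permutation count is 1000
(reduced in simulation loops; see below), default α = 0.05.

## Synthetic data

The generator emulates a microarray-style tumour cohort on the log2 scale:
per-gene means ~ Normal(7, 2²), per-gene standard deviations
~ |Normal(0.5, 0.25²)| + 0.1, genes in equicorrelated blocks of 20 with
within-block correlation 0.2, an unbalanced 120/60 two-group design and a
2000-gene universe by default — all configurable. Both groups are drawn from
the same distribution; effects are injected afterwards as exact additive
shifts on chosen genes of one group, so perturbation ground truth is exact.
What this generator does **not** emulate: heavy-tailed and probe-level
noise, batch effects, missing values, realistic pathway-correlated
co-expression beyond the block structure, and RNA-seq counts. Benchmarks
passing on these data therefore establish internal statistical behaviour
(calibration, power ordering, topology sensitivity), not performance on any
particular real cohort.

Toy fixtures cover the structures the algorithms care about: a ten-gene
activation cascade, a four-leaf star, a feedback triangle, a co-parent DAG,
complex/family/compound-bridge pathways and a 30-gene random DAG, plus a
20-pathway mixed-size collection (10–30 genes, mean out-degree ≈ 2) for
calibration studies.

## Benchmark design choices and problem sizes

* Null calibration: 20 pathways × 25 relabelings = 500 null tests per
  method, 60/30 samples, 2000-gene universe, 200 permutations.
* Influence scans share base datasets across genes, shifts and methods at a
  matched replicate (a paired design that reduces Monte-Carlo variance) and
  run at 1000 genes, 60/30 samples, 100 permutations, 20 replicates over the
  0.1–2.0 shift grid.
* The sample-size contrast places a 0.3-log2FC shift on 30% of the genes of
  5 of 20 pathways *and* on 30% of background genes. The diffuse background
  keeps pathway DEG enrichment constant in `n`, which is what makes the
  competitive methods' flat response visible while the self-contained
  methods' power grows from 20 to 200 samples.
* Influence categories are half-open bins [0, .2), [.2, .4), [.4, .6),
  [.6, .8), [.8, 1]; dense ranks give tied p-values the same rank and
  increment by one between distinct values; medians use the
  lower-interpolation convention.

## Known limitations

* On very small fixtures the pooled influence curves of the competitive
  univariable tests plateau once the shifted gene is reliably called a DEG
  (the over-representation component stops changing); on a star the
  propagation test plateaus at the hub/leaf mixture level. Rank correlations
  of dose-response curves are tie-sensitive in that regime.
* The connectivity-index test has little single-gene power at desk-scale
  sample sizes: a shift moves both groups' |z| almost symmetrically, so only
  its sign pattern across neighbours carries signal.
* Combined-node aggregation (means over members, any-member DEG calls) is a
  convention; alternatives (max-|t| member, union expression) would change
  the pre-processing contrast quantitatively.
* Cycle-breaking before moralization removes the lexicographically last edge
  of each directed cycle; any DAG-ification is statistically admissible but
  different choices yield different clique structures.
* The experiments driven purely by simulation (`ex1`, `ex3`–`ex6`) are
  library entry points; the CLI wraps the file-based workflows
  (`run`, `simulate`, `experiment ex2|ex7|ex8`, `report`).
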