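"""Single-gene influence profiling on the ten-gene cascade fixture.

Overexpresses each gene of the cascade by 0.5, 1.0 and 2.0 log2 units in 10
replicate datasets and reports, per gene, the fraction of runs in which the
propagation-based test calls the pathway differentially expressed.  Genes at
the top of the cascade (many downstream targets) should score highest.
"""

import topopath as tp
from topopath.methods import MethodConfig

universe = [f"g{i:05d}" for i in range(1000)]
chain = tp.preprocess_topology(
    next(p for p in tp.toy_pathway_suite(universe=universe) if p.pathway_id == "chain")
)
data_cfg = tp.SyntheticConfig(n_genes=1000, n1=60, n2=30, seed=3)

rep = tp.ex3_single_gene(
    data_cfg, chain, "spia", deltas=[0.5, 1.0, 2.0], n_datasets=10,
    cfg=MethodConfig(n_permutations=100, seed=1),
)
infl = rep.summary["influence"].sort_values("proportion", ascending=False)
print(infl[["target", "proportion", "category"]].to_string(index=False))
print("\n'proportion' pools differentially-expressed-pathway calls over all")
print("shifts and replicates; the cascade's upstream genes dominate because")
print("their perturbation propagates to every downstream node.")
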