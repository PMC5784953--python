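"""Pre-processing conventions: expanded complexes vs combined nodes.

A raw pathway with a two-subunit protein complex is converted to a gene-level
graph under the graphite-style convention (subunits expanded and connected)
and under the method-specific alternatives, and the resulting vertex and edge
sets are printed side by side.
"""

import topopath as tp
from topopath.pathways import GPT, MSPT_COMBINED, MSPT_DEGRAPH, MSPT_SPIA

raw = next(p for p in tp.toy_pathway_suite() if p.pathway_id == "complex")
print(f"raw pathway: nodes={[(n.node_id, n.kind, n.members) for n in raw.nodes]}")
for strategy in (GPT, MSPT_DEGRAPH, MSPT_COMBINED, MSPT_SPIA):
    g = tp.preprocess_topology(raw, strategy)
    edges = [(e.source, e.target, e.interaction_type) for e in g.edges]
    print(f"\n{strategy}: genes={list(g.genes)}")
    print(f"  edges={edges}")
print("\nUnder the graphite-style convention the complex subunits appear as")
print("separate genes linked by a neutral binding edge; the combined-node")
print("convention keeps the complex as one unit carrying its member ids.")
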