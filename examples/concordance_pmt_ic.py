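"""Per-edge concordance on a reference tree: PMT and internode certainty.

Builds a 37-gene x 100-tree pooled posterior sample in which one species
tree edge is kept in only 10% of sampled gene trees, then annotates every
internal edge of the species tree with the fraction of the 3,700 pooled
trees containing it (PMT), the strongest incompatible split's frequency,
and the signed internode certainty.
"""

import numpy as np

import cladecord as cc

rng = np.random.default_rng(42)
species = cc.random_tree([f"t{i:02d}" for i in range(12)], rng)

edges = sorted(species.split_masks())
contested = cc.Bipartition(edges[0], species.taxa)
scenario = cc.ConcordanceScenario(
    species,
    n_genes=37,
    trees_per_gene=100,
    edge_concordance={contested: 0.1},
    seed=7,
)
samples, _ = cc.simulate_gene_posteriors(scenario)
merged = cc.merge(samples)
annotated = cc.annotate_reference(species, merged)

print(f"pooled {merged.n_total} trees from {len(samples)} genes\n")
print(annotated.to_dataframe()[["clade", "pmt", "conflict_pmt", "ic"]].to_string())
print(
    "\nThe contested edge shows PMT near 0.1 (it was generated with 10% "
    "concordance); its negative IC means the best conflicting split is the "
    "more frequent one in the pooled sample. Edges at PMT 1.0 / IC 1.0 are "
    "unanimous across genes."
)
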