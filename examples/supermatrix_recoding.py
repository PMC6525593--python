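"""Codon supermatrix preparation and Ser/Ile/Arg ambiguity recoding.

Simulates codon alignments in which two unrelated taxon groups share a
preference for the same serine sub-family (convergent codon usage), builds
the concatenated supermatrix with codon-position partitions, and shows that
ambiguity recoding removes the convergent signal without touching the
amino-acid sequence.
"""

import numpy as np

import cladecord as cc

rng = np.random.default_rng(5)
tree = cc.random_tree([f"s{i:02d}" for i in range(10)], rng)
taxa = list(tree.leaf_labels)
groups = {"west": taxa[:2], "east": taxa[-2:]}

scenario = cc.CodonBiasScenario(
    tree=tree,
    n_genes=3,
    codons_per_gene=200,
    bias_groups=groups,
    family_preference={
        "west": {"S": "TCN", "R": "CGN"},
        "east": {"S": "TCN", "R": "AGR"},
    },
    substitution_rate=0.05,
    seed=1,
)
alignments = cc.simulate_codon_alignment(scenario)
universe = cc.TaxonSet(sorted(taxa))

sm = cc.concatenate(alignments, universe)
aa = cc.concatenate([cc.translate(a) for a in alignments], universe)
print(f"nucleotide supermatrix: {sm.n_taxa} taxa x {sm.n_columns} columns")
print(f"amino-acid supermatrix: {aa.n_taxa} taxa x {aa.n_columns} columns")
print("first partitions:", sm.charset_lines()[:3])

t1, t2 = groups["west"][0], groups["east"][0]


def mismatch(aln):
    s1, s2 = aln.sequences[t1], aln.sequences[t2]
    return sum(x != y for x, y in zip(s1, s2)) / len(s1)


aln = alignments[0]
recoded = cc.ambiguity_recode(aln)
print(f"\nbetween-group mismatch before recoding: {mismatch(aln):.3f}")
print(f"between-group mismatch after  recoding: {mismatch(recoded):.3f}")
assert cc.translate(recoded).sequences == cc.translate(aln).sequences
print(
    "Recoding lowers the apparent divergence between the two groups because "
    "their shared synonymous preferences no longer look like shared history; "
    "translations are identical before and after."
)
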