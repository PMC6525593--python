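"""Synthetic-data generators with the statistical structure the analyses
assume, so every pipeline stage is testable without any external download.

Three generators are provided:

* gene-tree posterior samples with *controlled per-edge concordance* — each
  sampled tree keeps a species-tree edge with probability pi(edge) and
  otherwise replaces it by a random nearest-neighbour-interchange (NNI)
  alternative at that edge, which destroys exactly that split; pi is the
  quantity the PMT statistic estimates, so parameter recovery is direct;
* in-frame codon alignments in which designated (possibly unrelated) taxon
  groups share a preferred synonymous sub-family for the split codon
  families Ser/Ile/Arg, creating the convergent codon-usage signal the
  ambiguity recoding is designed to remove;
* binary characters evolved under a single-gain/multiple-loss (Dollo)
  process on a known tree, with optional masking of tip cells to the
  uncertain state.

The NNI mixture is used instead of a multispecies-coalescent simulation on
purpose: the concordance statistic is a split-frequency summary, and the
mixture gives direct control of the per-edge split frequency under test.
All generators are bit-reproducible given (scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .charmap import ABSENT, PRESENT, UNCERTAIN, CharacterMatrix
from .supermatrix import CodonAlignment
from .taxa import Bipartition, TaxonSet
from .trees import Tree, TreeSample, parse_newick

__all__ = [
    "random_tree",
    "ConcordanceScenario",
    "CodonBiasScenario",
    "DolloScenario",
    "simulate_gene_posteriors",
    "simulate_codon_alignment",
    "simulate_dollo_characters",
]


def random_tree(
    labels: Sequence[str],
    rng: np.random.Generator,
    branch_lengths: bool = False,
) -> Tree:
    """A uniform-ish random binary tree built by random sequential joining."""
    if len(labels) < 2:
        raise ValueError("need at least two labels")
    universe = TaxonSet(sorted(labels))
    parts = [str(lab) for lab in labels]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        merged = f"({parts[i]},{parts[j]})"
        parts = [p for k, p in enumerate(parts) if k not in (i, j)] + [merged]
    newick = parts[0] + ";"
    tree = parse_newick(newick, universe)
    if branch_lengths:
        for edge in tree.dendropy_tree.preorder_edge_iter():
            if edge.head_node.parent_node is not None:
                edge.length = float(rng.exponential(0.1))
    return tree


# ---------------------------------------------------------------------------
# gene-tree posteriors with controlled concordance


@dataclass
class ConcordanceScenario:
    """Study conditions for the merged-posterior concordance analysis.

    Defaults mirror the target study design: 37 genes with 100 post-burnin
    trees each (3,700 pooled trees). ``edge_concordance`` maps species-tree
    bipartitions to their retention probability pi; unlisted edges use
    ``default_concordance``. ``dispersion`` is the probability that a
    sampled tree additionally undergoes one extra random NNI."""

    species_tree: Tree
    n_genes: int = 37
    trees_per_gene: int = 100
    edge_concordance: Mapping[Bipartition, float] = field(default_factory=dict)
    default_concordance: float = 1.0
    dispersion: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.trees_per_gene < 1 or self.n_genes < 1:
            raise ValueError("n_genes and trees_per_gene must be >= 1")
        for pi in list(self.edge_concordance.values()) + [
            self.default_concordance,
            self.dispersion,
        ]:
            if not 0.0 <= pi <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


class _LiteNode:
    """Minimal mutable tree node for fast simulation (cloning a dendropy
    tree per sampled posterior draw dominates runtime otherwise)."""

    __slots__ = ("label", "children", "parent", "mask")

    def __init__(self, label: str | None = None):
        self.label = label
        self.children: list["_LiteNode"] = []
        self.parent: "_LiteNode" | None = None
        self.mask = 0

    def add(self, child: "_LiteNode") -> None:
        child.parent = self
        self.children.append(child)

    def remove(self, child: "_LiteNode") -> None:
        self.children.remove(child)
        child.parent = None


def _lite_from_dendropy(dnode) -> _LiteNode:
    node = _LiteNode(dnode.taxon.label if dnode.is_leaf() else None)
    for ch in dnode.child_nodes():
        node.add(_lite_from_dendropy(ch))
    return node


def _lite_clone(node: _LiteNode) -> _LiteNode:
    out = _LiteNode(node.label)
    out.mask = node.mask
    for ch in node.children:
        out.add(_lite_clone(ch))
    return out


def _lite_fill_masks(node: _LiteNode, taxa: TaxonSet) -> int:
    if node.label is not None:
        node.mask = 1 << taxa.index(node.label)
    else:
        node.mask = 0
        for ch in node.children:
            node.mask |= _lite_fill_masks(ch, taxa)
    return node.mask


def _lite_internal(node: _LiteNode, out: list) -> list:
    for ch in node.children:
        if ch.children:
            out.append(ch)
            _lite_internal(ch, out)
    return out


def _lite_nni(node: _LiteNode, rng: np.random.Generator) -> None:
    """One random NNI across the edge above ``node``: swap a random child
    with a random sibling. Destroys exactly that edge's split; only the
    node's own clade mask changes."""
    parent = node.parent
    siblings = [c for c in parent.children if c is not node]
    if not siblings or len(node.children) < 2:
        return
    b = siblings[int(rng.integers(len(siblings)))]
    a = node.children[int(rng.integers(len(node.children)))]
    parent.remove(b)
    node.remove(a)
    parent.add(a)
    node.add(b)
    node.mask = node.mask & ~a.mask | b.mask


def _lite_to_dendropy(root: _LiteNode, tns, taxon_of) -> "Tree":
    import dendropy

    def build(node: _LiteNode):
        dnode = dendropy.Node()
        if node.label is not None:
            dnode.taxon = taxon_of[node.label]
        for ch in node.children:
            dnode.add_child(build(ch))
        return dnode

    dtree = dendropy.Tree(taxon_namespace=tns)
    dtree.seed_node = build(root)
    return dtree


def simulate_gene_posteriors(
    sc: ConcordanceScenario,
) -> tuple[list[TreeSample], dict]:
    """Generate per-gene posterior samples under the NNI-mixture model.

    Returns the samples and a truth record mapping each species-tree split
    (canonical mask) to its generating concordance pi, for recovery tests.
    """
    taxa = sc.species_tree.taxa
    base = sc.species_tree.dendropy_tree.clone(depth=1)
    if len(base.seed_node.child_nodes()) == 2:
        base.deroot()  # unrooted semantics: avoid degenerate NNIs at a bifurcating root

    species_splits = sorted(Tree(base, taxa).split_masks())
    pi_by_mask = {
        m: float(sc.edge_concordance.get(Bipartition(m, taxa), sc.default_concordance))
        for m in species_splits
    }
    first_bit = taxa.mask_of([taxa[0]])
    full = taxa.full_mask
    tns = base.taxon_namespace
    taxon_of = {t.label: t for t in tns}
    lite_base = _lite_from_dendropy(base.seed_node)
    _lite_fill_masks(lite_base, taxa)

    rng = np.random.default_rng(sc.seed)
    samples: list[TreeSample] = []
    for g in range(sc.n_genes):
        trees: list[Tree] = []
        for _ in range(sc.trees_per_gene):
            root = _lite_clone(lite_base)
            for mask in species_splits:
                pi = pi_by_mask[mask]
                if pi >= 1.0 or rng.random() < pi:
                    continue
                target = None
                for node in _lite_internal(root, []):
                    m = node.mask
                    cm = (full & ~m) if (m & first_bit) else m
                    if cm == mask:
                        target = node
                        break
                if target is not None:
                    _lite_nni(target, rng)
            if sc.dispersion > 0 and rng.random() < sc.dispersion:
                nodes = _lite_internal(root, [])
                if nodes:
                    _lite_nni(nodes[int(rng.integers(len(nodes)))], rng)
            tree = _lite_to_dendropy(root, tns, taxon_of)
            trees.append(Tree(tree, taxa))
        samples.append(TreeSample(gene_id=f"gene{g + 1:03d}", trees=trees))
    truth = {
        "pi": dict(pi_by_mask),
        "n_genes": sc.n_genes,
        "trees_per_gene": sc.trees_per_gene,
        "seed": sc.seed,
    }
    return samples, truth


# ---------------------------------------------------------------------------
# codon alignments with convergent synonymous preference


SYNONYMOUS_FAMILIES: dict[str, dict[str, tuple[str, ...]]] = {
    "S": {"TCN": ("TCA", "TCC", "TCG", "TCT"), "AGY": ("AGC", "AGT")},
    "I": {"ATH": ("ATA", "ATC", "ATT")},
    "R": {"CGN": ("CGA", "CGC", "CGG", "CGT"), "AGR": ("AGA", "AGG")},
}

_OTHER_RESIDUE_CODONS: dict[str, tuple[str, ...]] = {
    "A": ("GCA", "GCC", "GCG", "GCT"),
    "D": ("GAC", "GAT"),
    "E": ("GAA", "GAG"),
    "F": ("TTC", "TTT"),
    "G": ("GGA", "GGC", "GGG", "GGT"),
    "K": ("AAA", "AAG"),
    "L": ("CTA", "CTC", "CTG", "CTT"),
    "N": ("AAC", "AAT"),
    "P": ("CCA", "CCC", "CCG", "CCT"),
    "T": ("ACA", "ACC", "ACG", "ACT"),
    "V": ("GTA", "GTC", "GTG", "GTT"),
}


@dataclass
class CodonBiasScenario:
    """Study conditions for the convergent codon-usage simulation.

    ``bias_groups`` partitions the taxa; ``family_preference`` gives each
    group its preferred synonymous sub-family per target residue (e.g.
    ``{"S": "TCN", "R": "CGN"}``). At target sites a tip draws its codon
    from the preferred sub-family with probability ``family_bias``;
    ``substitution_rate`` is the per-site per-edge replacement probability
    of the underlying amino-acid process."""

    tree: Tree
    n_genes: int = 2
    codons_per_gene: int = 300
    bias_groups: Mapping[str, Sequence[str]] = field(default_factory=dict)
    family_preference: Mapping[str, Mapping[str, str]] = field(default_factory=dict)
    substitution_rate: float = 0.05
    family_bias: float = 0.9
    target_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self):
        taxa = set(self.tree.leaf_labels)
        grouped: list[str] = [t for g in self.bias_groups.values() for t in g]
        if len(grouped) != len(set(grouped)):
            raise ValueError("bias groups overlap")
        stray = [t for t in grouped if t not in taxa]
        if stray:
            raise ValueError(f"bias-group taxa not on the tree: {stray}")
        for group, prefs in self.family_preference.items():
            if group not in self.bias_groups:
                raise ValueError(f"preference for unknown group {group!r}")
            for res, fam in prefs.items():
                if fam not in SYNONYMOUS_FAMILIES.get(res, {}):
                    raise ValueError(f"{fam!r} is not a sub-family of {res!r}")


def simulate_codon_alignment(sc: CodonBiasScenario) -> list[CodonAlignment]:
    """Evolve amino-acid sequences along the tree (independent sites, single
    rate), then realize codons at the tips with group-specific synonymous
    preference at Ser/Ile/Arg sites.

    This is deliberately a simple process — just rich enough to create the
    convergent codon-usage artifact that ambiguity recoding removes."""
    rng = np.random.default_rng(sc.seed)
    residues = sorted(SYNONYMOUS_FAMILIES) + sorted(_OTHER_RESIDUE_CODONS)
    target = sorted(SYNONYMOUS_FAMILIES)
    n_other = len(_OTHER_RESIDUE_CODONS)
    probs = np.array(
        [sc.target_fraction / len(target)] * len(target)
        + [(1 - sc.target_fraction) / n_other] * n_other
    )
    group_of = {
        t: g for g, members in sc.bias_groups.items() for t in members
    }

    dtree = sc.tree.dendropy_tree
    out: list[CodonAlignment] = []
    for g in range(sc.n_genes):
        L = sc.codons_per_gene
        root_seq = rng.choice(residues, size=L, p=probs)
        tip_aa: dict[str, np.ndarray] = {}
        seq_at = {dtree.seed_node: root_seq}
        for node in dtree.preorder_node_iter():
            if node is dtree.seed_node:
                continue
            parent_seq = seq_at[node.parent_node]
            seq = parent_seq.copy()
            hits = np.flatnonzero(rng.random(L) < sc.substitution_rate)
            for site in hits:
                seq[site] = rng.choice(residues, p=probs)
            seq_at[node] = seq
            if node.is_leaf():
                tip_aa[node.taxon.label] = seq

        seqs: dict[str, str] = {}
        for taxon, aas in tip_aa.items():
            prefs = sc.family_preference.get(group_of.get(taxon, ""), {})
            codons = []
            for aa in aas:
                if aa in SYNONYMOUS_FAMILIES:
                    fams = SYNONYMOUS_FAMILIES[aa]
                    pref = prefs.get(aa)
                    if pref is not None and rng.random() < sc.family_bias:
                        pool = fams[pref]
                    else:
                        pool = tuple(c for fam in fams.values() for c in fam)
                else:
                    pool = _OTHER_RESIDUE_CODONS[aa]
                codons.append(pool[int(rng.integers(len(pool)))])
            seqs[taxon] = "".join(codons)
        out.append(CodonAlignment(seqs, f"gene{g + 1:03d}"))
    return out


# ---------------------------------------------------------------------------
# Dollo-evolved binary characters


@dataclass
class DolloScenario:
    """Study conditions for the gene-loss character simulation."""

    tree: Tree
    n_characters: int = 50
    loss_rate: float = 0.05
    uncertainty_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for r in (self.loss_rate, self.uncertainty_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


def simulate_dollo_characters(sc: DolloScenario) -> tuple[CharacterMatrix, dict]:
    """Evolve ``n_characters`` binary characters, each present at the root
    and lost independently on each edge with ``loss_rate`` (losses below a
    loss are unobservable and not counted as events).

    Returns the matrix (with cells masked to uncertain at
    ``uncertainty_rate``) and a truth record with the loss clades and the
    true event count per character."""
    rng = np.random.default_rng(sc.seed)
    dtree = sc.tree.dendropy_tree
    taxa = TaxonSet(sorted(sc.tree.leaf_labels))
    characters = [f"char{i + 1:03d}" for i in range(sc.n_characters)]
    states: dict[tuple[str, str], str] = {}
    truth_events: dict[str, list[tuple[str, ...]]] = {}
    for ch in characters:
        present_at = {dtree.seed_node: True}
        losses: list[tuple[str, ...]] = []
        for node in dtree.preorder_node_iter():
            if node is dtree.seed_node:
                continue
            parent_present = present_at[node.parent_node]
            if parent_present and rng.random() < sc.loss_rate:
                present_at[node] = False
                losses.append(
                    tuple(sorted(lf.taxon.label for lf in node.leaf_iter()))
                )
            else:
                present_at[node] = parent_present
        for lf in dtree.leaf_node_iter():
            state = PRESENT if present_at[lf] else ABSENT
            if sc.uncertainty_rate > 0 and rng.random() < sc.uncertainty_rate:
                state = UNCERTAIN
            states[(lf.taxon.label, ch)] = state
        truth_events[ch] = losses
    cm = CharacterMatrix(taxa, characters, states)
    truth = {
        "events": truth_events,
        "n_events": {ch: len(v) for ch, v in truth_events.items()},
        "seed": sc.seed,
    }
    return cm, truth
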