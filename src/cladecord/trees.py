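"""Tree containers and Newick / NEXUS tree IO.

Trees are stored rooted (at an arbitrary node) but all comparisons go
through unrooted, canonical bipartitions, so rooting and leaf rotation never
affect downstream statistics. Parsing and serialization are delegated to
dendropy; this module adds the shared taxon universe, canonical split
extraction and the per-gene :class:`TreeSample` bookkeeping.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy

from .taxa import Bipartition, TaxonSet

__all__ = [
    "Tree",
    "TreeSample",
    "parse_newick",
    "read_tree_file",
    "bipartitions",
    "compatible",
]


class Tree:
    """A leaf-labelled tree over a :class:`TaxonSet`.

    Wraps a dendropy tree; edge lengths are optional and never required by
    the downstream statistics (Robinson-Foulds comparisons are unweighted).
    ``annotations`` maps canonical split masks to per-edge annotation dicts
    (support values and the like).
    """

    __slots__ = ("_dtree", "taxa", "annotations", "_split_cache")

    def __init__(self, dtree: dendropy.Tree, taxa: TaxonSet):
        self._dtree = dtree
        self.taxa = taxa
        self.annotations: dict[int, dict] = {}
        self._split_cache: frozenset[int] | None = None

    # -- construction -----------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree, universe: TaxonSet | None = None) -> "Tree":
        labels = [lf.taxon.label for lf in dtree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate leaf labels in tree: {dup}")
        if universe is None:
            universe = TaxonSet(sorted(labels))
        else:
            missing = [l for l in labels if l not in universe]
            if missing:
                raise ValueError(f"leaf labels not in taxon universe: {missing}")
        return cls(dtree, universe)

    # -- basic queries -----------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._dtree

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(lf.taxon.label for lf in self._dtree.leaf_node_iter())

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self._dtree.leaf_node_iter())

    def leaf_mask(self) -> int:
        """Bitmask over the universe of the taxa present in this tree."""
        return self.taxa.mask_of(self.leaf_labels)

    # -- splits ------------------------------------------------------------

    def node_masks(self) -> dict:
        """Map dendropy node -> bitmask of the leaves below it (rooted view)."""
        masks: dict = {}
        for node in self._dtree.postorder_node_iter():
            if node.is_leaf():
                masks[node] = 1 << self.taxa.index(node.taxon.label)
            else:
                m = 0
                for ch in node.child_nodes():
                    m |= masks[ch]
                masks[node] = m
        return masks

    def split_masks(self) -> frozenset[int]:
        """Canonical masks of all non-trivial splits (unrooted semantics).

        Cached after first computation; the topology is treated as fixed
        once a tree enters an analysis."""
        if self._split_cache is not None:
            return self._split_cache
        full = self.leaf_mask()
        n = full.bit_count()
        out = set()
        for node, m in self.node_masks().items():
            if node.parent_node is None:
                continue
            k = m.bit_count()
            if k <= 1 or k >= n - 1:
                continue  # trivial
            # canonicalize within the tree's own leaf set, then store the
            # block not containing the universe's first present taxon
            first_bit = full & -full
            if m & first_bit:
                m = full & ~m
            out.add(m)
        self._split_cache = frozenset(out)
        return self._split_cache

    def bipartitions(self) -> set[Bipartition]:
        """Non-trivial bipartitions of the unrooted tree (one per internal
        edge; rooting does not change the result)."""
        if self.leaf_mask() != self.taxa.full_mask:
            raise ValueError("tree does not cover the full taxon universe")
        return {Bipartition(m, self.taxa) for m in self.split_masks()}

    # -- output ------------------------------------------------------------

    def newick(self, include_annotations: bool = False) -> str:
        if include_annotations and self.annotations:
            masks = self.node_masks()
            full = self.leaf_mask()
            first_bit = full & -full
            for node, m in masks.items():
                if node.parent_node is None or node.is_leaf():
                    continue
                cm = (full & ~m) if (m & first_bit) else m
                ann = self.annotations.get(cm)
                if ann:
                    node.label = None
                    node.comments = [",".join(f"{k}={v}" for k, v in ann.items())]
        s = self._dtree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            suppress_item_comments=False,
        ).strip()
        return s

    def clone(self) -> "Tree":
        t = Tree(self._dtree.clone(depth=1), self.taxa)
        t.annotations = {k: dict(v) for k, v in self.annotations.items()}
        return t

    def __repr__(self) -> str:
        return f"Tree({self.n_leaves} leaves)"


@dataclass
class TreeSample:
    """An ordered collection of trees from one source (e.g. one gene's
    posterior sample), sharing a single taxon universe."""

    gene_id: str
    trees: list[Tree]
    source: str | None = None

    def __post_init__(self):
        if self.trees:
            u = self.trees[0].taxa
            for t in self.trees:
                if t.taxa != u:
                    raise ValueError("trees in a sample must share one TaxonSet")

    @property
    def n_sampled(self) -> int:
        return len(self.trees)

    @property
    def taxa(self) -> TaxonSet:
        if not self.trees:
            raise ValueError("empty tree sample has no taxon universe")
        return self.trees[0].taxa

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


# ---------------------------------------------------------------------------
# parsing


def _parse_dendropy(text: str, schema: str) -> dendropy.TreeList:
    try:
        return dendropy.TreeList.get(
            data=text, schema=schema, preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several exception types
        raise ValueError(f"could not parse {schema} tree data: {exc}") from exc


def parse_newick(text: str, universe: TaxonSet | None = None) -> Tree:
    """Parse a single Newick statement into a :class:`Tree`.

    Branch lengths are preserved to full precision; quoted labels and
    underscores are taken verbatim (no underscore-to-space conversion).
    """
    if not text.strip():
        raise ValueError("empty Newick string")
    trees = _parse_dendropy(text, "newick")
    if len(trees) != 1:
        raise ValueError(f"expected exactly one Newick statement, got {len(trees)}")
    return Tree.from_dendropy(trees[0], universe)


def read_tree_file(
    path: str | Path,
    format: str = "newick",
    universe: TaxonSet | None = None,
    gene_id: str | None = None,
) -> TreeSample:
    """Read all trees from a Newick or NEXUS-TREES file into a
    :class:`TreeSample`.

    NEXUS TRANSLATE tables are resolved by dendropy. All trees must share
    one leaf set; a mismatch raises an error listing the symmetric
    difference. ``gene_id`` defaults to the file stem.
    """
    path = Path(path)
    schema = {"newick": "newick", "nexus-trees": "nexus", "nexus": "nexus"}.get(format)
    if schema is None:
        raise ValueError(f"unknown tree file format {format!r}")
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"empty tree file: {path}")
    dtrees = _parse_dendropy(text, schema)
    if len(dtrees) == 0:
        raise ValueError(f"no trees found in {path}")

    leafsets = [frozenset(lf.taxon.label for lf in t.leaf_node_iter()) for t in dtrees]
    ref = leafsets[0]
    for i, ls in enumerate(leafsets[1:], start=2):
        if ls != ref:
            diff = sorted(ls ^ ref)
            raise ValueError(
                f"tree {i} in {path} has a different taxon set; "
                f"symmetric difference: {diff}"
            )
    if universe is None:
        universe = TaxonSet(sorted(ref))
    trees = [Tree.from_dendropy(t, universe) for t in dtrees]
    return TreeSample(gene_id=gene_id or path.stem, trees=trees, source=str(path))


# ---------------------------------------------------------------------------
# functional conveniences


def bipartitions(tree: Tree) -> set[Bipartition]:
    """Non-trivial bipartitions of ``tree`` (one per internal edge)."""
    return tree.bipartitions()


def compatible(a: Bipartition, b: Bipartition) -> bool:
    """True iff the two splits can occur together in one tree."""
    return a.is_compatible_with(b)
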