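"""Taxon universes and canonical bipartitions.

A :class:`TaxonSet` fixes an ordered universe of taxon labels; a
:class:`Bipartition` is a split of that universe induced by removing one
internal edge of an unrooted tree, stored in a canonical form so that splits
can be hashed, counted and compared across trees regardless of rooting or
leaf rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

__all__ = ["TaxonSet", "Bipartition"]


class TaxonSet:
    """An ordered, immutable universe of unique taxon labels.

    The order is fixed at construction and defines the bit positions used by
    :class:`Bipartition` masks. Equality is by label sequence.
    """

    __slots__ = ("_labels", "_index")

    def __init__(self, labels: Iterable[str]):
        labels = tuple(labels)
        if len(set(labels)) != len(labels):
            seen, dups = set(), []
            for lab in labels:
                if lab in seen:
                    dups.append(lab)
                seen.add(lab)
            raise ValueError(f"duplicate taxon labels: {dups}")
        self._labels = labels
        self._index = {lab: i for i, lab in enumerate(labels)}

    @property
    def labels(self) -> tuple[str, ...]:
        return self._labels

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"taxon {label!r} not in universe") from None

    def __contains__(self, label: object) -> bool:
        return label in self._index

    def __len__(self) -> int:
        return len(self._labels)

    def __iter__(self) -> Iterator[str]:
        return iter(self._labels)

    def __getitem__(self, i: int) -> str:
        return self._labels[i]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TaxonSet) and self._labels == other._labels

    def __hash__(self) -> int:
        return hash(self._labels)

    def __repr__(self) -> str:
        return f"TaxonSet({len(self)} taxa)"

    @property
    def full_mask(self) -> int:
        return (1 << len(self._labels)) - 1

    def mask_of(self, labels: Iterable[str]) -> int:
        """Bitmask with the bit of every given label set."""
        m = 0
        for lab in labels:
            m |= 1 << self.index(lab)
        return m

    def labels_of(self, mask: int) -> tuple[str, ...]:
        """Labels whose bits are set in ``mask``, in universe order."""
        return tuple(lab for i, lab in enumerate(self._labels) if mask >> i & 1)


@dataclass(frozen=True)
class Bipartition:
    """A canonical split of a :class:`TaxonSet` into two non-empty blocks.

    The stored ``mask`` is the block that does *not* contain the first taxon
    of the universe; this makes the representation unique per split and
    stable for hashing and set arithmetic.
    """

    mask: int
    universe: TaxonSet = field(compare=True)

    def __post_init__(self):
        full = self.universe.full_mask
        if not 0 < self.mask < full:
            raise ValueError("both blocks of a bipartition must be non-empty")
        if self.mask & 1:  # canonical side excludes taxon 0
            object.__setattr__(self, "mask", full & ~self.mask)

    @classmethod
    def from_labels(cls, labels: Iterable[str], universe: TaxonSet) -> "Bipartition":
        return cls(universe.mask_of(labels), universe)

    @property
    def complement_mask(self) -> int:
        return self.universe.full_mask & ~self.mask

    @property
    def is_trivial(self) -> bool:
        """True for singleton|rest splits (uninformative about topology)."""
        n = len(self.universe)
        k = self.mask.bit_count()
        return k <= 1 or k >= n - 1

    def side_of(self, label: str) -> bool:
        """True if ``label`` lies in the stored (canonical) block."""
        return bool(self.mask >> self.universe.index(label) & 1)

    def smaller_block(self) -> tuple[str, ...]:
        """Labels of the smaller block (canonical block on ties)."""
        n = len(self.universe)
        if self.mask.bit_count() * 2 <= n:
            return self.universe.labels_of(self.mask)
        return self.universe.labels_of(self.complement_mask)

    def is_compatible_with(self, other: "Bipartition") -> bool:
        """Two splits are compatible iff one of the four pairwise block
        intersections is empty, i.e. both can occur in a single tree."""
        if self.universe != other.universe:
            raise ValueError("bipartitions on different taxon universes")
        a, b = self.mask, other.mask
        full = self.universe.full_mask
        return (
            a & b == 0
            or a & ~b & full == 0
            or ~a & b & full == 0
            or ~a & ~b & full == 0
        )

    def __repr__(self) -> str:
        small = self.smaller_block()
        shown = ",".join(small[:4]) + ("..." if len(small) > 4 else "")
        return f"Bipartition({shown} | rest)"


def compatible(a: Bipartition, b: Bipartition) -> bool:
    """Functional alias for :meth:`Bipartition.is_compatible_with`."""
    return a.is_compatible_with(b)
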