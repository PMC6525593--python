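"""Merged-posterior clade support (PMT) and internode certainty (IC).

The concordance statistic pools post-burnin posterior tree samples from many
genes into one merged sample and asks, for every internal edge of a
reference tree: what fraction of the pooled trees contains that split (PMT,
proportion of merged trees), what the most frequent *incompatible* split is,
and how decisively the merged sample favours one over the other (signed
internode certainty).

IC uses the two-split form: with focal frequency f and strongest-conflict
frequency c, let p1 = f/(f+c) and p2 = c/(f+c); the magnitude is

    1 + p1*log2(p1) + p2*log2(p2)        (0*log 0 == 0)

i.e. one minus the binary entropy of the relative frequencies, and the sign
is negative when the conflicting split outnumbers the focal one.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .taxa import Bipartition, TaxonSet
from .trees import Tree, TreeSample

__all__ = [
    "MergedSample",
    "CladeSupport",
    "sample_postburnin",
    "merge",
    "pmt",
    "strongest_conflict",
    "internode_certainty",
    "annotate_reference",
    "AnnotatedReference",
]


def sample_postburnin(
    sample: TreeSample, n: int, burnin_fraction: float, seed: int
) -> TreeSample:
    """Draw ``n`` trees uniformly without replacement from the post-burnin
    portion of a posterior sample.

    The first ``floor(burnin_fraction * N)`` trees are discarded as burn-in
    (per MCMC run; pass 0.0 when the file already holds post-burnin trees
    only). Selection is reproducible under ``seed`` and preserves the
    original within-run order. Drawing exactly the post-burnin count
    returns the full post-burnin set.
    """
    if not 0.0 <= burnin_fraction < 1.0:
        raise ValueError("burnin_fraction must be in [0, 1)")
    total = sample.n_sampled
    start = math.floor(burnin_fraction * total)
    post = sample.trees[start:]
    if n > len(post):
        raise ValueError(
            f"requested {n} trees but only {len(post)} post-burnin trees remain "
            f"of {total} (burn-in {start})"
        )
    if n == len(post):
        chosen = post
    else:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(post), size=n, replace=False))
        chosen = [post[i] for i in idx]
    return TreeSample(gene_id=sample.gene_id, trees=list(chosen), source=sample.source)


class MergedSample:
    """Pooled per-gene posterior trees with split-occurrence counts.

    ``split_counts`` tallies, for every canonical non-trivial split, the
    number of pooled trees whose split set contains it (each tree counts a
    split at most once).
    """

    def __init__(self, samples: Sequence[TreeSample]):
        if not samples:
            raise ValueError("cannot merge zero samples")
        universe = samples[0].taxa
        for s in samples:
            if s.taxa != universe:
                raise ValueError(
                    f"taxon-set mismatch: sample {s.gene_id!r} does not share "
                    "the common universe"
                )
        self.taxa: TaxonSet = universe
        self.trees: list[Tree] = []
        self.gene_of: list[str] = []
        self.tree_splits: list[frozenset[int]] = []
        counts: Counter[int] = Counter()
        for s in samples:
            for t in s.trees:
                splits = t.split_masks()
                self.trees.append(t)
                self.gene_of.append(s.gene_id)
                self.tree_splits.append(splits)
                counts.update(splits)
        self.split_counts: dict[int, int] = dict(counts)

    @property
    def n_total(self) -> int:
        return len(self.trees)

    def count(self, focal: Bipartition) -> int:
        if focal.universe != self.taxa:
            raise ValueError("bipartition is not on the merged sample's universe")
        return self.split_counts.get(focal.mask, 0)

    def pmt(self, focal: Bipartition) -> float:
        """Proportion of merged trees whose split set contains ``focal``."""
        return self.count(focal) / self.n_total

    def strongest_conflict(
        self, focal: Bipartition
    ) -> tuple[Bipartition, float] | None:
        """The most frequent counted split incompatible with ``focal`` and
        its merged-sample frequency; ``None`` when every counted split is
        compatible. Frequency ties break to the numerically smallest
        canonical mask for reproducibility."""
        if focal.universe != self.taxa:
            raise ValueError("bipartition is not on the merged sample's universe")
        best_mask, best_count = None, 0
        for mask, cnt in self.split_counts.items():
            if cnt < best_count or (cnt == best_count and best_mask is not None and mask > best_mask):
                continue
            other = Bipartition(mask, self.taxa)
            if not focal.is_compatible_with(other):
                best_mask, best_count = mask, cnt
        if best_mask is None:
            return None
        return Bipartition(best_mask, self.taxa), best_count / self.n_total


def merge(samples: Sequence[TreeSample]) -> MergedSample:
    """Pool per-gene tree samples into one :class:`MergedSample`."""
    return MergedSample(samples)


def pmt(merged: MergedSample, focal: Bipartition) -> float:
    return merged.pmt(focal)


def strongest_conflict(
    merged: MergedSample, focal: Bipartition
) -> tuple[Bipartition, float] | None:
    return merged.strongest_conflict(focal)


def internode_certainty(focal_freq: float, conflict_freq: float | None) -> float:
    """Signed two-split internode certainty.

    ``conflict_freq`` is the frequency of the strongest incompatible split;
    pass ``None`` when no conflicting split occurs (IC = 1 for any focal
    frequency > 0). The sign is negative when the conflict outnumbers the
    focal split. The degenerate case f = 0 with a conflict present gives
    -1 (certain conflict); f = 0 with no conflict is reported as 0 by
    :func:`annotate_reference` and rejected here.
    """
    f = float(focal_freq)
    if f < 0 or (conflict_freq is not None and conflict_freq < 0):
        raise ValueError("frequencies must be nonnegative")
    if conflict_freq is None:
        if f <= 0:
            raise ValueError("IC undefined for zero focal frequency and no conflict")
        return 1.0
    c = float(conflict_freq)
    tot = f + c
    if tot <= 0:
        raise ValueError("IC undefined when both frequencies are zero")
    p1, p2 = f / tot, c / tot
    h = 0.0
    for p in (p1, p2):
        if p > 0:
            h += p * math.log2(p)
    magnitude = 1.0 + h
    # guard tiny negative round-off at p1 == p2
    magnitude = max(magnitude, 0.0)
    return -magnitude if c > f else magnitude


@dataclass(frozen=True)
class CladeSupport:
    """Per-edge concordance summary on a reference tree."""

    focal: Bipartition
    pmt: float
    conflict: Bipartition | None
    conflict_pmt: float
    ic: float
    degenerate: bool = False  # focal never observed and no conflict either


@dataclass
class AnnotatedReference:
    """A reference tree with per-edge :class:`CladeSupport` annotations."""

    tree: Tree
    supports: list[CladeSupport]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.supports):
            rows.append(
                {
                    "edge": i,
                    "clade": ";".join(s.focal.smaller_block()),
                    "pmt": s.pmt,
                    "conflict": ";".join(s.conflict.smaller_block()) if s.conflict else "",
                    "conflict_pmt": s.conflict_pmt,
                    "ic": s.ic,
                    "degenerate": s.degenerate,
                }
            )
        return pd.DataFrame(rows)

    def newick(self) -> str:
        return self.tree.newick(include_annotations=True)


def annotate_reference(reference: Tree, merged: MergedSample) -> AnnotatedReference:
    """Attach PMT, strongest-conflict PMT and signed IC to every internal
    edge of ``reference``, computed against ``merged``.

    Edges are reported in a deterministic order (sorted canonical masks).
    """
    if reference.taxa != merged.taxa:
        raise ValueError("reference tree and merged sample use different universes")
    annotated = reference.clone()
    supports: list[CladeSupport] = []
    for mask in sorted(reference.split_masks()):
        focal = Bipartition(mask, merged.taxa)
        f = merged.pmt(focal)
        conflict = merged.strongest_conflict(focal)
        if conflict is None:
            if f > 0:
                cs = CladeSupport(focal, f, None, 0.0, 1.0)
            else:
                cs = CladeSupport(focal, 0.0, None, 0.0, 0.0, degenerate=True)
        else:
            cb, c = conflict
            cs = CladeSupport(focal, f, cb, c, internode_certainty(f, c))
        supports.append(cs)
        annotated.annotations[mask] = {
            "pmt": f"{cs.pmt:.6g}",
            "ic": f"{cs.ic:.6g}",
            "conflict_pmt": f"{cs.conflict_pmt:.6g}",
        }
    return AnnotatedReference(annotated, supports)
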