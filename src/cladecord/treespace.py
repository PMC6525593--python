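"""Robinson-Foulds treespace and its Euclidean embedding.

Posterior tree clouds from many genes are compared with the unweighted
Robinson-Foulds metric (size of the symmetric difference between the two
trees' non-trivial split sets), the resulting distance matrix is made
Euclidean-embeddable with Cailliez's additive constant, and embedded in 2-3
dimensions by classical (Torgerson) metric MDS so that per-gene clouds and
the concatenated-analysis trees can be inspected in one picture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .trees import Tree, TreeSample
from .concordance import sample_postburnin

__all__ = [
    "DistanceMatrix",
    "Embedding",
    "rf_distance",
    "distance_matrix",
    "cailliez",
    "classical_mds",
    "treespace_report",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with per-tree provenance labels."""

    values: np.ndarray
    labels: list[str]
    genes: list[str] | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")
        self.values = v
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count does not match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class Embedding:
    """A k-dimensional MDS configuration with its eigenvalue spectrum."""

    coordinates: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # full spectrum, descending
    k: int
    cailliez_constant: float = 0.0
    labels: list[str] | None = None
    genes: list[str] | None = None


def rf_distance(a: Tree, b: Tree) -> int:
    """Unweighted Robinson-Foulds distance: |splits(a) Δ splits(b)|."""
    if a.taxa != b.taxa or a.leaf_mask() != b.leaf_mask():
        raise ValueError("trees must share an identical leaf set")
    return len(a.split_masks() ^ b.split_masks())


def distance_matrix(
    trees: Sequence[Tree],
    labels: Sequence[str] | None = None,
    genes: Sequence[str] | None = None,
) -> DistanceMatrix:
    """All pairwise unweighted RF distances.

    Identical topologies are detected by their hashed split sets, so the
    quadratic pair loop runs over unique topologies only; duplicates are
    kept in the output (they carry frequency information for the MDS cloud).
    """
    if not trees:
        raise ValueError("no trees given")
    ref_taxa, ref_leaf = trees[0].taxa, trees[0].leaf_mask()
    splitsets: list[frozenset[int]] = []
    for t in trees:
        if t.taxa != ref_taxa or t.leaf_mask() != ref_leaf:
            raise ValueError("all trees must share an identical leaf set")
        splitsets.append(t.split_masks())

    uniq: dict[frozenset[int], int] = {}
    idx_of = np.empty(len(trees), dtype=int)
    for i, s in enumerate(splitsets):
        idx_of[i] = uniq.setdefault(s, len(uniq))
    uniq_sets = list(uniq.keys())
    m = len(uniq_sets)
    du = np.zeros((m, m))
    for i in range(m):
        si = uniq_sets[i]
        for j in range(i + 1, m):
            du[i, j] = du[j, i] = len(si ^ uniq_sets[j])
    values = du[np.ix_(idx_of, idx_of)]
    if labels is None:
        labels = [f"tree_{i}" for i in range(len(trees))]
    return DistanceMatrix(values, list(labels), list(genes) if genes else None)


def cailliez(d: DistanceMatrix) -> tuple[DistanceMatrix, float]:
    """Smallest additive constant c such that d_ij + c (i != j) is
    Euclidean-embeddable, via the largest eigenvalue of the standard
    2n x 2n companion matrix; c = 0 when d is already Euclidean."""
    D = d.values
    n = d.n
    if n < 3:
        return DistanceMatrix(D.copy(), list(d.labels), d.genes), 0.0
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    delta1 = -0.5 * J @ (D * D) @ J
    delta2 = -0.5 * J @ D @ J
    comp = np.zeros((2 * n, 2 * n))
    comp[:n, n:] = 2.0 * delta1
    comp[n:, :n] = -np.eye(n)
    comp[n:, n:] = -4.0 * delta2
    eigvals = scipy.linalg.eigvals(comp)
    c = float(np.max(eigvals.real))
    if c < 1e-8 * max(1.0, D.max()):
        c = 0.0  # within eigenvalue round-off of an already-Euclidean matrix
    out = D + c
    np.fill_diagonal(out, 0.0)
    return DistanceMatrix(out, list(d.labels), d.genes), c


def _gram(d: DistanceMatrix) -> np.ndarray:
    D2 = d.values**2
    n = d.n
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    return -0.5 * J @ D2 @ J


def classical_mds(d: DistanceMatrix, k: int = 2) -> Embedding:
    """Classical (Torgerson) metric MDS of a distance matrix.

    Eigendecomposes the double-centered Gram matrix and scales the top-k
    eigenvectors by sqrt(eigenvalue). Requires at least k strictly positive
    eigenvalues; apply :func:`cailliez` first for non-Euclidean input. The
    sign of each axis is fixed by making its first nonzero coordinate
    positive so plots are reproducible.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    B = _gram(d)
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-9 * max(1.0, abs(evals[0]) if len(evals) else 1.0)
    n_pos = int(np.sum(evals > tol))
    if n_pos == 0 and np.allclose(d.values, 0.0):
        # degenerate cloud of identical trees: everything sits at the origin
        return Embedding(
            coordinates=np.zeros((d.n, k)),
            eigenvalues=evals,
            k=k,
            labels=list(d.labels),
            genes=d.genes,
        )
    if n_pos < k:
        if evals[-1] < -tol:
            raise ValueError(
                f"only {n_pos} positive Gram eigenvalues; the matrix is not "
                f"Euclidean-embeddable in {k} dimensions — apply the Cailliez "
                "correction first"
            )
        # Euclidean but degenerate (configuration of rank < k): pad with zeros
        coords = np.zeros((d.n, k))
        coords[:, :n_pos] = evecs[:, :n_pos] * np.sqrt(evals[:n_pos])
    else:
        coords = evecs[:, :k] * np.sqrt(evals[:k])
    for j in range(k):
        col = coords[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, j] = -col
    return Embedding(
        coordinates=coords,
        eigenvalues=evals,
        k=k,
        labels=list(d.labels),
        genes=d.genes,
    )


def treespace_report(
    samples: Sequence[TreeSample],
    concatenated: TreeSample | None = None,
    k: int = 2,
    n_per_gene: int | None = None,
    burnin_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[Embedding, pd.DataFrame]:
    """Full treespace pipeline: pool per-gene posterior samples (optionally
    subsampling ``n_per_gene`` trees after burn-in), compute the unweighted
    RF distance matrix, apply Cailliez's correction and embed with classical
    MDS.

    Returns the embedding and a tidy table with one row per tree: tree id,
    gene, ``is_concat`` flag (trees from the concatenated analysis, for
    highlighting) and the k coordinates.
    """
    pools: list[TreeSample] = []
    for i, s in enumerate(samples):
        if n_per_gene is not None:
            s = sample_postburnin(s, n_per_gene, burnin_fraction, seed + i)
        pools.append(s)
    trees: list[Tree] = []
    labels: list[str] = []
    genes: list[str] = []
    flags: list[bool] = []
    for s in pools:
        for j, t in enumerate(s.trees):
            trees.append(t)
            labels.append(f"{s.gene_id}#{j}")
            genes.append(s.gene_id)
            flags.append(False)
    if concatenated is not None:
        for j, t in enumerate(concatenated.trees):
            trees.append(t)
            labels.append(f"{concatenated.gene_id}#{j}")
            genes.append(concatenated.gene_id)
            flags.append(True)
    d = distance_matrix(trees, labels, genes)
    d_corr, c = cailliez(d)
    emb = classical_mds(d_corr, k)
    emb.cailliez_constant = c
    table = pd.DataFrame(
        {
            "tree_id": labels,
            "gene": genes,
            "is_concat": flags,
            **{f"dim{j + 1}": emb.coordinates[:, j] for j in range(k)},
        }
    )
    return emb, table
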