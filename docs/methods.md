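# Methods

This note documents the models, conventions and numerical choices behind
`cladecord`, in the order the pipeline uses them.

## Trees, taxon universes and canonical splits

All statistics operate on unrooted bipartitions. A `TaxonSet` fixes an
ordered universe of labels; a split is stored as the bitmask of the block
*not* containing the first taxon, which makes the representation unique,
hashable and invariant to rooting and leaf rotation. Trees are parsed and
written with dendropy (Newick and NEXUS-TREES with TRANSLATE tables);
labels are taken verbatim — no underscore/space conversion — because mixed
conventions in real tree files otherwise silently split one taxon into two.
Polytomies are accepted everywhere and simply contribute fewer splits.
Branch lengths are carried through IO but never used by any statistic
(tree comparison is unweighted throughout).

Split sets are cached per tree after first computation; a tree's topology
is treated as immutable once it enters an analysis.

## Merged-posterior concordance (PMT and IC)

Post-burnin samples are pooled across genes; burn-in is applied per file as
`floor(burnin_fraction · N)` leading trees (pass 0 for files that already
contain only post-burnin trees), and the requested number of trees is drawn
uniformly without replacement under an explicit seed — the seed is required
because reproducibility must be internal when the upstream MCMC seed is
unknown.

For a focal split with merged frequency f, the strongest conflict is the
most frequent counted split incompatible with it (frequency c); frequency
ties break to the numerically smallest canonical mask so reruns are
reproducible. The internode certainty uses the two-split form on relative
frequencies p₁ = f/(f+c), p₂ = c/(f+c):

    |IC| = 1 + p₁ log₂ p₁ + p₂ log₂ p₂        (0·log 0 ≡ 0)

with a negative sign when c > f. Degenerate cases: no conflict and f > 0
gives IC = 1; f = 0 with a conflict gives −1 (this is the formula's limit);
f = 0 with no conflict is reported as IC = 0 with a `degenerate` flag
rather than an error, so fully absent clades still appear in the table. The
all-conflicts variant (ICA) and aggregate tree-certainty scores are out of
scope. A tree "contains" a clade through unrooted bipartition containment,
consistent with the unweighted RF comparisons elsewhere.

Note that IC computed from *rounded* frequencies differs in the third
decimal from IC computed from raw counts (e.g. f=0.007, c=0.062 gives
−0.5264, while the underlying unrounded counts can give a value a few
thousandths away); the implementation always uses raw counts, and the unit
tests pin the closed form on rounded inputs.

## Treespace

Unweighted Robinson–Foulds distance = |splits(a) Δ splits(b)|. The pairwise
matrix is computed over *unique* topologies (hashed split sets) and expanded
back, so clouds with many duplicate trees cost little; duplicates are kept
in the output because they carry frequency information in the MDS picture.

Cailliez's constant is the largest eigenvalue of the standard 2n×2n
companion matrix built from the double-centred first- and second-order
distance matrices; it is added to off-diagonal entries only, and values
within 1e-8·max(d) of zero are clamped to 0 (an already-Euclidean matrix).
Classical (Torgerson) MDS eigendecomposes the double-centred Gram matrix;
coordinates are the top-k eigenvectors scaled by √eigenvalue, centred by
construction. Sign convention: each axis is flipped so its first nonzero
coordinate is positive, making plots reproducible. A non-Euclidean input
with fewer than k positive eigenvalues raises an error that names the
Cailliez correction; a *Euclidean but degenerate* configuration (e.g. all
trees identical, or two point-clusters spanning one dimension) is zero-padded
to k dimensions instead of erroring, since the embedding is exact.

## Supermatrix preparation

Coordinates are 0-based half-open internally; mask files and NEXUS output
use 1-based inclusive ranges as humans write them. Masks are explicit
column-exclusion sets; a gap-fraction helper (`propose_mask`, default >50%
gaps) exists as a convenience but is not a homology assessment. Masking
snaps to codons by default: a codon losing any column is dropped entirely,
keeping the matrix in frame for codon-position partitioning (disabling
snapping turns a codon-splitting mask into an error).

Translation uses NCBI table 11 (bacterial/plastid), configurable by id.
Gapped codons translate to a gap; ambiguity codons translate to their
residue when every IUPAC expansion agrees and to X otherwise; internal stop
codons translate to `*` with a warning carrying taxon and codon index
(plastid annotation artifacts do occur and should not abort a 58-gene run).

Ambiguity recoding replaces every codon of the three amino acids with split
synonymous families by a family-wide IUPAC pattern: Ser (TCN+AGY) → WSN,
Ile (ATH) → ATH, Arg (CGN+AGR) → MGN. The patterns are the minimal IUPAC
cover of each family; WSN and MGN necessarily also cover codons outside the
family (no exact single-pattern cover of TCN∪AGY exists), so the translator
recognises the three patterns *before* the generic ambiguity rule and
decodes them to their residue — the recoding convention is known, so the
translation round-trips exactly and recoding is idempotent. The pattern
table is one module-level mapping (`DEGEN_PATTERNS`) and can be swapped in
a single place if a different recoding convention is preferred.

## Character mapping

Characters are binary (present/absent) with `uncertain` as a free state:
uncertain tips are pruned before any dynamic program, which guarantees that
adding an uncertain tip never increases the minimum event count. Intron
position and cis/trans status travel as per-character metadata; a
trans-splicing gain is modelled as its own binary character (ancestrally
absent, overridable per character) rather than a multistate one, so each
gain is an independent mark on the tree.

Fitch counts use the Sankoff formulation with unit transition costs, which
also yields the exact number of minimal reconstructions (the `ambiguous`
flag is exact, not heuristic) and supports an optional root-state
constraint (the ancestral-presence assumption for gene-content characters).
The reported placement prefers the parent's state on ties — delayed
transformation — which puts events on the stem edges of maximal clades.
Without a root constraint the count is invariant to rooting (tested).

Dollo mapping constrains the root to present and forbids gains: the minimum
is the number of maximal clades whose state-known tips are all absent, with
one loss on each such clade's stem; this placement is unique. Dollo ≥ Fitch
always, and the gap between them separates clean loss histories from
characters that would require reversals.

## Synthetic data

The concordance generator models per-edge discordance directly: each
sampled gene tree keeps species-tree edge e with probability π(e) and
otherwise undergoes one random NNI across e, which destroys exactly that
split and leaves every other split intact — so the marginal split frequency
is π(e) by construction and PMT recovery is a direct parameter-recovery
test. An optional `dispersion` probability adds one extra random NNI per
tree to fatten the clouds. This deliberately is *not* a multispecies
coalescent: the statistic under test is a split frequency, and the NNI
mixture controls it exactly; conclusions about coalescent processes are
outside what these tests show. A bifurcating root is collapsed to a
trifurcation first so NNIs at the root edge are well defined. Default
scenario sizes mirror the target study design (37 genes × 100 trees);
tests and the acceptance script run at 10–20 taxa, where the statistic's
behaviour is size-independent, to stay fast.

The codon generator evolves amino acids along the tree as independent sites
with a single per-edge substitution probability, then realizes codons at
the tips, drawing Ser/Ile/Arg codons from the taxon group's preferred
sub-family with probability `family_bias` (default 0.9). Two unrelated
groups given the same preference therefore look artificially similar at
synonymous positions — the exact artifact ambiguity recoding removes. It is
not a realistic codon model (no rate heterogeneity, no selection, no
indels) and is documented as such; what passing tests show is that the
recoding removes the convergent signal, not that real plastomes evolve this
way.

The Dollo character generator loses each character independently on each
edge with a fixed probability below a present root; losses in already-lost
lineages are unobservable and not counted, so the recorded truth is the
number of *observable* loss events, an upper bound on any parsimony count.

## Problem sizes and seeds

The test suite and `scripts/acceptance.py` use 10–20 taxa, 37×100 tree
pools, 200–300-codon genes and 20 replicate seeds; these sizes were chosen
so each quantity's Monte-Carlo error is well inside its assertion bound
(e.g. 3·√(π(1−π)/3700) for PMT recovery). All randomness flows through
`numpy.random.default_rng` with explicit seeds; derived seeds stay below
2³¹.

## Known limitations

* No tree inference, branch-length estimation or consensus construction:
  reference trees are inputs.
* IC is the two-split form; ICA and tree-certainty aggregates are not
  implemented.
* Non-metric MDS and weighted tree metrics are out of scope.
* The recoding pattern table is a documented reconstruction of the
  published convention, isolated in one mapping precisely so it can be
  replaced if the original recoding script is consulted.
* The character model is binary; true multistate characters must be split
  into presence flags.
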