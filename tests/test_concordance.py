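"""Merged-sample clade support (PMT) and signed internode certainty."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cladecord import (
    Bipartition,
    ConcordanceScenario,
    TaxonSet,
    TreeSample,
    annotate_reference,
    internode_certainty,
    merge,
    parse_newick,
    pmt,
    random_tree,
    sample_postburnin,
    simulate_gene_posteriors,
    strongest_conflict,
)


def _sample(newicks, universe, gene="g"):
    return TreeSample(gene, [parse_newick(s, universe) for s in newicks])


class TestPostburninSampling:
    @pytest.fixture
    def chain(self, rng):
        labels = list("ABCDEF")
        trees = [random_tree(labels, rng) for _ in range(50)]
        return TreeSample("chain", trees)

    def test_burnin_boundary_respected(self, chain):
        out = sample_postburnin(chain, 10, burnin_fraction=0.2, seed=1)
        post = chain.trees[10:]
        assert all(any(t is p for p in post) for t in out.trees)
        assert out.n_sampled == 10

    def test_same_seed_same_selection(self, chain):
        a = sample_postburnin(chain, 10, 0.2, seed=9)
        b = sample_postburnin(chain, 10, 0.2, seed=9)
        assert all(x is y for x, y in zip(a.trees, b.trees))

    def test_exhaustive_draw_keeps_original_order(self, chain):
        out = sample_postburnin(chain, 40, 0.2, seed=0)
        assert all(x is y for x, y in zip(out.trees, chain.trees[10:]))

    def test_insufficient_trees_reported(self, chain):
        with pytest.raises(ValueError, match="40"):
            sample_postburnin(chain, 41, 0.2, seed=0)


class TestMerge:
    def test_study_design_pool_size(self, abcde):
        tree = parse_newick("((A,B),(C,D),E);", abcde)
        samples = [
            TreeSample(f"gene{i}", [tree] * 100) for i in range(37)
        ]
        merged = merge(samples)
        assert merged.n_total == 3700
        ab = Bipartition.from_labels(["A", "B"], abcde)
        assert merged.count(ab) == 3700

    def test_single_tree_counts(self, tree5):
        merged = merge([TreeSample("g", [tree5])])
        assert merged.n_total == 1
        assert set(merged.split_counts.values()) == {1}
        assert set(merged.split_counts) == tree5.split_masks()

    def test_merging_twice_doubles_counts(self, abcde):
        s = _sample(["((A,B),(C,D),E);", "((A,C),(B,D),E);"], abcde)
        once = merge([s])
        twice = merge([s, TreeSample("g2", s.trees)])
        assert twice.n_total == 2 * once.n_total
        assert twice.split_counts == {m: 2 * c for m, c in once.split_counts.items()}

    def test_taxon_set_mismatch_rejected(self, abcde):
        s1 = _sample(["((A,B),(C,D),E);"], abcde)
        other = TaxonSet(list("ABCDF"))
        s2 = TreeSample("g2", [parse_newick("((A,B),(C,D),F);", other)])
        with pytest.raises(ValueError, match="mismatch"):
            merge([s1, s2])


class TestPmtAndConflict:
    @pytest.fixture
    def toy_merged(self, abcde):
        # 10 trees: AB in 3, AC in 4, BC in 3; DE in all 10
        newicks = (
            ["((A,B),(D,E),C);"] * 3
            + ["((A,C),(D,E),B);"] * 4
            + ["((B,C),(D,E),A);"] * 3
        )
        return merge([_sample(newicks, abcde)])

    def test_pmt_direct_count_oracle(self, toy_merged, abcde):
        ab = Bipartition.from_labels(["A", "B"], abcde)
        de = Bipartition.from_labels(["D", "E"], abcde)
        assert pmt(toy_merged, ab) == 0.3
        assert pmt(toy_merged, de) == 1.0
        assert pmt(toy_merged, Bipartition.from_labels(["A", "D"], abcde)) == 0.0

    def test_pmt_counts_are_exact_integers(self, toy_merged, abcde):
        ab = Bipartition.from_labels(["A", "B"], abcde)
        assert pmt(toy_merged, ab) * toy_merged.n_total == toy_merged.count(ab)

    def test_strongest_conflict_matches_exhaustive_scan(self, toy_merged, abcde):
        focal = Bipartition.from_labels(["A", "B"], abcde)
        got, freq = strongest_conflict(toy_merged, focal)
        # independent oracle: scan every counted split
        best = max(
            (
                (c, -m)
                for m, c in toy_merged.split_counts.items()
                if not focal.is_compatible_with(Bipartition(m, abcde))
            ),
        )
        assert got.mask == -best[1]
        assert freq == best[0] / toy_merged.n_total
        assert got == Bipartition.from_labels(["A", "C"], abcde)
        assert freq == 0.4

    def test_unanimous_split_has_no_conflict(self, toy_merged, abcde):
        de = Bipartition.from_labels(["D", "E"], abcde)
        assert strongest_conflict(toy_merged, de) is None

    def test_tie_broken_by_smallest_canonical_mask(self, abcde):
        newicks = ["((A,C),(D,E),B);"] * 3 + ["((B,C),(D,E),A);"] * 3
        merged = merge([_sample(newicks, abcde)])
        focal = Bipartition.from_labels(["A", "B"], abcde)
        got, freq = strongest_conflict(merged, focal)
        bc = Bipartition.from_labels(["B", "C"], abcde)
        ac = Bipartition.from_labels(["A", "C"], abcde)
        assert freq == 0.5
        assert got == min((bc, ac), key=lambda b: b.mask)

    def test_incompatible_counts_cannot_both_exceed_half(self, abcde, rng):
        labels = list("ABCDEFGH")
        trees = [random_tree(labels, rng) for _ in range(40)]
        merged = merge([TreeSample("g", trees)])
        universe = trees[0].taxa
        masks = list(merged.split_counts)
        for i, m1 in enumerate(masks):
            b1 = Bipartition(m1, universe)
            for m2 in masks[i + 1 :]:
                b2 = Bipartition(m2, universe)
                if not b1.is_compatible_with(b2):
                    assert (
                        merged.split_counts[m1] + merged.split_counts[m2]
                        <= merged.n_total
                    )


class TestInternodeCertainty:
    def test_equal_frequencies_give_zero(self):
        assert internode_certainty(0.6, 0.6) == 0.0

    def test_no_conflict_gives_one(self):
        assert internode_certainty(0.3, None) == 1.0
        assert internode_certainty(0.3, 0.0) == 1.0

    def test_certain_conflict_gives_minus_one(self):
        assert internode_certainty(0.0, 0.4) == -1.0

    def test_low_support_high_conflict_closed_form(self):
        # independent oracle: 1 - H2 of the relative counts (7, 62), negated
        import scipy.stats

        expected = -(1.0 - scipy.stats.entropy([7, 62], base=2))
        got = internode_certainty(0.007, 0.062)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(-0.5264, abs=1e-4)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            internode_certainty(0.0, 0.0)

    @given(
        f=st.floats(0, 1, allow_nan=False),
        c=st.floats(0, 1, allow_nan=False),
    )
    @settings(max_examples=300, deadline=None)
    def test_range_and_antisymmetry(self, f, c):
        if f + c == 0:
            return
        ic = internode_certainty(f, c)
        assert -1.0 <= ic <= 1.0
        assert internode_certainty(c, f) == pytest.approx(-ic, abs=1e-12)

    @given(
        c=st.floats(0.05, 1, allow_nan=False),
        f1=st.floats(0.0, 1, allow_nan=False),
        f2=st.floats(0.0, 1, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_strictly_increasing_in_focal_frequency(self, c, f1, f2):
        lo, hi = sorted([f1, f2])
        if hi - lo < 1e-6:
            return
        assert internode_certainty(lo, c) < internode_certainty(hi, c)


class TestAnnotateReference:
    def test_single_tree_sample_gives_unit_support(self, tree5):
        merged = merge([TreeSample("g", [tree5])])
        ann = annotate_reference(tree5, merged)
        assert len(ann.supports) == 2
        assert all(s.pmt == 1.0 and s.ic == 1.0 for s in ann.supports)
        df = ann.to_dataframe()
        assert list(df["pmt"]) == [1.0, 1.0]
        assert "pmt=1" in ann.newick()

    def test_star_reference_has_empty_table(self, abcde):
        star = parse_newick("(A,B,C,D,E);", abcde)
        merged = merge([_sample(["((A,B),(C,D),E);"], abcde)])
        ann = annotate_reference(star, merged)
        assert ann.supports == []
        assert ann.to_dataframe().empty

    def test_recovers_generating_concordance(self, rng):
        species = random_tree([f"s{i}" for i in range(8)], rng)
        edges = sorted(species.split_masks())
        target = {
            Bipartition(m, species.taxa): p
            for m, p in zip(edges[:3], (0.9, 0.5, 0.1))
        }
        sc = ConcordanceScenario(
            species, n_genes=10, trees_per_gene=50, edge_concordance=target, seed=5
        )
        samples, truth = simulate_gene_posteriors(sc)
        merged = merge(samples)
        ann = annotate_reference(species, merged)
        by_mask = {s.focal.mask: s for s in ann.supports}
        for b, p in target.items():
            est = by_mask[b.mask].pmt
            assert abs(est - p) <= 3 * math.sqrt(p * (1 - p) / merged.n_total)

    def test_universe_mismatch_rejected(self, abcde, tree5):
        other = TaxonSet(list("ABCDF"))
        ref = parse_newick("((A,B),(C,D),F);", other)
        merged = merge([TreeSample("g", [tree5])])
        with pytest.raises(ValueError):
            annotate_reference(ref, merged)
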