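"""Robinson-Foulds metric, Cailliez correction and classical MDS."""

import numpy as np
import pytest

from cladecord import (
    DistanceMatrix,
    TreeSample,
    cailliez,
    classical_mds,
    distance_matrix,
    parse_newick,
    random_tree,
    rf_distance,
    treespace_report,
)

from conftest import make_random_trees


def _recon_distances(coords):
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


class TestRfDistance:
    def test_identical_trees_distance_zero(self, tree5):
        assert rf_distance(tree5, tree5) == 0

    def test_five_taxon_example_by_hand(self, abcde):
        a = parse_newick("((A,B),(C,D),E);", abcde)
        b = parse_newick("((A,C),(B,D),E);", abcde)
        # splits(a) = {AB, CD}; splits(b) = {AC, BD}; disjoint -> 4
        assert rf_distance(a, b) == 4

    def test_maximal_distance_is_twice_n_minus_3(self):
        # search deterministically for a pair of split-disjoint binary trees,
        # then the symmetric difference must be 2(n-3)
        rng = np.random.default_rng(17)
        labels = [f"x{i}" for i in range(8)]
        base = random_tree(labels, rng)
        for _ in range(200):
            other = random_tree(labels, np.random.default_rng(int(rng.integers(1 << 31))))
            if not (base.split_masks() & other.split_masks()):
                assert rf_distance(base, other) == 2 * (len(labels) - 3)
                return
        pytest.fail("no split-disjoint pair found in 200 draws")

    def test_leaf_set_mismatch_rejected(self, abcde):
        a = parse_newick("((A,B),(C,D),E);", abcde)
        b = parse_newick("((A,B),C,D);", abcde)  # subset of the universe
        with pytest.raises(ValueError):
            rf_distance(a, b)

    def test_metric_axioms_on_random_triples(self):
        trees = make_random_trees(15, 10, seed=23)
        for a, b, c in zip(trees[::3], trees[1::3], trees[2::3]):
            dab, dba = rf_distance(a, b), rf_distance(b, a)
            assert dab == dba  # symmetry
            assert rf_distance(a, a) == 0  # identity
            assert dab <= rf_distance(a, c) + rf_distance(c, b)  # triangle

    def test_even_values_on_binary_trees(self):
        trees = make_random_trees(8, 9, seed=29)
        for i, a in enumerate(trees):
            for b in trees[i + 1 :]:
                assert rf_distance(a, b) % 2 == 0


class TestDistanceMatrix:
    def test_single_tree_gives_zero_matrix(self, tree5):
        d = distance_matrix([tree5])
        assert d.values.shape == (1, 1)
        assert d.values[0, 0] == 0

    def test_duplicated_trees_give_zero_blocks(self, tree5, abcde):
        other = parse_newick("((A,C),(B,D),E);", abcde)
        d = distance_matrix([tree5, tree5, other, other])
        assert np.all(d.values[:2, :2] == 0)
        assert np.all(d.values[2:, 2:] == 0)
        assert np.all(d.values[:2, 2:] == 4)

    def test_matches_double_loop_oracle(self):
        trees = make_random_trees(10, 10, seed=31)
        d = distance_matrix(trees)
        for i in range(10):
            for j in range(10):
                expected = len(trees[i].split_masks() ^ trees[j].split_masks())
                assert d.values[i, j] == expected

    def test_matches_dendropy_oracle(self):
        import dendropy
        from dendropy.calculate import treecompare

        trees = make_random_trees(6, 12, seed=37)
        newicks = [t.newick() for t in trees]
        tns = dendropy.TaxonNamespace()
        dtrees = [
            dendropy.Tree.get(data=s, schema="newick", taxon_namespace=tns)
            for s in newicks
        ]
        for t in dtrees:
            t.encode_bipartitions()
        d = distance_matrix(trees)
        for i in range(6):
            for j in range(6):
                assert d.values[i, j] == treecompare.symmetric_difference(
                    dtrees[i], dtrees[j]
                )


class TestCailliez:
    def test_three_point_metric_needs_no_constant(self):
        d = DistanceMatrix(
            np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float),
            ["a", "b", "c"],
        )
        _, c = cailliez(d)
        assert c == 0.0

    def test_four_point_obstruction_matches_bisection_oracle(self):
        # equilateral triangle of side 2 with a centre point at distance 1:
        # the circumradius 2/sqrt(3) > 1 makes this non-Euclidean
        vals = np.full((4, 4), 2.0)
        vals[3, :] = vals[:, 3] = 1.0
        np.fill_diagonal(vals, 0.0)
        d = DistanceMatrix(vals, list("abcd"))
        corrected, c = cailliez(d)
        assert c > 0

        def min_gram_eig(cc):
            m = vals + cc
            np.fill_diagonal(m, 0.0)
            n = 4
            J = np.eye(n) - np.full((n, n), 1 / n)
            B = -0.5 * J @ (m**2) @ J
            return np.linalg.eigvalsh(B).min()

        lo, hi = 0.0, 10.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if min_gram_eig(mid) < -1e-12:
                lo = mid
            else:
                hi = mid
        assert c == pytest.approx(hi, abs=1e-6)
        assert np.allclose(corrected.values, np.where(np.eye(4), 0, vals + c))

    def test_constant_scales_with_distances(self):
        vals = np.full((4, 4), 2.0)
        vals[3, :] = vals[:, 3] = 1.0
        np.fill_diagonal(vals, 0.0)
        _, c1 = cailliez(DistanceMatrix(vals, list("abcd")))
        _, c2 = cailliez(DistanceMatrix(3 * vals, list("abcd")))
        assert c2 == pytest.approx(3 * c1, rel=1e-8)

    def test_corrected_gram_matrix_is_psd(self):
        trees = make_random_trees(12, 8, seed=41)
        d = distance_matrix(trees)
        corrected, _ = cailliez(d)
        n = corrected.n
        J = np.eye(n) - np.full((n, n), 1 / n)
        B = -0.5 * J @ (corrected.values**2) @ J
        evals = np.linalg.eigvalsh(B)
        assert evals.min() >= -1e-8 * max(evals.max(), 1.0)


class TestClassicalMds:
    def test_collinear_points_recovered_in_one_dimension(self):
        d = DistanceMatrix(
            np.array([[0, 3, 7], [3, 0, 4], [7, 4, 0]], dtype=float),
            list("abc"),
        )
        emb = classical_mds(d, k=1)
        recon = _recon_distances(emb.coordinates)
        assert np.allclose(recon, d.values, atol=1e-9)

    def test_roundtrip_from_planar_configuration(self, rng):
        pts = rng.normal(size=(12, 2))
        diff = pts[:, None, :] - pts[None, :, :]
        vals = np.sqrt((diff**2).sum(axis=-1))
        d = DistanceMatrix(vals, [str(i) for i in range(12)])
        emb = classical_mds(d, k=2)
        assert np.allclose(_recon_distances(emb.coordinates), vals, atol=1e-9)
        # coordinates are centred
        assert np.allclose(emb.coordinates.mean(axis=0), 0, atol=1e-9)

    def test_regular_simplex_needs_three_dimensions(self):
        vals = np.ones((4, 4)) - np.eye(4)
        d = DistanceMatrix(vals, list("abcd"))
        emb3 = classical_mds(d, k=3)
        assert np.allclose(_recon_distances(emb3.coordinates), vals, atol=1e-9)
        emb2 = classical_mds(d, k=2)
        residual = np.abs(_recon_distances(emb2.coordinates) - vals).max()
        assert residual > 1e-3

    def test_insufficient_positive_eigenvalues_advises_cailliez(self):
        vals = np.full((4, 4), 2.0)
        vals[3, :] = vals[:, 3] = 1.0
        np.fill_diagonal(vals, 0.0)
        with pytest.raises(ValueError, match="[Cc]ailliez"):
            classical_mds(DistanceMatrix(vals, list("abcd")), k=3)

    def test_matches_scikit_bio_pcoa(self, rng):
        from skbio.stats.ordination import pcoa

        pts = rng.normal(size=(10, 3))
        diff = pts[:, None, :] - pts[None, :, :]
        vals = np.sqrt((diff**2).sum(axis=-1))
        d = DistanceMatrix(vals, [str(i) for i in range(10)])
        emb = classical_mds(d, k=3)
        ord_res = pcoa(vals, number_of_dimensions=3)
        ref = ord_res.samples.to_numpy()[:, :3]
        # configurations agree up to per-axis sign
        for j in range(3):
            col, refcol = emb.coordinates[:, j], ref[:, j]
            assert np.allclose(col, refcol, atol=1e-6) or np.allclose(
                col, -refcol, atol=1e-6
            )


class TestTreespaceReport:
    def test_two_concentrated_genes_separate(self):
        rng = np.random.default_rng(43)
        labels = [f"x{i}" for i in range(10)]
        a = random_tree(labels, rng)
        b = None
        for _ in range(300):
            cand = random_tree(labels, rng)
            if not (a.split_masks() & cand.split_masks()):
                b = cand
                break
        assert b is not None
        samples = [
            TreeSample("geneA", [a] * 15),
            TreeSample("geneB", [b] * 15),
        ]
        emb, table = treespace_report(samples, k=2)
        ca = table[table.gene == "geneA"][["dim1", "dim2"]].to_numpy()
        cb = table[table.gene == "geneB"][["dim1", "dim2"]].to_numpy()
        between = np.linalg.norm(ca.mean(axis=0) - cb.mean(axis=0))
        spread = lambda pts: np.linalg.norm(pts - pts.mean(axis=0), axis=1).mean()
        within = max(spread(ca), spread(cb))
        assert between > 5 * max(within, 1e-12)

    def test_identical_trees_collapse_to_origin(self, tree5):
        emb, table = treespace_report([TreeSample("g", [tree5] * 6)], k=2)
        assert np.allclose(emb.coordinates, 0)

    def test_concatenated_cloud_outside_gene_hulls(self):
        from scipy.spatial import Delaunay

        rng = np.random.default_rng(47)
        labels = [f"x{i}" for i in range(12)]
        species = random_tree(labels, rng)
        import cladecord as cc

        sc = cc.ConcordanceScenario(
            species, n_genes=3, trees_per_gene=25, dispersion=0.6, seed=3
        )
        samples, _ = cc.simulate_gene_posteriors(sc)
        distant = None
        for _ in range(500):
            cand = random_tree(labels, rng)
            if not (species.split_masks() & cand.split_masks()):
                distant = cand
                break
        assert distant is not None
        concat = TreeSample("concat", [distant] * 5)
        emb, table = treespace_report(samples, concatenated=concat, k=2)
        concat_pts = table[table.is_concat][["dim1", "dim2"]].to_numpy()
        for gene in ("gene001", "gene002", "gene003"):
            pts = table[table.gene == gene][["dim1", "dim2"]].to_numpy()
            hull = Delaunay(pts)
            assert np.all(hull.find_simplex(concat_pts) < 0)
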