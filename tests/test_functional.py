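import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from parknest import (
    Dendrogram,
    DistanceMatrix,
    MatrixError,
    SiteAttributes,
    gower_distance,
    nodf,
    perm_rows_test,
    tree_nodf,
    upgma,
)

from conftest import make_matrix


def traits_df(rows, columns=("t1", "t2")):
    return pd.DataFrame(rows, columns=list(columns)[: len(rows[0])],
                        index=[f"sp{i}" for i in range(len(rows))])


class TestGower:
    def test_hand_computed_example(self):
        # ranges 20 and 100: d(A,B) = (10/20 + 50/100)/2 = 0.5
        d = gower_distance(traits_df([[10, 50], [20, 100], [30, 150]]))
        assert d.d[0, 1] == pytest.approx(0.5)
        assert d.d[0, 2] == pytest.approx(1.0)
        assert d.d[1, 2] == pytest.approx(0.5)

    def test_identical_trait_vectors_have_zero_distance(self):
        d = gower_distance(traits_df([[5, 7], [5, 7], [6, 8]]))
        assert d.d[0, 1] == 0.0

    def test_single_trait_extremes_give_one(self):
        d = gower_distance(traits_df([[2.0], [9.0]], columns=["t1"]))
        assert d.d[0, 1] == pytest.approx(1.0)

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(0)
        d = gower_distance(traits_df(rng.lognormal(size=(20, 2))))
        assert (d.d >= 0).all() and (d.d <= 1 + 1e-12).all()

    def test_zero_range_trait_dropped(self, caplog):
        import logging

        logging.getLogger("parknest").setLevel(logging.WARNING)
        with caplog.at_level("WARNING", logger="parknest"):
            d = gower_distance(traits_df([[1, 4], [1, 6], [1, 8]]))
        assert any("zero-range" in r.message for r in caplog.records)
        assert d.d[0, 1] == pytest.approx(0.5)  # only t2 left, range 4

    def test_all_zero_range_errors(self):
        with pytest.raises(MatrixError, match="zero range"):
            gower_distance(traits_df([[1, 2], [1, 2]]))

    def test_missing_values_excluded_pairwise(self):
        d = gower_distance(traits_df([[10, np.nan], [20, 100], [30, 150]]))
        assert d.d[0, 1] == pytest.approx(0.5)  # only t1 comparable
        # both traits comparable: (10/20 + 50/50)/2
        assert d.d[1, 2] == pytest.approx(0.75)


class TestUpgma:
    def test_two_tips_get_half_distance_branches(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 2.0], [2.0, 0.0]]))
        t = upgma(d)
        assert t.length[0] == pytest.approx(1.0)
        assert t.length[1] == pytest.approx(1.0)

    def test_hand_example_merge_heights(self):
        dm = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        t = upgma(DistanceMatrix(["A", "B", "C"], dm))
        assert sorted(t.height[3:]) == pytest.approx([1.0, 2.0])
        # C's branch runs from the root (height 2) to the tip
        assert t.length[2] == pytest.approx(2.0)

    def test_cophenetic_reproduces_scipy(self):
        rng = np.random.default_rng(5)
        X = rng.random((10, 3))
        from scipy.spatial.distance import pdist

        d = squareform(pdist(X))
        tree = upgma(DistanceMatrix([f"s{i}" for i in range(10)], d))
        expected = squareform(hierarchy.cophenet(hierarchy.linkage(pdist(X), "average")))
        assert np.allclose(tree.cophenetic().d, expected)

    def test_ultrametric_tips_equidistant_from_root(self):
        rng = np.random.default_rng(6)
        d = gower_distance(traits_df(rng.lognormal(size=(12, 2))))
        t = upgma(d)
        paths = t.tip_paths()
        depths = paths @ t.length
        assert np.allclose(depths, depths[0])

    def test_newick_round_trip_via_biopython(self, tmp_path):
        from io import StringIO

        from Bio import Phylo

        rng = np.random.default_rng(7)
        d = gower_distance(traits_df(rng.lognormal(size=(6, 2))))
        t = upgma(d)
        tree = Phylo.read(StringIO(t.to_newick()), "newick")
        tips = sorted(term.name for term in tree.get_terminals())
        assert tips == sorted(t.tip_labels)
        # total branch length is preserved
        assert tree.total_branch_length() == pytest.approx(t.length.sum())


class TestTreeNodf:
    def test_strict_subset_pair_scores_100(self):
        m = make_matrix([[1, 1], [1, 1], [1, 0]])  # site1's species subset of site0's
        tree = Dendrogram.star(m.species_ids)
        r = tree_nodf(m, tree, site_order=["site0", "site1"])
        assert r.treenodf == pytest.approx(100.0)
        assert r.toponodf == pytest.approx(0.0)

    def test_star_tree_reduces_to_binary_nodf_rows(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            X = (rng.random((6, 10)) < 0.5).astype(int)  # sites x species
            if (X.sum(axis=1) == 0).any():
                continue
            m = make_matrix(X.T)  # species in rows
            tree = Dendrogram.star(m.species_ids)
            order = list(m.site_ids)  # fixed "given" order
            r = tree_nodf(m, tree, site_order=order)
            # binary NODF row component computed over sites-in-rows in the same order
            site_matrix = make_matrix(X)
            n = nodf(site_matrix, ordering="given")
            assert r.treenodf == pytest.approx(n.row_component)
            assert r.toponodf == pytest.approx(0.0, abs=1e-9)

    def test_equal_branch_lengths_pair_contributes_zero(self):
        m = make_matrix([[1, 0], [0, 1]])
        tree = Dendrogram.star(m.species_ids)
        r = tree_nodf(m, tree, site_order=["site0", "site1"])
        assert (r.treenodf, r.s_fraction, r.toponodf) == (0.0, 0.0, 0.0)

    def test_decomposition_additivity(self, small_community):
        m, areas, _, traits = small_community
        tree = upgma(gower_distance(traits))
        r = tree_nodf(m, tree, areas=areas)
        assert abs(r.treenodf - (r.s_fraction + r.toponodf)) < 1e-9
        assert r.s_fraction >= 0 and r.toponodf >= -1e-12

    def test_monotone_containment_adding_species_to_upper_site(self):
        rng = np.random.default_rng(21)
        traits = traits_df(rng.lognormal(size=(12, 2)))
        tree = upgma(gower_distance(traits))
        for seed in range(20):
            r2 = np.random.default_rng(seed)
            X = (r2.random((12, 2)) < 0.5).astype(int)
            X[:, 0] += (X[:, 0] == 0) & (r2.random(12) < 0.3)  # ensure upper not empty
            if X[:, 0].sum() == 0 or X[:, 1].sum() == 0:
                continue
            m = make_matrix(X, species=list(traits.index))
            base = tree_nodf(m, tree, site_order=["site0", "site1"])
            absent = np.flatnonzero(X[:, 0] == 0)
            if absent.size == 0:
                continue
            X2 = X.copy()
            X2[absent[0], 0] = 1
            m2 = make_matrix(X2, species=list(traits.index))
            grown = tree_nodf(m2, tree, site_order=["site0", "site1"])
            assert grown.treenodf >= base.treenodf - 1e-9

    def test_species_missing_from_tree_listed(self):
        m = make_matrix([[1, 1], [1, 0]])
        tree = Dendrogram.star(["sp0", "other"])
        with pytest.raises(MatrixError, match="sp1"):
            tree_nodf(m, tree, site_order=["site0", "site1"])


class TestPermRows:
    def test_p_floor_with_99_permutations(self, areas_for):
        from parknest.synthetic import SyntheticSpec, generate_community, generate_traits

        spec = SyntheticSpec(n_species=20, n_sites=10, theta=1.0, seed=3)
        m, areas, _ = generate_community(spec)
        traits = generate_traits(20, 0.5, seed=3)
        tree = upgma(gower_distance(traits))
        res = perm_rows_test(m, tree, areas, n_perm=99, seed=8)
        assert res.p["treeNODF"] == pytest.approx(0.01)
        assert min(res.p.values()) >= 1 / 100

    def test_single_permutation_tying_observed_gives_p_one(self):
        # identical sites: every ordering scores 0, so the permutation ties
        m = make_matrix([[1, 1], [1, 1]])
        tree = Dendrogram.star(m.species_ids)
        areas = SiteAttributes(pd.Series([10.0, 5.0], index=m.site_ids))
        res = perm_rows_test(m, tree, areas, n_perm=1, seed=0)
        assert res.p["treeNODF"] == 1.0

    def test_reproducible_for_identical_seed(self, small_community):
        m, areas, _, traits = small_community
        tree = upgma(gower_distance(traits))
        a = perm_rows_test(m, tree, areas, n_perm=19, seed=4)
        b = perm_rows_test(m, tree, areas, n_perm=19, seed=4)
        assert a.p == b.p and a.z == b.z

    def test_p_has_add_one_floor(self, small_community):
        m, areas, _, traits = small_community
        tree = upgma(gower_distance(traits))
        res = perm_rows_test(m, tree, areas, n_perm=19, seed=4)
        for comp, p in res.p.items():
            assert 1 / 20 <= p <= 1.0
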