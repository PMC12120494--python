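import numpy as np
import pandas as pd
import pytest

from parknest import (
    CommunityMatrix,
    InsufficientGroupError,
    MatrixError,
    MissingAttributeError,
    SiteAttributes,
    convert_spreadsheet,
    order_matrix,
    read_community_matrix,
    subset_by_group,
    write_community_matrix,
)

from conftest import make_matrix


class TestReadWrite:
    def test_round_trip_preserves_labels_and_cells(self, tmp_path):
        m = make_matrix([[0, 5], [3, 1], [2, 0]])
        path = tmp_path / "m.csv"
        write_community_matrix(m, path)
        back = read_community_matrix(path)
        pd.testing.assert_frame_equal(back.data, m.data)

    def test_orientation_flag_transposes_to_identical_matrix(self, tmp_path):
        m = make_matrix([[0, 5], [3, 1], [2, 0]])
        path = tmp_path / "t.csv"
        m.data.T.to_csv(path)  # sites in rows on disk
        back = read_community_matrix(path, orientation="species_cols")
        pd.testing.assert_frame_equal(back.data, m.data)

    def test_tab_delimited_accepted(self, tmp_path):
        m = make_matrix([[1, 2], [0, 3]])
        path = tmp_path / "m.tsv"
        write_community_matrix(m, path)
        pd.testing.assert_frame_equal(read_community_matrix(path).data, m.data)

    def test_spreadsheet_converter(self, tmp_path):
        m = make_matrix([[4, 0], [1, 2]])
        xlsx = tmp_path / "m.xlsx"
        m.data.to_excel(xlsx)
        csv = convert_spreadsheet(xlsx, tmp_path / "m.csv")
        pd.testing.assert_frame_equal(read_community_matrix(csv).data, m.data)

    def test_duplicate_species_label_names_the_label(self):
        df = pd.DataFrame([[1, 0], [0, 1]], index=["dup", "dup"], columns=["a", "b"])
        with pytest.raises(MatrixError, match="dup"):
            CommunityMatrix(df)

    @pytest.mark.parametrize(
        "cells, message",
        [([[1, -2], [0, 1]], "negative"), ([[1, "x"], [0, 1]], "non-numeric")],
    )
    def test_bad_cells_rejected_naming_the_cell(self, cells, message):
        df = pd.DataFrame(cells, index=["a", "b"], columns=["s1", "s2"])
        with pytest.raises(MatrixError, match=message):
            CommunityMatrix(df)

    def test_marginals_recomputable(self):
        m = make_matrix([[0, 5], [3, 1]])
        assert m.grand_total == 9
        assert m.fill == 3
        assert list(m.species_totals()) == [5, 4]
        assert list(m.site_totals()) == [3, 6]


class TestSiteAttributes:
    def test_positive_areas_required(self):
        with pytest.raises(MatrixError):
            SiteAttributes(pd.Series([10.0, 0.0], index=["a", "b"]))

    def test_relative_area_sums_to_one(self):
        a = SiteAttributes(pd.Series([30.0, 10.0], index=["a", "b"]))
        assert a.relative_area().sum() == pytest.approx(1.0)


class TestSubsetByGroup:
    def test_guild_subset(self, group_table):
        m = make_matrix(np.ones((5, 3), dtype=int))
        sub = subset_by_group(m, group_table, "insectivorous")
        assert sub.species_ids == ["sp0", "sp1"]

    def test_all_removes_waterbirds(self, group_table):
        m = make_matrix(np.ones((5, 3), dtype=int))
        sub = subset_by_group(m, group_table, "all")
        assert sub.n_species == 4 and "sp4" not in sub.species_ids

    def test_small_guilds_rejected(self, group_table):
        m = make_matrix(np.ones((5, 3), dtype=int))
        with pytest.raises(InsufficientGroupError):
            subset_by_group(m, group_table, "nectarivorous")

    def test_too_few_species_rejected(self, group_table):
        m = make_matrix(np.ones((5, 3), dtype=int))
        # only sp2 is a non-waterbird omnivore
        with pytest.raises(InsufficientGroupError, match="omnivorous"):
            subset_by_group(m, group_table, "omnivorous")

    def test_zero_richness_sites_kept(self, group_table):
        cells = np.ones((5, 3), dtype=int)
        cells[[0, 1], 2] = 0  # insectivores absent from site 2
        m = make_matrix(cells)
        sub = subset_by_group(m, group_table, "insectivorous")
        assert sub.n_sites == 3 and sub.site_richness()["site2"] == 0

    def test_unclassified_species_error(self, group_table):
        m = make_matrix(np.ones((6, 2), dtype=int))
        with pytest.raises(MatrixError, match="sp5"):
            subset_by_group(m, group_table, "all")


class TestOrderMatrix:
    def test_marginal_totals_desc(self):
        m = make_matrix([[1, 0], [2, 1], [1, 1]])  # totals 1, 3, 2
        out = order_matrix(m, row_key="marginal_totals_desc", col_key="given")
        assert out.species_ids == ["sp1", "sp2", "sp0"]

    def test_external_attribute_desc(self):
        m = make_matrix([[1, 1, 1], [1, 1, 1]])
        areas = pd.Series([10.0, 300.0, 25.0], index=["site0", "site1", "site2"])
        out = order_matrix(m, row_key="given", col_key="external_attribute_desc",
                           col_attribute=areas)
        assert out.site_ids == ["site1", "site2", "site0"]

    def test_ties_keep_input_order(self):
        m = make_matrix([[1, 1], [2, 0], [0, 2]])  # equal totals everywhere
        out = order_matrix(m)
        assert out.species_ids == ["sp0", "sp1", "sp2"]

    def test_pure_permutation(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.poisson(2, size=(5, 4)))
        out = order_matrix(m)
        assert sorted(out.values.ravel()) == sorted(m.values.ravel())
        assert out.grand_total == m.grand_total
        assert sorted(out.species_totals()) == sorted(m.species_totals())
        assert sorted(out.site_totals()) == sorted(m.site_totals())

    def test_missing_attribute_error(self):
        m = make_matrix([[1, 1], [1, 1]])
        with pytest.raises(MissingAttributeError):
            order_matrix(m, row_key="external_attribute_desc",
                         row_attribute=pd.Series([1.0], index=["sp0"]))
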