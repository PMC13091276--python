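import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from transkingdom.tables import (CountTable, TableError, age_tertiles,
                                 aggregate_by_rank, clr_transform,
                                 prevalence_filter, rare_taxon_filter, rarefy,
                                 read_count_table, relative_abundance,
                                 write_count_table)


class TestCountTable:
    def test_rejects_duplicate_ids(self):
        df = pd.DataFrame([[1, 2], [3, 4]], index=["a", "a"],
                          columns=["t1", "t2"])
        with pytest.raises(TableError, match="a"):
            CountTable(df)

    def test_rejects_non_integer_counts(self):
        df = pd.DataFrame([[1.0, 3.7]], index=["a"], columns=["t1", "t2"])
        with pytest.raises(TableError, match="integer"):
            CountTable(df)

    def test_rejects_negative_counts(self):
        df = pd.DataFrame([[1, -2]], index=["a"], columns=["t1", "t2"])
        with pytest.raises(TableError):
            CountTable(df)

    def test_roundtrip(self, toy_table, tmp_path):
        path = tmp_path / "counts.tsv"
        write_count_table(toy_table, path)
        again = read_count_table(path)
        assert again == toy_table


class TestAggregation:
    def test_sums_within_genus(self, toy_table, toy_taxonomy):
        agg = aggregate_by_rank(toy_table, toy_taxonomy, "genus")
        # tA + tB share genus G1
        assert agg.data.loc["s4", "G1"] == 10
        assert agg.data.loc["s1", "G1"] == 10

    def test_conserves_sample_totals(self, toy_table, toy_taxonomy):
        agg = aggregate_by_rank(toy_table, toy_taxonomy, "genus")
        assert (agg.depths() == toy_table.depths()).all()

    def test_unassigned_pooled_by_parent(self, toy_table, toy_taxonomy):
        agg = aggregate_by_rank(toy_table, toy_taxonomy, "genus")
        assert "unassigned_fY" in agg.taxon_ids

    def test_many_asvs_two_genera(self):
        # 23 + 3 ASVs of two genera collapse to exactly two columns
        cols = [f"d{i}" for i in range(23)] + [f"p{i}" for i in range(3)]
        data = pd.DataFrame([[1] * 26], index=["s1"], columns=cols)
        tax = pd.DataFrame(
            {"kingdom": "Bacteria", "phylum": "Bacillota", "class": "c",
             "order": "o", "family": "f",
             "genus": ["Dialister"] * 23 + ["Phascolarctobacterium"] * 3},
            index=cols)
        agg = aggregate_by_rank(CountTable(data), tax, "genus")
        assert sorted(agg.taxon_ids) == ["Dialister", "Phascolarctobacterium"]
        assert agg.data.loc["s1", "Dialister"] == 23


class TestFilters:
    def test_rare_filter_drops_below_threshold(self):
        # mean depth 100000 -> taxa with total < 100 removed at 0.001
        data = pd.DataFrame(
            [[99_000, 99, 500, 1], [99_301, 0, 99, 0]],
            index=["s1", "s2"], columns=["big", "rare1", "mid", "single"])
        table = CountTable(data)
        out, report = rare_taxon_filter(table, 0.001)
        assert set(out.taxon_ids) == {"big", "mid"}
        assert "single" in report["dropped_taxa"]

    def test_singleton_always_dropped(self):
        data = pd.DataFrame([[5, 1], [5, 0]], index=["s1", "s2"],
                            columns=["keep", "single"])
        out, _ = rare_taxon_filter(CountTable(data), 0.5)
        assert "single" not in out.taxon_ids

    def test_abundant_table_unchanged(self, toy_table):
        out, _ = rare_taxon_filter(toy_table, 0.001)
        assert out == toy_table

    def test_prevalence_strict_boundary(self):
        n = 20
        data = pd.DataFrame(0, index=[f"s{i}" for i in range(n)],
                            columns=["one", "two", "all"])
        data.iloc[0, 0] = 5          # 1/20 < 10% -> removed
        data.iloc[0:2, 1] = 5        # 2/20 = 10%, not < 10% -> kept
        data.loc[:, "all"] = 1
        out, _ = prevalence_filter(CountTable(data), 0.10)
        assert set(out.taxon_ids) == {"two", "all"}

    def test_prevalence_zero_is_identity(self, toy_table):
        out, _ = prevalence_filter(toy_table, 0.0)
        assert out == toy_table

    def test_filters_idempotent(self, toy_table):
        once, _ = prevalence_filter(toy_table, 0.5)
        twice, _ = prevalence_filter(once, 0.5)
        assert once == twice


class TestRarefaction:
    def test_exact_depth_and_bound(self, toy_table):
        out, _ = rarefy(toy_table, 10, seed=1)
        assert (out.depths() == 10).all()
        assert (out.data.to_numpy()
                <= toy_table.data.loc[out.sample_ids].to_numpy()).all()

    def test_insufficient_samples_dropped(self):
        data = pd.DataFrame([[10, 10], [3, 2]], index=["deep", "shallow"],
                            columns=["a", "b"])
        out, report = rarefy(CountTable(data), 10, seed=1)
        assert out.sample_ids == ["deep"]
        assert report["dropped_samples"] == ["shallow"]

    def test_sample_at_depth_unchanged(self):
        data = pd.DataFrame([[4, 6]], index=["s1"], columns=["a", "b"])
        out, _ = rarefy(CountTable(data), 10, seed=0)
        assert (out.data.loc["s1"] == [4, 6]).all()

    def test_marginal_mean_matches_hypergeometric(self):
        # E[rarefied count] = depth * x / total (hypergeometric mean)
        data = pd.DataFrame([[30, 50, 20]], index=["s1"],
                            columns=["a", "b", "c"])
        table = CountTable(data)
        depth = 40
        draws = np.array([rarefy(table, depth, seed=s)[0].data.loc["s1", "a"]
                          for s in range(600)])
        expected = hypergeom(100, 30, depth).mean()
        se = hypergeom(100, 30, depth).std() / np.sqrt(600)
        assert abs(draws.mean() - expected) < 3 * se


class TestTransforms:
    def test_relative_abundance_rows_sum_to_one(self, toy_table):
        rel = relative_abundance(toy_table)
        assert np.allclose(rel.sum(axis=1), 1.0, atol=1e-12)

    def test_relative_abundance_zero_sample_errors(self):
        data = pd.DataFrame([[0, 0]], index=["empty"], columns=["a", "b"])
        with pytest.raises(TableError, match="empty"):
            relative_abundance(CountTable(data))

    def test_clr_rows_sum_to_zero(self, toy_table):
        out = clr_transform(toy_table)
        assert np.allclose(out.sum(axis=1), 0.0, atol=1e-9)

    def test_clr_equal_counts_row_is_zero(self):
        data = pd.DataFrame([[7, 7, 7]], index=["s"], columns=list("abc"))
        out = clr_transform(CountTable(data))
        assert np.allclose(out.to_numpy(), 0.0)

    def test_clr_scale_invariant_without_pseudocount(self):
        x = pd.DataFrame([[1.0, 2.0, 4.0]])
        assert np.allclose(clr_transform(x, 0).to_numpy(),
                           clr_transform(2 * x, 0).to_numpy())


def test_age_tertiles_balanced_on_99():
    ages = pd.Series(np.arange(99) + 20.0)
    tert = age_tertiles(ages)
    assert tert.value_counts().tolist() == [33, 33, 33]
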