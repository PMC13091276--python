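import itertools

import numpy as np
import pandas as pd
import pytest

from transkingdom.abundance import (AbundanceError, ba_ratio, bh_adjust,
                                    da_screen, wilcoxon_rank_sum)
from transkingdom.tables import CountTable


def exact_rank_sum_p(x, y):
    """Enumerate every rank split (no ties) for a two-sided exact p."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    rx = ranks[: len(x)].sum()
    n = len(pooled)
    splits = list(itertools.combinations(range(n), len(x)))
    sums = np.array([ranks[list(s)].sum() for s in splits])
    mean = sums.mean()
    extreme = np.abs(sums - mean) >= abs(rx - mean) - 1e-9
    return extreme.mean()


class TestWilcoxon:
    def test_exact_p_disjoint_triples(self):
        # (1,2,3) vs (4,5,6): 2 of C(6,3)=20 splits as extreme -> p = 0.1
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)
        assert p == pytest.approx(exact_rank_sum_p(
            np.array([1.0, 2, 3]), np.array([4.0, 5, 6])))

    def test_identical_samples_p_one(self):
        _, p = wilcoxon_rank_sum([2, 2, 2], [2, 2, 2])
        assert p == 1.0

    def test_approximation_close_to_exact(self):
        rng = np.random.default_rng(0)
        diffs = []
        for _ in range(20):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            _, p_exact = wilcoxon_rank_sum(x, y)       # n=16 <= 20: exact
            from scipy.stats import mannwhitneyu
            p_approx = mannwhitneyu(x, y, alternative="two-sided",
                                    method="asymptotic")[1]
            diffs.append(abs(p_exact - p_approx))
        assert max(diffs) < 0.02

    def test_empty_sample_errors(self):
        with pytest.raises(AbundanceError):
            wilcoxon_rank_sum([], [1.0])


class TestBH:
    def test_stepup_arithmetic(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_monotone_in_ranks(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=30)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(AbundanceError):
            bh_adjust([0.5, 1.2])


class TestDAScreen:
    def _cohort(self, shift_genus=None, fold=4.0, n=30, seed=0):
        rng = np.random.default_rng(seed)
        genera = [f"g{j}" for j in range(12)]
        base = rng.uniform(2, 8, size=12)
        rows, groups = [], []
        for g, mult in (("a", 1.0), ("b", fold)):
            for _ in range(n):
                lam = base.copy()
                if shift_genus is not None and g == "b":
                    lam[shift_genus] *= mult
                rows.append(rng.poisson(lam * 20))
                groups.append(g)
        ids = [f"s{i}" for i in range(len(rows))]
        table = CountTable(pd.DataFrame(rows, index=ids, columns=genera))
        md = pd.DataFrame({"group": groups,
                           "age": rng.uniform(20, 70, len(rows))}, index=ids)
        return table, md

    def test_spiked_genus_detected(self):
        table, md = self._cohort(shift_genus=3)
        out = da_screen(table, md, "group")
        hit = out[(out["genus"] == "g3") & (out["p_adj"] < 0.05)]
        assert len(hit) == 1
        assert hit.iloc[0]["direction"] < 0  # enriched in group b

    def test_null_has_no_excess_rejections(self):
        rejections = []
        for seed in range(10):
            table, md = self._cohort(shift_genus=None, seed=seed)
            out = da_screen(table, md, "group")
            rejections.append((out["p_adj"] < 0.05).mean())
        assert np.mean(rejections) <= 0.05

    def test_invariant_to_sample_and_taxon_order(self):
        table, md = self._cohort(shift_genus=2)
        out1 = da_screen(table, md, "group")
        rng = np.random.default_rng(3)
        perm = rng.permutation(table.sample_ids)
        cols = rng.permutation(table.taxon_ids)
        shuffled = CountTable(table.data.loc[perm, cols])
        out2 = da_screen(shuffled, md.loc[perm], "group")
        merged = out1.merge(out2, on=["stratum", "comparison", "genus"],
                            suffixes=("_1", "_2"))
        assert np.allclose(merged["p_1"], merged["p_2"])

    def test_small_stratum_skipped_with_reason(self):
        table, md = self._cohort()
        md.loc[md["group"] == "b", "group"] = "a"
        md.iloc[:2, md.columns.get_loc("group")] = "tiny"
        out = da_screen(table, md, "group")
        assert (out["skipped"] != "").any()

    def test_age_tertile_strata(self):
        table, md = self._cohort(shift_genus=1)
        out = da_screen(table, md, "group", strata="age_tertile")
        assert set(out["stratum"]) == {"T1", "T2", "T3"}


class TestBARatio:
    def _fungal(self, rows):
        ids = [f"s{i}" for i in range(len(rows))]
        cols = ["basi1", "basi2", "asco1"]
        table = CountTable(pd.DataFrame(rows, index=ids, columns=cols),
                           kingdom="fungal")
        tax = pd.DataFrame(
            {"kingdom": "Fungi",
             "phylum": ["Basidiomycota", "Basidiomycota", "Ascomycota"],
             "class": "c", "order": "o", "family": "f",
             "genus": cols}, index=cols)
        return table, tax

    def test_cohort_scale_ratio(self):
        table, tax = self._fungal([[33, 33, 32]])
        out = ba_ratio(table, tax)
        assert out.loc["s0", "ratio"] == pytest.approx(66 / 32)

    def test_equal_counts_log_zero(self):
        table, tax = self._fungal([[10, 6, 16]])
        out = ba_ratio(table, tax)
        assert out.loc["s0", "log_ratio"] == pytest.approx(0.0)

    def test_zero_denominator_continuity(self):
        table, tax = self._fungal([[10, 6, 0]])
        out = ba_ratio(table, tax)
        assert out.loc["s0", "ratio"] == pytest.approx(16.5 / 0.5)
        assert bool(out.loc["s0", "flagged"])

    def test_both_zero_undefined(self):
        table, tax = self._fungal([[0, 0, 0]])
        out = ba_ratio(table, tax)
        assert np.isnan(out.loc["s0", "ratio"])
        assert bool(out.loc["s0", "flagged"])
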