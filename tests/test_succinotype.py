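import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from transkingdom.succinotype import (SuccinotypeError, association_tests,
                                      classify_cohort, classify_succinotype,
                                      fisher_exact_2x2, prevalence_summary)
from transkingdom.tables import CountTable


def brute_force_label(nD, nP, hi=0.9, lo=0.1, min_reads=10):
    """Independent re-statement of the dominance rule."""
    if nD + nP < min_reads:
        return "unclassified"
    share = nD / (nD + nP)
    if share > hi:
        return "D"
    if share < lo:
        return "P"
    return "mixed"


class TestClassifyRule:
    @pytest.mark.parametrize("nD,nP,expected", [
        (95, 5, "D"),            # rD = 0.95
        (90, 10, "mixed"),       # rD = 0.90 exactly, strict inequality
        (10, 90, "mixed"),       # rD = 0.10 exactly
        (5, 95, "P"),
        (9, 0, "unclassified"),  # total 9 < 10
        (10, 0, "D"),            # total exactly 10 is classifiable
        (0, 0, "unclassified"),
    ])
    def test_boundary_cases(self, nD, nP, expected):
        assert classify_succinotype(nD, nP) == expected

    def test_negative_counts_error(self):
        with pytest.raises(SuccinotypeError):
            classify_succinotype(-1, 5)

    def test_scaling_never_flips_classified_labels(self):
        for nD, nP in [(95, 5), (5, 95), (50, 50), (7, 2)]:
            base = classify_succinotype(nD, nP)
            for c in (2, 3, 10):
                scaled = classify_succinotype(c * nD, c * nP)
                if base != "unclassified":
                    assert scaled == base


class TestClassifyCohort:
    def test_genus_aggregation_before_rule(self):
        data = pd.DataFrame([[40, 60, 0]], index=["s1"],
                            columns=["d1", "d2", "p1"])
        tax = pd.DataFrame(
            {"kingdom": "Bacteria", "phylum": "Bacillota", "class": "c",
             "order": "o", "family": "f",
             "genus": ["Dialister", "Dialister", "Phascolarctobacterium"]},
            index=["d1", "d2", "p1"])
        calls = classify_cohort(CountTable(data), tax)
        assert calls.loc["s1", "nD"] == 100
        assert calls.loc["s1", "rD"] == 1.0
        assert calls.loc["s1", "label"] == "D"

    def test_subject_priority_clear_over_mixed(self):
        data = pd.DataFrame([[50, 50], [5, 95]], index=["v1", "v2"],
                            columns=["Dialister", "Phascolarctobacterium"])
        subject = pd.Series(["subj1", "subj1"], index=["v1", "v2"])
        calls = classify_cohort(CountTable(data), subject_map=subject)
        assert list(calls.index) == ["subj1"]
        assert calls.loc["subj1", "label"] == "P"

    def test_missing_genera_warns_unclassified(self):
        data = pd.DataFrame([[10, 10]], index=["s1"], columns=["a", "b"])
        with pytest.warns(UserWarning):
            calls = classify_cohort(CountTable(data))
        assert calls.loc["s1", "label"] == "unclassified"

    def test_agreement_with_brute_force_small_grid(self):
        for nD, nP in itertools.product(range(0, 40), range(0, 40)):
            data = pd.DataFrame(
                [[nD, nP]], index=["s"],
                columns=["Dialister", "Phascolarctobacterium"])
            assert (classify_cohort(CountTable(data)).loc["s", "label"]
                    == brute_force_label(nD, nP))


class TestFisher:
    def test_diagonal_table_enumeration(self):
        # margins (5,5,5,5): P(table) summed over tables as extreme
        assert fisher_exact_2x2(5, 0, 0, 5) == pytest.approx(2 / 252)

    def test_uniform_table_p_one(self):
        assert fisher_exact_2x2(1, 1, 1, 1) == pytest.approx(1.0)

    def test_symmetry_under_swaps(self):
        p = fisher_exact_2x2(7, 2, 3, 8)
        assert fisher_exact_2x2(3, 8, 7, 2) == pytest.approx(p)
        assert fisher_exact_2x2(2, 7, 8, 3) == pytest.approx(p)

    def test_empty_margin_convention(self):
        assert fisher_exact_2x2(0, 0, 3, 4) == 1.0

    def test_matches_hypergeometric_enumeration(self):
        """Cross-check against direct hypergeometric enumeration."""
        a, b, c, d = 6, 2, 1, 7
        r1, n1 = a + b, a + c
        n = a + b + c + d
        rv = hypergeom(n, r1, n1)
        p_obs = rv.pmf(a)
        total = sum(rv.pmf(k) for k in range(max(0, n1 - (n - r1)),
                                             min(r1, n1) + 1)
                    if rv.pmf(k) <= p_obs * (1 + 1e-9))
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(total)


class TestAssociations:
    def _calls(self, labels, ids):
        return pd.DataFrame({"nD": 50, "nP": 50, "rD": 0.5,
                             "label": labels},
                            index=pd.Index(ids, name="sample_id"))

    def test_identical_distribution_all_p_one(self):
        ids = [f"s{i}" for i in range(40)]
        labels = (["D"] * 10 + ["P"] * 10) * 2
        md = pd.DataFrame({"group": ["x"] * 20 + ["y"] * 20}, index=ids)
        out = association_tests(self._calls(labels, ids), md, ["group"])
        assert (out["p"].dropna() == 1.0).all()

    def test_bh_adjusted_geq_raw(self):
        rng = np.random.default_rng(0)
        ids = [f"s{i}" for i in range(60)]
        labels = rng.choice(["D", "P", "mixed"], size=60)
        md = pd.DataFrame({"group": rng.choice(["x", "y", "z"], size=60)},
                          index=ids)
        out = association_tests(self._calls(labels, ids), md, ["group"])
        ok = out["p"].notna()
        assert (out.loc[ok, "p_adj"] >= out.loc[ok, "p"] - 1e-12).all()

    def test_enrichment_detected_with_power(self):
        """A strong (odds 5) D-enrichment in one group is flagged at FDR
        0.05 in most simulated cohorts of n = 100."""
        rng = np.random.default_rng(1)
        hits = 0
        n_sim = 25
        for _ in range(n_sim):
            ids = [f"s{i}" for i in range(100)]
            group = np.array(["x"] * 50 + ["y"] * 50)
            labels = []
            for g in group:
                pD = 0.7 if g == "x" else 0.32  # odds ratio ~ 5
                labels.append("D" if rng.random() < pD else "P")
            md = pd.DataFrame({"group": group}, index=ids)
            out = association_tests(self._calls(labels, ids), md, ["group"])
            sig = out[(out["labels"] == "D vs P")
                      & (out["p_adj"] < 0.05)]
            hits += len(sig) > 0
        assert hits / n_sim >= 0.8


def test_prevalence_summary_both_normalisations(small_cohort):
    bact, _, md, _, truth = small_cohort
    calls = classify_cohort(bact)
    prev = prevalence_summary(calls, md["group"])
    assert prev["cohort_fraction"].sum() == pytest.approx(1.0)
    # cohort-normalised group columns sum to the cohort fraction
    of_cohort = [c for c in prev.columns if c.endswith("_of_cohort")]
    assert np.allclose(prev[of_cohort].sum(axis=1),
                       prev["cohort_fraction"])
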