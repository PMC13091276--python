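"""Succinotype classification and host-association tests.

Samples are classed by dominance among the two succinate-utilising genera:
with nD and nP the read counts of *Dialister* and *Phascolarctobacterium*,
rD = nD / (nD + nP); a sample is D-type when rD > 0.9, P-type when rD < 0.1,
mixed otherwise, and unclassified when the combined count is below 10 reads.
Associations between succinotype labels and host categories use Fisher's
exact test with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .tables import CountTable, aggregate_by_rank

# spelling variants occasionally seen in classifier output
GENUS_ALIASES = {
    "Phascolarctobacterium": ("Phascolarctobacterium", "Phaseolaretobacterium"),
    "Dialister": ("Dialister",),
}

LABELS = ("D", "P", "mixed", "unclassified")


class SuccinotypeError(ValueError):
    pass


def classify_succinotype(nD: int, nP: int, hi: float = 0.9, lo: float = 0.1,
                         min_reads: int = 10) -> str:
    """Apply the dominance rule to one (nD, nP) pair.

    Strict inequalities: rD == hi or rD == lo are mixed; a combined total of
    exactly ``min_reads`` is classifiable.
    """
    if nD < 0 or nP < 0:
        raise SuccinotypeError("counts must be non-negative")
    total = nD + nP
    if total < min_reads:
        return "unclassified"
    rD = nD / total
    if rD > hi:
        return "D"
    if rD < lo:
        return "P"
    return "mixed"


def _resolve_genus(columns, canonical: str) -> list[str]:
    aliases = GENUS_ALIASES.get(canonical, (canonical,))
    return [c for c in columns if c in aliases]


def classify_cohort(table: CountTable, taxonomy: pd.DataFrame | None = None,
                    dialister_name: str = "Dialister",
                    phasco_name: str = "Phascolarctobacterium",
                    subject_map: pd.Series | None = None,
                    hi: float = 0.9, lo: float = 0.1,
                    min_reads: int = 10) -> pd.DataFrame:
    """Per-sample succinotype calls for a count table.

    ASV-level tables are aggregated to genus first when a taxonomy is given.
    With a ``subject_map`` (sample -> subject), one call per subject is
    produced, prioritising clear D/P calls over mixed ones.
    """
    if taxonomy is not None:
        table = aggregate_by_rank(table, taxonomy, "genus")
    cols_d = _resolve_genus(table.data.columns, dialister_name)
    cols_p = _resolve_genus(table.data.columns, phasco_name)
    if not cols_d and not cols_p:
        warnings.warn("neither succinate-utiliser genus found; "
                      "all samples unclassified")
    nD = table.data[cols_d].sum(axis=1) if cols_d else \
        pd.Series(0, index=table.data.index)
    nP = table.data[cols_p].sum(axis=1) if cols_p else \
        pd.Series(0, index=table.data.index)
    rows = []
    for sid in table.sample_ids:
        d, p = int(nD[sid]), int(nP[sid])
        total = d + p
        rows.append({
            "sample_id": sid, "nD": d, "nP": p,
            "rD": d / total if total > 0 else np.nan,
            "label": classify_succinotype(d, p, hi, lo, min_reads),
        })
    calls = pd.DataFrame(rows).set_index("sample_id")
    if subject_map is not None:
        calls = _per_subject(calls, subject_map)
    return calls


def _per_subject(calls: pd.DataFrame, subject_map: pd.Series) -> pd.DataFrame:
    """Collapse multi-sample subjects, preferring clear D/P calls."""
    priority = {"D": 0, "P": 0, "mixed": 1, "unclassified": 2}
    out = []
    for subject, sids in subject_map.groupby(subject_map):
        sub = calls.loc[sids.index]
        sub = sub.assign(_prio=[priority[l] for l in sub["label"]])
        best = sub.sort_values("_prio", kind="stable").iloc[0]
        row = best.drop("_prio").to_dict()
        row["sample_id"] = subject
        out.append(row)
    return pd.DataFrame(out).set_index("sample_id")


def prevalence_summary(calls: pd.DataFrame,
                       groups: pd.Series | None = None) -> pd.DataFrame:
    """Label frequencies, both cohort-normalised and group-normalised."""
    rows = []
    n_total = len(calls)
    for label in LABELS:
        row = {"label": label,
               "cohort_fraction": (calls["label"] == label).sum() / n_total}
        if groups is not None:
            for g, idx in groups.groupby(groups):
                sub = calls.loc[calls.index.intersection(idx.index)]
                within = (sub["label"] == label).mean() if len(sub) else np.nan
                cohort = ((sub["label"] == label).sum() / n_total)
                row[f"{g}_within"] = within
                row[f"{g}_of_cohort"] = cohort
        rows.append(row)
    return pd.DataFrame(rows).set_index("label")


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for [[a, b], [c, d]] (probability-mass rule).

    An empty margin makes the table degenerate; p = 1 by convention.
    """
    if min(a, b, c, d) < 0:
        raise SuccinotypeError("cell counts must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return 1.0
    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def association_tests(calls: pd.DataFrame, metadata: pd.DataFrame,
                      variables: list[str]) -> pd.DataFrame:
    """Pairwise label x variable-level Fisher tests, BH-adjusted per variable.

    For every variable, every (label pair, level pair) 2x2 contingency table
    of sample counts is tested; degenerate tables are skipped with a reason.
    """
    shared = calls.index.intersection(metadata.index)
    if len(shared) == 0:
        raise SuccinotypeError("calls and metadata share no samples")
    calls = calls.loc[shared]
    metadata = metadata.loc[shared]
    rows = []
    for var in variables:
        values = metadata[var].astype(str)
        levels = sorted(values.unique())
        tests = []
        for la, lb in itertools.combinations(LABELS, 2):
            for va, vb in itertools.combinations(levels, 2):
                a = int(((calls["label"] == la) & (values == va)).sum())
                b = int(((calls["label"] == la) & (values == vb)).sum())
                c = int(((calls["label"] == lb) & (values == va)).sum())
                d = int(((calls["label"] == lb) & (values == vb)).sum())
                rec = {"variable": var, "labels": f"{la} vs {lb}",
                       "levels": f"{va} vs {vb}", "a": a, "b": b,
                       "c": c, "d": d}
                if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                    rec["p"] = np.nan
                    rec["skipped"] = "empty margin"
                else:
                    rec["p"] = fisher_exact_2x2(a, b, c, d)
                    rec["skipped"] = ""
                tests.append(rec)
        sub = pd.DataFrame(tests)
        ok = sub["p"].notna()
        sub["p_adj"] = np.nan
        if ok.any():
            sub.loc[ok, "p_adj"] = multipletests(
                sub.loc[ok, "p"], method="fdr_bh")[1]
        rows.append(sub)
    return pd.concat(rows, ignore_index=True)
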