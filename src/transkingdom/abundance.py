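"""Differential-abundance screening and the fungal dysbiosis ratio.

The screen is deliberately plain: relative abundances, pairwise two-sample
Wilcoxon rank-sum tests per genus (exact for small tie-free samples, normal
approximation with tie correction otherwise), Benjamini-Hochberg correction
within each comparison family, optional stratification (e.g. calprotectin
status, symptom subsets, empirical age tertiles).  A hook records where
results from an external bias-corrected compositional method (ANCOM-BC2)
would be merged; that method is not reimplemented here.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, ttest_ind
from statsmodels.stats.multitest import multipletests

from .tables import CountTable, age_tertiles, prevalence_filter, relative_abundance


class AbundanceError(ValueError):
    pass


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test, two-sided.

    Exact enumeration for combined n <= 20 without ties; otherwise the
    normal approximation with tie correction.  Identical pooled values give
    p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise AbundanceError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return float(len(x) * len(y) / 2), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    stat, p = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(stat), float(min(p, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise AbundanceError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def da_screen(table: CountTable, metadata: pd.DataFrame, grouping: str,
              strata: str | None = None, prevalence: float = 0.10,
              min_per_group: int = 3, direction_eps: float = 1e-6,
              test: str = "wilcoxon") -> pd.DataFrame:
    """Pairwise differential-abundance screen (Wilcoxon by default).

    Prevalence-filters the table, converts to relative abundance, then for
    every stratum and every unordered pair of ``grouping`` levels tests each
    genus; BH correction is applied within each (stratum, pair) family.
    ``strata="age_tertile"`` derives empirical age tertiles from metadata.
    Direction is the natural-log fold change of mean relative abundance
    (group1 over group2, stabilised by ``direction_eps``).  ``test="t"``
    switches to Welch's t-test, the documented parametric option; the
    nonparametric path is the default and needs no normality gate.
    """
    if test not in ("wilcoxon", "t"):
        raise AbundanceError(f"unknown test {test!r}")
    shared = table.data.index.intersection(metadata.index)
    if len(shared) < len(table.data.index):
        missing = sorted(set(table.data.index) - set(shared))
        raise AbundanceError(f"metadata missing samples: {missing}")
    metadata = metadata.loc[table.data.index].copy()
    filtered, _ = prevalence_filter(table, prevalence)
    rel = relative_abundance(filtered)

    if strata == "age_tertile":
        metadata["age_tertile"] = age_tertiles(metadata["age"])
        strata_col = "age_tertile"
    else:
        strata_col = strata
    strata_values = (metadata[strata_col].astype(str)
                     if strata_col else pd.Series("all", index=metadata.index))

    rows = []
    for stratum in sorted(strata_values.unique()):
        in_stratum = strata_values == stratum
        groups = metadata.loc[in_stratum, grouping].astype(str)
        levels = sorted(groups.unique())
        for a, b in itertools.combinations(levels, 2):
            ia = groups.index[groups == a]
            ib = groups.index[groups == b]
            if len(ia) < min_per_group or len(ib) < min_per_group:
                rows.append({"stratum": stratum, "comparison": f"{a} vs {b}",
                             "genus": None, "statistic": np.nan, "p": np.nan,
                             "p_adj": np.nan, "direction": np.nan,
                             "skipped": f"<{min_per_group} samples per group"})
                continue
            family = []
            for genus in rel.columns:
                xa = rel.loc[ia, genus].to_numpy()
                xb = rel.loc[ib, genus].to_numpy()
                if test == "wilcoxon":
                    stat, p = wilcoxon_rank_sum(xa, xb)
                else:
                    stat, p = ttest_ind(xa, xb, equal_var=False)
                    if np.isnan(p):  # zero variance in both groups
                        stat, p = 0.0, 1.0
                lfc = float(np.log((xa.mean() + direction_eps)
                                   / (xb.mean() + direction_eps)))
                family.append({"stratum": stratum,
                               "comparison": f"{a} vs {b}", "genus": genus,
                               "statistic": stat, "p": p, "direction": lfc,
                               "skipped": ""})
            fam = pd.DataFrame(family)
            fam["p_adj"] = bh_adjust(fam["p"])
            rows.extend(fam.to_dict("records"))
    out = pd.DataFrame(rows, columns=["stratum", "comparison", "genus",
                                      "statistic", "p", "p_adj",
                                      "direction", "skipped"])
    return out.reset_index(drop=True)


def ba_ratio(fungal: CountTable, taxonomy: pd.DataFrame,
             basidiomycota: str = "Basidiomycota",
             ascomycota: str = "Ascomycota",
             continuity: float = 0.5) -> pd.DataFrame:
    """Per-sample Basidiomycota/Ascomycota count ratio (+ natural log).

    Samples with a zero in either phylum get a +``continuity`` correction on
    both phyla and are flagged; samples with zero in both are flagged as
    undefined (NaN ratio).
    """
    phylum = taxonomy["phylum"]
    cols_b = [c for c in fungal.data.columns if phylum.get(c) == basidiomycota]
    cols_a = [c for c in fungal.data.columns if phylum.get(c) == ascomycota]
    if not cols_b or not cols_a:
        raise AbundanceError("both phyla must be resolvable in the taxonomy")
    nb = fungal.data[cols_b].sum(axis=1).astype(float)
    na = fungal.data[cols_a].sum(axis=1).astype(float)
    both_zero = (nb == 0) & (na == 0)
    any_zero = ((nb == 0) | (na == 0)) & ~both_zero
    nb_adj = nb.where(~any_zero, nb + continuity)
    na_adj = na.where(~any_zero, na + continuity)
    ratio = nb_adj / na_adj
    ratio[both_zero] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.log(ratio)
    return pd.DataFrame({
        "basidiomycota": nb.astype(int), "ascomycota": na.astype(int),
        "ratio": ratio, "log_ratio": log_ratio,
        "flagged": any_zero | both_zero,
    }, index=fungal.data.index)


def ancombc2_hook(da_results: pd.DataFrame,
                  external_path: str | None = None) -> pd.DataFrame:
    """Attachment point for externally computed bias-corrected results.

    When ``external_path`` (a TSV with columns genus/comparison/lfc/p_adj)
    is given, its rows are outer-merged onto the Wilcoxon screen under an
    ``ancombc2_`` prefix; otherwise the screen is returned unchanged.
    """
    if external_path is None:
        return da_results
    ext = pd.read_csv(external_path, sep="\t")
    ext = ext.rename(columns={c: f"ancombc2_{c}" for c in ext.columns
                              if c not in ("genus", "comparison")})
    return da_results.merge(ext, on=["genus", "comparison"], how="outer")
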