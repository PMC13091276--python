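"""Alpha diversity, beta-diversity distances, and PERMANOVA.

PERMANOVA follows the distance-based linear-model formulation: the squared
distance matrix is Gower-centred, model sums of squares come from hat-matrix
traces, and significance is assessed by permuting sample labels of the focal
factor.  Both sequential (terms added in order) and marginal (each term
conditional on the covariates) partitions are available; the marginal mode is
what "adjusting for GIT category" means downstream.  Distance matrices are
carried as :class:`skbio.DistanceMatrix` objects.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, spearmanr
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .tables import CountTable


class DiversityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def alpha_diversity(table: CountTable) -> pd.DataFrame:
    """Observed richness, Shannon index (natural log) and Pielou evenness.

    Pielou = Shannon / ln(richness), defined as 0 for single-taxon samples.
    """
    X = table.data.to_numpy(dtype=float)
    totals = X.sum(axis=1)
    if (totals == 0).any():
        sid = table.sample_ids[int(np.argmax(totals == 0))]
        raise DiversityError(f"empty sample: {sid!r}")
    richness = (X > 0).sum(axis=1)
    p = X / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    pielou = np.where(richness > 1, shannon / np.log(np.maximum(richness, 2)), 0.0)
    return pd.DataFrame({"richness": richness, "shannon": shannon,
                         "pielou": pielou}, index=table.data.index)


# ---------------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------------

def beta_distance(table: CountTable, metric: str = "bray_curtis") -> DistanceMatrix:
    """Bray-Curtis on counts, or Jaccard on presence/absence."""
    if table.n_samples < 2:
        raise DiversityError("need at least two samples")
    X = table.data.to_numpy(dtype=float)
    if metric == "bray_curtis":
        with np.errstate(invalid="ignore"):
            d = pdist(X, metric="braycurtis")
    elif metric == "jaccard":
        d = pdist(X > 0, metric="jaccard")
    else:
        raise DiversityError(f"unknown metric {metric!r}")
    if np.isnan(d).any():
        warnings.warn("all-zero sample pair; distance set to 0")
        d = np.nan_to_num(d, nan=0.0)
    return DistanceMatrix(squareform(d), ids=table.sample_ids)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    """Per-term variance partition of a PERMANOVA fit."""

    table: pd.DataFrame           # term / df / SS / R2 / F / p
    n_permutations: int
    seed: int | None
    mode: str                     # "sequential" | "marginal"

    def summary(self) -> str:
        lines = [f"PERMANOVA ({self.mode}, {self.n_permutations} permutations)",
                 self.table.to_string(float_format=lambda v: f"{v:.4f}")]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _design_columns(values: pd.Series) -> np.ndarray:
    """Treatment-coded dummy columns for one factor (drop first level)."""
    dummies = pd.get_dummies(values.astype(str), drop_first=True)
    return dummies.to_numpy(dtype=float)


def _hat(X: np.ndarray) -> tuple[np.ndarray, int]:
    """SVD-based projector onto the column space of [1, X] and its rank."""
    n = X.shape[0]
    Z = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    keep = s > s.max() * 1e-10
    Uk = U[:, keep]
    return Uk @ Uk.T, int(keep.sum())


def _gower(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    n = a.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ a @ J


def permanova(dist: DistanceMatrix, factor: pd.Series,
              covariates: pd.DataFrame | None = None,
              n_perm: int = 999, seed: int | None = None,
              mode: str | None = None) -> PermanovaResult:
    """Permutational MANOVA of ``factor`` on a distance matrix.

    With covariates the test is marginal: the factor's sum of squares is the
    gain over the covariate-only model, and permutations shuffle the factor's
    labels while covariate assignments stay fixed.  Without covariates the
    partition is sequential (one term + residual).
    """
    if n_perm < 99:
        raise DiversityError("n_perm must be >= 99")
    ids = list(dist.ids)
    factor = factor.loc[ids]
    levels = factor.astype(str).unique()
    if len(levels) < 2:
        raise DiversityError("no between-group df: factor has a single level")
    if mode is None:
        mode = "marginal" if covariates is not None else "sequential"

    d = dist.data
    G = _gower(d)
    ss_total = np.trace(G)
    n = len(ids)
    rng = np.random.default_rng(seed)

    X_fac = _design_columns(factor)
    if covariates is not None:
        covariates = covariates.loc[ids]
        X_cov = np.column_stack([_design_columns(covariates[c])
                                 for c in covariates.columns])
    else:
        X_cov = np.empty((n, 0))

    H_cov, rank_cov = _hat(X_cov)
    H_full, rank_full = _hat(np.column_stack([X_cov, X_fac]))
    df_cov = rank_cov - 1          # intercept absorbed
    df_fac = rank_full - rank_cov
    # trace(H G H) = sum(G * H) for idempotent symmetric H
    ss_cov = float(np.sum(G * H_cov))
    ss_full = float(np.sum(G * H_full))
    ss_fac = ss_full - ss_cov
    df_resid = n - rank_full
    ss_resid = ss_total - ss_full
    F_obs = (ss_fac / df_fac) / (ss_resid / df_resid)

    def perm_F(perm: np.ndarray) -> float:
        Xp = X_fac[perm]
        Hf, _ = _hat(np.column_stack([X_cov, Xp]))
        ssf = float(np.sum(G * Hf)) - ss_cov
        ssr = ss_total - float(np.sum(G * Hf))
        return (ssf / df_fac) / (ssr / df_resid)

    exceed = 0
    for _ in range(n_perm):
        if perm_F(rng.permutation(n)) >= F_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)

    rows = []
    if df_cov:
        rows.append({"term": "+".join(covariates.columns), "df": df_cov,
                     "SS": ss_cov, "R2": ss_cov / ss_total,
                     "F": np.nan, "p": np.nan})
    rows.append({"term": factor.name or "factor", "df": df_fac, "SS": ss_fac,
                 "R2": ss_fac / ss_total, "F": F_obs, "p": p})
    rows.append({"term": "residual", "df": df_resid, "SS": ss_resid,
                 "R2": ss_resid / ss_total, "F": np.nan, "p": np.nan})
    out = pd.DataFrame(rows)
    return PermanovaResult(out, n_perm, seed, mode)


def pairwise_permanova(dist: DistanceMatrix, factor: pd.Series,
                       n_perm: int = 999,
                       seed: int | None = None) -> pd.DataFrame:
    """One PERMANOVA per unordered level pair, BH-adjusted across pairs."""
    ids = list(dist.ids)
    factor = factor.loc[ids].astype(str)
    levels = sorted(factor.unique())
    if len(levels) < 2:
        raise DiversityError("need at least two factor levels")
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in itertools.combinations(levels, 2):
        keep = [i for i in ids if factor[i] in (a, b)]
        sub = dist.filter(keep)
        res = permanova(sub, factor.loc[keep], n_perm=n_perm,
                        seed=int(rng.integers(2 ** 31)))
        fac_row = res.table[res.table["term"] != "residual"].iloc[-1]
        rows.append({"pair": f"{a} vs {b}", "R2": fac_row["R2"],
                     "F": fac_row["F"], "p": fac_row["p"]})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def write_distance_matrix(dist: DistanceMatrix, path) -> None:
    """Square tab-separated matrix with sample ids as header row/column."""
    dist.write(str(path))


def read_distance_matrix(path) -> DistanceMatrix:
    return DistanceMatrix.read(str(path))


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DiversityError("x and y must share length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DiversityError("zero-variance input")
    if method == "pearson":
        r, p = pearsonr(x, y)
    elif method == "spearman":
        r, p = spearmanr(x, y)
    else:
        raise DiversityError(f"unknown method {method!r}")
    return float(r), float(p)
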