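"""Count-table data model, I/O, compositional transforms and filtering rules.

The central container is :class:`CountTable`, a thin validated wrapper around a
pandas DataFrame of non-negative integer read counts with samples as rows and
taxa as columns.  Taxonomy and sample metadata are plain DataFrames indexed by
taxon and sample id respectively.  All filters return a ``(table, report)``
pair so that every dropped taxon or sample is accounted for; writers can emit
the report as a sidecar JSON log.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

TAXONOMY_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")


class TableError(ValueError):
    """Raised for malformed count tables, taxonomy or metadata."""


@dataclass
class CountTable:
    """Integer abundance matrix (samples x taxa) with a kingdom tag.

    Parameters
    ----------
    data : pandas.DataFrame
        Non-negative integer counts; index = sample ids, columns = taxon ids.
    kingdom : str
        Label for the table as a whole, e.g. ``"bacterial"`` or ``"fungal"``.
    """

    data: pd.DataFrame
    kingdom: str = "bacterial"

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise TableError(f"duplicate sample id: {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise TableError(f"duplicate taxon id: {dup!r}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values), atol=0):
                bad = values[values != np.round(values)][0]
                raise TableError(f"counts must be integers, found {bad}")
            df = df.astype(np.int64)
        if (df.to_numpy() < 0).any():
            raise TableError("counts must be non-negative")
        self.data = df.astype(np.int64)

    # -- basic views ------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def depths(self) -> pd.Series:
        """Per-sample total read count."""
        return self.data.sum(axis=1)

    def copy(self) -> "CountTable":
        return CountTable(self.data.copy(), self.kingdom)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.kingdom == other.kingdom and self.data.equals(other.data)


# ---------------------------------------------------------------------------
# I/O — counts are written taxa x samples (the common amplicon convention),
# metadata and taxonomy with one row per sample / taxon.
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path, kingdom: str = "bacterial") -> CountTable:
    """Read a tab-separated taxa x samples count file."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise TableError(f"{path}: duplicate taxon id {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise TableError(f"{path}: duplicate sample id {dup!r}")
    try:
        return CountTable(df.T, kingdom=kingdom)
    except TableError as exc:
        raise TableError(f"{path}: {exc}") from exc


def write_count_table(table: CountTable, path: str | Path,
                      log: dict | None = None) -> None:
    """Write taxa x samples TSV; optional sidecar ``<path>.log.json``."""
    table.data.T.to_csv(path, sep="\t", index_label="taxon_id")
    if log is not None:
        Path(str(path) + ".log.json").write_text(
            json.dumps(log, indent=2, sort_keys=True))


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    tax = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if tax.index.duplicated().any():
        dup = tax.index[tax.index.duplicated()][0]
        raise TableError(f"{path}: duplicate taxon id {dup!r}")
    return tax


def write_taxonomy(tax: pd.DataFrame, path: str | Path) -> None:
    tax.to_csv(path, sep="\t", index_label="taxon_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", index_col=0)
    if md.index.duplicated().any():
        dup = md.index[md.index.duplicated()][0]
        raise TableError(f"{path}: duplicate sample id {dup!r}")
    if "age" in md.columns and (md["age"].dropna() < 0).any():
        raise TableError(f"{path}: negative age")
    return md


def write_metadata(md: pd.DataFrame, path: str | Path) -> None:
    md.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Aggregation and filtering
# ---------------------------------------------------------------------------

def aggregate_by_rank(table: CountTable, taxonomy: pd.DataFrame,
                      rank: str = "genus") -> CountTable:
    """Sum counts of all taxa sharing a value at ``rank``.

    Taxa absent from the taxonomy, or unassigned at ``rank``, are pooled into
    an ``unassigned_<parent>`` bucket keyed by the nearest assigned parent
    rank, so per-sample totals are conserved exactly.
    """
    if rank not in TAXONOMY_RANKS:
        raise TableError(f"unknown taxonomy rank {rank!r}")
    rank_idx = TAXONOMY_RANKS.index(rank)
    labels = []
    for tid in table.taxon_ids:
        if tid not in taxonomy.index:
            labels.append("unassigned_unknown")
            continue
        row = taxonomy.loc[tid]
        value = row.get(rank)
        if isinstance(value, str) and value and value.lower() != "unassigned":
            labels.append(value)
            continue
        # walk up to the nearest assigned parent
        parent = "unknown"
        for r in reversed(TAXONOMY_RANKS[:rank_idx]):
            v = row.get(r)
            if isinstance(v, str) and v and v.lower() != "unassigned":
                parent = v
                break
        labels.append(f"unassigned_{parent}")
    out = table.data.T.groupby(pd.Index(labels, name=rank), sort=True).sum().T
    return CountTable(out, kingdom=table.kingdom)


def rare_taxon_filter(table: CountTable, fraction: float = 0.001,
                      mode: str = "total_count") -> tuple[CountTable, dict]:
    """Drop singletons and rare taxa.

    ``mode="total_count"`` (default): drop taxa whose total count across the
    cohort is below ``fraction`` of the mean per-sample sequencing depth.
    ``mode="relative"``: drop taxa whose maximum per-sample relative abundance
    is below ``fraction``.  Singletons (total count == 1) are always dropped.
    """
    if not 0 < fraction < 1:
        raise TableError("fraction must be in (0, 1)")
    totals = table.data.sum(axis=0)
    singleton = totals == 1
    if mode == "total_count":
        threshold = fraction * table.depths().mean()
        rare = totals < threshold
    elif mode == "relative":
        depths = table.depths().replace(0, 1)
        rel = table.data.div(depths, axis=0)
        rare = rel.max(axis=0) < fraction
        threshold = fraction
    else:
        raise TableError(f"unknown rare-taxon filter mode {mode!r}")
    drop = singleton | rare
    report = {
        "filter": "rare_taxon", "mode": mode, "fraction": fraction,
        "threshold": float(threshold),
        "dropped_taxa": sorted(table.data.columns[drop]),
    }
    return CountTable(table.data.loc[:, ~drop], table.kingdom), report


def prevalence_filter(table: CountTable,
                      min_prevalence: float) -> tuple[CountTable, dict]:
    """Remove taxa present (count > 0) in strictly fewer than
    ``min_prevalence`` of samples."""
    if not 0 <= min_prevalence <= 1:
        raise TableError("min_prevalence must be in [0, 1]")
    prev = (table.data > 0).mean(axis=0)
    drop = prev < min_prevalence
    report = {"filter": "prevalence", "min_prevalence": min_prevalence,
              "dropped_taxa": sorted(table.data.columns[drop])}
    kept = table.data.loc[:, ~drop]
    if kept.shape[1] == 0:
        warnings.warn("prevalence filter removed every taxon")
    return CountTable(kept, table.kingdom), report


def rarefy(table: CountTable, depth: int,
           seed: int) -> tuple[CountTable, dict]:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped and listed in
    the report.  Uses multivariate hypergeometric sampling, the standard
    rarefaction model.
    """
    if depth < 1:
        raise TableError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    rows, kept, dropped = [], [], []
    for sid in table.sample_ids:
        counts = table.data.loc[sid].to_numpy()
        total = int(counts.sum())
        if total < depth:
            dropped.append(sid)
            continue
        if total == depth:
            rows.append(counts.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(counts, depth))
        kept.append(sid)
    data = pd.DataFrame(np.array(rows, dtype=np.int64).reshape(len(kept), table.n_taxa),
                        index=kept, columns=table.taxon_ids)
    report = {"filter": "rarefy", "depth": depth, "seed": seed,
              "dropped_samples": dropped}
    return CountTable(data, table.kingdom), report


# ---------------------------------------------------------------------------
# Compositional transforms
# ---------------------------------------------------------------------------

def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Row-normalised proportions; errors on all-zero samples."""
    depths = table.depths()
    zero = depths[depths == 0]
    if len(zero):
        raise TableError(f"all-zero sample: {zero.index[0]!r}")
    return table.data.div(depths, axis=0)


def clr_transform(counts: CountTable | pd.DataFrame,
                  pseudocount: float = 1.0) -> pd.DataFrame:
    """Centred log-ratio transform: log(x + pc) minus its per-sample mean.

    Each output row sums to zero.  ``pseudocount=0`` is allowed for strictly
    positive input.
    """
    df = counts.data if isinstance(counts, CountTable) else counts
    if pseudocount < 0:
        raise TableError("pseudocount must be >= 0")
    x = df.to_numpy(dtype=float) + pseudocount
    if (x <= 0).any():
        raise TableError("clr_transform requires positive values "
                         "(use a positive pseudocount)")
    logx = np.log(x)
    out = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def age_tertiles(age: pd.Series) -> pd.Series:
    """Empirical age tertiles (labels T1/T2/T3); ties go to the lower tertile."""
    cuts = np.quantile(age.to_numpy(dtype=float), [1 / 3, 2 / 3])
    labels = np.where(age <= cuts[0], "T1", np.where(age <= cuts[1], "T2", "T3"))
    return pd.Series(labels, index=age.index, name="age_tertile")
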