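"""Seeded synthetic multi-kingdom cohorts with known ground truth.

The generator emulates the statistical structure a stratification analysis of
an IBS/UC/CD cohort relies on, at desk scale:

* four host groups (controls / IBS / UC / CD, default sizes 9/29/31/30);
* bacterial genus counts drawn from a two-component Dirichlet-multinomial
  mixture (two Bacteroides-dominant enterotype-like community states);
* a succinotype layer written into the *Dialister* and *Phascolarctobacterium*
  columns so that class prevalences converge to configurable targets
  (default 43% D-type, 30% P-type, 18% mixed, 9% unclassified);
* an independent fungal table whose phylum labels support the
  Basidiomycota/Ascomycota dysbiosis ratio;
* optional counts drawn from a known sparse precision matrix
  (logistic-normal-multinomial) for network-recovery experiments.

Every draw flows from a single :class:`numpy.random.Generator`, so a config
plus seed pins the whole cohort bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .tables import (CountTable, TAXONOMY_RANKS, write_count_table,
                     write_metadata, write_taxonomy)


class ConfigError(ValueError):
    """Raised when a SynthConfig field violates its invariants."""


# Named bacterial genera placed at the head of the taxon list; the remainder
# are anonymous "genus_###" fillers.  Dialister / Phascolarctobacterium carry
# the succinotype signal; the first ten separate the two community states.
NAMED_BACTERIA = [
    "Bacteroides", "Faecalibacterium", "Escherichia-Shigella", "Streptococcus",
    "Alistipes", "Akkermansia", "Bifidobacterium", "Segatella", "Roseburia",
    "Coprococcus", "Dialister", "Phascolarctobacterium", "Blautia",
    "Agathobacter", "Ruminococcus", "Subdoligranulum", "Parabacteroides",
    "Lachnoclostridium", "Catenibacterium", "Holdemanella",
]

NAMED_FUNGI = [
    "Rigidoporus", "Malassezia", "Saitozyma", "Candida", "Saccharomyces",
    "Meyerozyma", "Kazachstania", "Wickerhamomyces", "Didymella", "Capronia",
]

SYMPTOMS = ("abdominal_pain", "nausea", "vomiting", "diarrhoea", "anorexia",
            "bloating", "urgency")


@dataclass
class SynthConfig:
    """Knobs of the synthetic cohort; defaults are the emulation targets."""

    group_sizes: dict = field(default_factory=lambda: {
        "control": 9, "IBS": 29, "UC": 31, "CD": 30})
    n_bact_taxa: int = 250
    n_fungal_taxa: int = 150
    # lognormal depth parameters (of the underlying normal), per kingdom;
    # medians exp(mu): 5000 reads (16S) and 3000 reads (ITS)
    depth_lognorm: dict = field(default_factory=lambda: {
        "bacterial": (np.log(5000.0), 0.25), "fungal": (np.log(3000.0), 0.25)})
    enterotype_weights: tuple = (0.55, 0.45)
    enterotype_concentration: float = 60.0
    enterotype_shift: float = 10.0   # fold-change on the discriminating genera
    n_shift_taxa: int = 10
    succinotype_targets: dict = field(default_factory=lambda: {
        "D": 0.43, "P": 0.30, "mixed": 0.18, "unclassified": 0.09})
    # odds multiplier per group for D-type membership; default = independence
    succinotype_group_odds: dict = field(default_factory=dict)
    network_topology: str = "band"
    network_strength: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if int(n) <= 0:
                raise ConfigError(f"group_sizes[{g!r}] must be positive")
        if self.n_bact_taxa < len(NAMED_BACTERIA):
            raise ConfigError("n_bact_taxa too small for the named genera")
        if self.n_fungal_taxa < len(NAMED_FUNGI):
            raise ConfigError("n_fungal_taxa too small for the named genera")
        w = np.asarray(self.enterotype_weights, dtype=float)
        if (w < 0).any() or abs(w.sum() - 1) > 1e-9:
            raise ConfigError("enterotype_weights must lie on the simplex")
        s = self.succinotype_targets
        if any(not 0 <= v <= 1 for v in s.values()):
            raise ConfigError("succinotype_targets fractions must be in [0,1]")
        if abs(sum(s.values()) - 1) > 1e-9:
            raise ConfigError("succinotype_targets must sum to 1")
        if self.network_topology not in ("band", "cluster", "scale_free"):
            raise ConfigError(
                f"unknown network_topology {self.network_topology!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class GroundTruth:
    """Generative record for recovery tests."""

    enterotype: pd.Series          # per-sample true component label (0-based)
    succinotype: pd.Series         # per-sample true class
    alphas: np.ndarray             # K x G Dirichlet parameter matrix
    weights: np.ndarray
    precision: np.ndarray | None = None   # generating precision, if any
    adjacency: np.ndarray | None = None   # signed support of the precision

    def to_json(self, path: str | Path) -> None:
        obj = {
            "enterotype": self.enterotype.astype(int).to_dict(),
            "succinotype": self.succinotype.to_dict(),
            "alphas": self.alphas.tolist(),
            "weights": self.weights.tolist(),
            "precision": None if self.precision is None else self.precision.tolist(),
            "adjacency": None if self.adjacency is None else self.adjacency.tolist(),
        }
        Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Generative primitives
# ---------------------------------------------------------------------------

def sample_dmm_counts(alphas, weights, n: int, depths,
                      rng: np.random.Generator):
    """Draw ``n`` count rows from a Dirichlet-multinomial mixture.

    Row i: component z_i ~ Categorical(weights), composition
    p_i ~ Dirichlet(alpha_{z_i}), counts ~ Multinomial(depth_i, p_i).
    Returns (counts array n x G, labels array n).
    """
    alphas = [np.asarray(a, dtype=float) for a in alphas]
    weights = np.asarray(weights, dtype=float)
    if len(alphas) != len(weights):
        raise ConfigError("one weight per alpha vector required")
    for a in alphas:
        if (a <= 0).any():
            raise ConfigError("alpha vectors must be strictly positive")
    depths = np.broadcast_to(np.asarray(depths, dtype=np.int64), (n,))
    if (depths < 1).any():
        raise ConfigError("depths must be >= 1")
    labels = rng.choice(len(alphas), size=n, p=weights)
    G = alphas[0].shape[0]
    counts = np.empty((n, G), dtype=np.int64)
    for i in range(n):
        p = rng.dirichlet(alphas[labels[i]])
        counts[i] = rng.multinomial(depths[i], p)
    return counts, labels


def make_precision_matrix(topology: str, p: int, strength: float = 0.3,
                          rng: np.random.Generator | None = None,
                          block_size: int = 5):
    """Symmetric positive-definite precision matrix with known support.

    ``band``: first off-diagonal; ``cluster``: dense blocks of ``block_size``;
    ``scale_free``: preferential-attachment tree (needs ``rng``).  Negative
    off-diagonal entries of the precision encode *positive* partial
    correlations of matching magnitude.  If the requested strength breaks
    positive definiteness the diagonal is inflated until the smallest
    eigenvalue clears 0.05 (recorded in the returned dict).
    """
    if p < 3:
        raise ConfigError("p must be >= 3")
    support = np.zeros((p, p), dtype=bool)
    if topology == "band":
        idx = np.arange(p - 1)
        support[idx, idx + 1] = support[idx + 1, idx] = True
    elif topology == "cluster":
        for start in range(0, p, block_size):
            stop = min(start + block_size, p)
            support[start:stop, start:stop] = True
        np.fill_diagonal(support, False)
    elif topology == "scale_free":
        if rng is None:
            rng = np.random.default_rng(0)
        degree = np.zeros(p)
        for new in range(1, p):
            probs = degree[:new] + 1.0
            target = rng.choice(new, p=probs / probs.sum())
            support[new, target] = support[target, new] = True
            degree[new] += 1
            degree[target] += 1
    else:
        raise ConfigError(f"unknown topology {topology!r}")

    omega = np.eye(p)
    omega[support] = -strength  # negative precision entry -> positive partial corr
    inflation = 0.0
    min_eig = np.linalg.eigvalsh(omega).min()
    while min_eig <= 0.05:
        inflation += 0.1
        omega[np.diag_indices(p)] = 1.0 + inflation
        min_eig = np.linalg.eigvalsh(omega).min()
    info = {"topology": topology, "strength": strength,
            "diagonal_inflation": inflation, "min_eigenvalue": float(min_eig)}
    return omega, support, info


def sample_network_counts(precision: np.ndarray, n: int, depths,
                          rng: np.random.Generator,
                          mean: np.ndarray | None = None) -> np.ndarray:
    """Logistic-normal-multinomial counts with the given latent precision.

    Latent log-abundances z ~ N(mean, precision^-1); compositions by softmax;
    counts multinomial at the requested depths.
    """
    precision = np.asarray(precision, dtype=float)
    p = precision.shape[0]
    eigs = np.linalg.eigvalsh(precision)
    if eigs.min() <= 0:
        raise ConfigError("precision matrix must be positive definite")
    cov = np.linalg.inv(precision)
    if mean is None:
        mean = np.zeros(p)
    depths = np.broadcast_to(np.asarray(depths, dtype=np.int64), (n,))
    z = rng.multivariate_normal(mean, cov, size=n, method="cholesky")
    z = z - z.max(axis=1, keepdims=True)
    comp = np.exp(z)
    comp /= comp.sum(axis=1, keepdims=True)
    counts = np.empty((n, p), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(depths[i], comp[i])
    return counts


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _base_alphas(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Two enterotype-like Dirichlet parameter vectors over all genera."""
    G = cfg.n_bact_taxa
    # steep rank-abundance baseline: a handful of dominant genera, long tail
    base = np.sort(rng.lognormal(mean=0.0, sigma=1.6, size=G))[::-1]
    base[0] *= 8.0   # Bacteroides dominance in both states
    base /= base.sum()
    alpha1 = cfg.enterotype_concentration * base
    alpha2 = alpha1.copy()
    # shift a block of discriminating genera (skipping Bacteroides and the
    # two succinotype genera, whose counts are overwritten later)
    skip = {0, NAMED_BACTERIA.index("Dialister"),
            NAMED_BACTERIA.index("Phascolarctobacterium")}
    shift_idx = [i for i in range(1, G) if i not in skip][:cfg.n_shift_taxa]
    half = len(shift_idx) // 2
    alpha2[shift_idx[:half]] *= cfg.enterotype_shift
    alpha2[shift_idx[half:]] /= cfg.enterotype_shift
    alpha2 *= alpha1.sum() / alpha2.sum()
    return np.vstack([alpha1, alpha2])


def _succinotype_counts(label: str, depth: int, rng: np.random.Generator):
    """Draw (nD, nP) consistent with a succinotype class label."""
    if label == "unclassified":
        total = int(rng.integers(0, 10))  # < 10 combined reads
        nD = int(rng.integers(0, total + 1)) if total else 0
        return nD, total - nD
    # combined succinate-utiliser load: 2-5% of depth, at least 50 reads,
    # so the class survives desk-scale rarefaction
    total = max(50, int(depth * rng.uniform(0.02, 0.05)))
    if label == "D":
        r = rng.uniform(0.94, 0.995)
    elif label == "P":
        r = rng.uniform(0.005, 0.06)
    elif label == "mixed":
        r = rng.uniform(0.25, 0.75)
    else:
        raise ConfigError(f"unknown succinotype label {label!r}")
    nD = int(round(total * r))
    nD = min(max(nD, 1 if label != "P" else 0), total)
    return nD, total - nD


def _succinotype_probs(cfg: SynthConfig, group: str) -> np.ndarray:
    """Class probabilities, optionally tilting D-type odds for a group."""
    classes = ["D", "P", "mixed", "unclassified"]
    p = np.array([cfg.succinotype_targets[c] for c in classes], dtype=float)
    odds = cfg.succinotype_group_odds.get(group, 1.0)
    if odds != 1.0:
        new_d = odds * p[0] / (odds * p[0] + (1 - p[0]))
        p = np.concatenate([[new_d], p[1:] / p[1:].sum() * (1 - new_d)])
    return p / p.sum()


def _metadata(groups: list[str], sample_ids: list[str],
              rng: np.random.Generator) -> pd.DataFrame:
    """Host covariates with group-typical rates (ages, calprotectin,
    symptoms, Blastocystis carriage and subtype)."""
    age_median = {"control": 41, "IBS": 36, "UC": 33, "CD": 24}
    calpro_pos = {"control": 0.2, "IBS": 0.3, "UC": 0.72, "CD": 0.60}
    blasto_pos = {"control": 0.78, "IBS": 0.55, "UC": 0.45, "CD": 0.37}
    symptom_p = {
        "abdominal_pain": {"control": 0.2, "IBS": 0.79, "UC": 0.5, "CD": 0.5},
        "nausea": {"control": 0.15, "IBS": 0.38, "UC": 0.2, "CD": 0.2},
        "vomiting": {"control": 0.44, "IBS": 0.15, "UC": 0.15, "CD": 0.15},
        "diarrhoea": {"control": 0.2, "IBS": 0.5, "UC": 0.6, "CD": 0.55},
        "anorexia": {"control": 0.1, "IBS": 0.25, "UC": 0.3, "CD": 0.35},
        "bloating": {"control": 0.2, "IBS": 0.6, "UC": 0.35, "CD": 0.35},
        "urgency": {"control": 0.1, "IBS": 0.4, "UC": 0.5, "CD": 0.35},
    }
    rows = []
    for g in groups:
        age = float(np.clip(rng.normal(age_median.get(g, 35), 9.0), 16, 80))
        calpro = "pos" if rng.random() < calpro_pos.get(g, 0.3) else "neg"
        if rng.random() < blasto_pos.get(g, 0.5):
            blasto = rng.choice(["ST1", "ST3", "other"], p=[0.77, 0.22, 0.01])
        else:
            blasto = "neg"
        row = {"group": g, "age": round(age, 1), "calprotectin": calpro,
               "blastocystis": blasto}
        for s in SYMPTOMS:
            row[s] = int(rng.random() < symptom_p[s].get(g, 0.3))
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id"))


def _taxonomy(taxon_ids: list[str], kingdom: str,
              phyla: list[str]) -> pd.DataFrame:
    rows = []
    for tid, phylum in zip(taxon_ids, phyla):
        rows.append({"kingdom": kingdom, "phylum": phylum, "class": "unassigned",
                     "order": "unassigned", "family": "unassigned",
                     "genus": tid})
    return pd.DataFrame(rows, index=pd.Index(taxon_ids, name="taxon_id"),
                        columns=list(TAXONOMY_RANKS))


def generate_cohort(cfg: SynthConfig):
    """Generate (bacterial CountTable, fungal CountTable, metadata DataFrame,
    taxonomy dict, GroundTruth) for one synthetic cohort."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    groups = [g for g, n in cfg.group_sizes.items() for _ in range(int(n))]
    n = len(groups)
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]

    bact_names = (NAMED_BACTERIA +
                  [f"genus_{i:03d}" for i in range(cfg.n_bact_taxa - len(NAMED_BACTERIA))])
    fung_names = (NAMED_FUNGI +
                  [f"fgenus_{i:03d}" for i in range(cfg.n_fungal_taxa - len(NAMED_FUNGI))])

    # --- bacterial counts: DMM enterotype layer -------------------------
    mu_b, sd_b = cfg.depth_lognorm["bacterial"]
    depths_b = np.maximum(200, rng.lognormal(mu_b, sd_b, size=n)).astype(np.int64)
    alphas = _base_alphas(cfg, rng)
    counts_b, ent_labels = sample_dmm_counts(
        alphas, cfg.enterotype_weights, n, depths_b, rng)

    # --- succinotype layer: overwrite the two succinate-utiliser genera --
    iD = bact_names.index("Dialister")
    iP = bact_names.index("Phascolarctobacterium")
    succ_labels = []
    for i, g in enumerate(groups):
        probs = _succinotype_probs(cfg, g)
        label = rng.choice(["D", "P", "mixed", "unclassified"], p=probs)
        nD, nP = _succinotype_counts(label, int(depths_b[i]), rng)
        counts_b[i, iD] = nD
        counts_b[i, iP] = nP
        succ_labels.append(label)

    bact = CountTable(pd.DataFrame(counts_b, index=sample_ids,
                                   columns=bact_names), kingdom="bacterial")

    # --- fungal counts: independent composition, phylum structure --------
    mu_f, sd_f = cfg.depth_lognorm["fungal"]
    depths_f = np.maximum(200, rng.lognormal(mu_f, sd_f, size=n)).astype(np.int64)
    Gf = cfg.n_fungal_taxa
    base_f = np.sort(rng.lognormal(0.0, 1.6, size=Gf))[::-1]
    base_f /= base_f.sum()
    alpha_f = 40.0 * base_f
    counts_f, _ = sample_dmm_counts([alpha_f], [1.0], n, depths_f, rng)
    fung = CountTable(pd.DataFrame(counts_f, index=sample_ids,
                                   columns=fung_names), kingdom="fungal")

    # phylum labels: top fungal taxa alternate 2:1 Basidiomycota:Ascomycota
    # so the cohort-level ratio lands near the ~2:1 dysbiosis-scale regime
    phyla_f = []
    for i in range(Gf):
        if i % 3 < 2:
            phyla_f.append("Basidiomycota")
        else:
            phyla_f.append("Ascomycota")
    taxonomy = {
        "bacterial": _taxonomy(bact_names, "Bacteria",
                               ["Bacillota"] * len(bact_names)),
        "fungal": _taxonomy(fung_names, "Fungi", phyla_f),
    }

    metadata = _metadata(groups, sample_ids, rng)

    truth = GroundTruth(
        enterotype=pd.Series(ent_labels, index=sample_ids, name="enterotype"),
        succinotype=pd.Series(succ_labels, index=sample_ids, name="succinotype"),
        alphas=alphas, weights=np.asarray(cfg.enterotype_weights, dtype=float))
    return bact, fung, metadata, taxonomy, truth


def write_cohort(outdir: str | Path, bact: CountTable, fung: CountTable,
                 metadata: pd.DataFrame, taxonomy: dict,
                 truth: GroundTruth | None = None) -> None:
    """Write the cohort as tab-separated files plus a ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_count_table(bact, outdir / "bacterial_counts.tsv")
    write_count_table(fung, outdir / "fungal_counts.tsv")
    write_metadata(metadata, outdir / "metadata.tsv")
    write_taxonomy(taxonomy["bacterial"], outdir / "bacterial_taxonomy.tsv")
    write_taxonomy(taxonomy["fungal"], outdir / "fungal_taxonomy.tsv")
    if truth is not None:
        truth.to_json(outdir / "ground_truth.json")
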