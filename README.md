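# transkingdom

Multi-kingdom gut microbiome stratification for case/control cohort studies:
enterotype and succinotype classification, diversity and variance
partitioning, differential-abundance screening, and sparse signed
bacterial-fungal association networks with keystone and robustness analysis.

The package is aimed at microbiome analysts working with genus-level 16S and
ITS amplicon count tables from clinical cohorts (e.g. IBS / ulcerative
colitis / Crohn's disease versus controls), where the questions are: which
community states exist, which taxa separate them, how much host metadata
explains community variation, and how fragile the inferred ecological
networks are.

## Models and statistics at the core

**Enterotyping — Dirichlet-multinomial mixture (DMM).** Sample counts
x_i over G genera follow

P(x_i) = Σ_k π_k · DM(x_i | α_k),

where DM is the Dirichlet-multinomial density with component parameter
α_k > 0 and mixture weights π on the simplex. Fitting is EM with a
responsibility-weighted Minka fixed-point M-step; the number of community
states K is chosen by BIC, AIC and a Laplace approximation to the negative
log evidence. Genus contributions to the split are ranked by
Σ_k |t(α_k/A_k) − t(α_1/A_1)| with t the CLR transform of the component
mean profile.

**Succinotyping.** With nD and nP the read counts of the succinate
utilisers *Dialister* and *Phascolarctobacterium*, rD = nD/(nD+nP);
samples are D-type (rD > 0.9), P-type (rD < 0.1), mixed otherwise, and
unclassified when nD + nP < 10. Associations with host categories use
Fisher's exact test with Benjamini-Hochberg correction.

**Diversity.** Observed richness, Shannon (natural log), Pielou evenness;
Bray-Curtis and Jaccard distances; PERMANOVA via the Gower-centred
distance partition with sequential and marginal (covariate-adjusted) R²,
permutation p-values, and BH-corrected pairwise comparisons.

**Differential abundance.** Prevalence filter (< 10% of samples excluded),
pairwise Wilcoxon rank-sum on relative abundances (exact for small
tie-free samples), BH per comparison family, optional stratification by
calprotectin status, symptoms, or empirical age tertiles; plus the
Basidiomycota/Ascomycota ratio as a fungal dysbiosis indicator.

**Networks.** Prevalence filter (< 20% excluded), CLR transform per
kingdom, graphical lasso along a 30-point penalty path with StARS
stability selection (80% subsampling, 50 repetitions, instability
threshold 0.05); edge weights are partial correlations
ρ_ij = −Ω_ij/√(Ω_ii Ω_jj). Signed Leiden communities (Q⁺ − Q⁻,
resolution 0.5), the full node/global metric set, keystones as the top 5%
by summed z-scored centralities, and targeted-attack robustness curves
with AUC and R50.

A seeded synthetic-cohort generator produces bacterial and fungal count
tables, host metadata and ground-truth labels with exactly this structure,
so every stage can be validated against known truth.

## Worked example

```python
import transkingdom as tk
import pandas as pd

cfg = tk.SynthConfig(seed=1)                  # 99 samples: 9/29/31/30
bact, fung, metadata, taxonomy, truth = tk.generate_cohort(cfg)

calls = tk.classify_cohort(bact)
print(calls["label"].value_counts(normalize=True).round(3))
```

prints the succinotype class fractions of the generated cohort:

```
label
D               0.465
P               0.323
mixed           0.131
unclassified    0.081
Name: proportion, dtype: float64
```

i.e. roughly 43/30/18/9% D/P/mixed/unclassified at n = 99, the generator's
prevalence targets, within sampling error. Fitting the mixture model and
selecting the number of community states:

```python
best, fits, scores = tk.select_k(bact, k_range=[1, 2, 3], seed=0)
print(best)            # {'BIC': 2, 'AIC': 2, 'Laplace': 3}
labels = fits[best["BIC"]].assign()
```

recovers the two generated enterotype-like states by BIC and AIC (the
Laplace approximation, flatter at this genus count, entertains a third
component; on the lower-dimensional recovery scenario in the test suite
all three criteria agree on two). The full pipeline —
preprocessing, diversity, enterotype, succinotype, differential abundance,
per-group cross-kingdom networks and per-succinotype bacterial networks,
network statistics and a report — runs from one config:

```bash
transkingdom all --seed 1 --out runs/demo
```

and ends with a `manifest.json` of output hashes; re-running with the same
seed reproduces the bundle byte for byte.

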