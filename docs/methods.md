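# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of the `transkingdom` package. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and preprocessing

Count tables are non-negative integer matrices (samples × taxa) with a
kingdom tag; taxonomy and metadata are DataFrames keyed by taxon and sample
id. Preprocessing follows common amplicon practice:

- **Rare-taxon filter.** Singletons are always removed. The rare-taxon
  threshold is interpreted as *total count below `fraction` × mean
  per-sample depth* (default fraction 0.001). The phrase "relative
  abundance below 0.1% of the mean sequencing depth" mixes a proportion
  with a depth; a per-sample relative-abundance variant
  (`mode="relative"`) is provided, with total-count as default. The choice
  is a named, overridable parameter.
- **Prevalence filters.** Strict inequality: a taxon present in exactly
  10% (or 20%) of samples is kept. Differential abundance uses 0.10,
  network inference 0.20.
- **Rarefaction** is multivariate hypergeometric (without replacement) at a
  mandatory seed; samples below the target depth are dropped and listed.
  Desk-scale defaults are 2000 reads (bacterial) and 1200 (fungal), chosen
  so that most generated samples survive while every downstream stage sees
  the statistical regime it assumes; the generator's depth medians (5000 /
  3000) sit comfortably above them.
- **CLR.** log(x + pseudocount) centred per sample; pseudocount 1 by
  default (simplest documented choice).

## Dirichlet-multinomial mixture (enterotyping)

The component density is the multivariate Pólya distribution in the
exchangeable-sequence convention (no multinomial coefficient); the constant
cancels in responsibilities and in model-selection differences. EM details:

- **Initialisation:** k-means on CLR-transformed counts; restarts add
  uniform jitter to the responsibilities (3 restarts by default, 2 in the
  pipeline profile).
- **M-step:** weights from responsibility means; each α_k by five inner
  iterations of the responsibility-weighted fixed point
  α_j ← α_j · Σ_i r_ik[ψ(x_ij+α_j) − ψ(α_j)] / Σ_i r_ik[ψ(N_i+A) − ψ(A)],
  clipped to [1e-8, 1e6].
- **Convergence:** relative log-likelihood change below 1e-7 (after at
  least 5 iterations); non-convergence is flagged, not raised. EM
  monotonicity is property-tested at tolerance 1e-8.
- **Scores:** with d = K·G + (K−1) parameters, BIC = −2ℓ + d ln n,
  AIC = −2ℓ + 2d, and a Laplace approximation to the negative log evidence
  using the *diagonal* curvature of the mixture log-likelihood in α
  (ψ′ terms), −ℓ − (d/2)ln 2π + ½Σ log(−H_jj). This is an approximation in
  the Holmes style, not a claim of equivalence to any particular package.
  On wide tables (hundreds of genera) the diagonal Laplace is flatter than
  BIC and can entertain one extra component; BIC is the pipeline's
  selection criterion.
- **Genus contributions:** Σ_k |t(α_k/A_k) − t(α_1/A_1)| per genus, t = CLR
  of the component mean composition by default, raw proportions as the
  alternative. The two readings of "mean absolute differences" (CLR vs
  proportion space) are both implemented; CLR is default because that is
  the space in which discriminating genera are displayed.

## Succinotype classification

Strict inequalities on rD = nD/(nD+nP): D-type above 0.9, P-type below
0.1, mixed in between (inclusive of the boundaries), unclassified below 10
combined reads — the boundary total of exactly 10 is classifiable. "Mixed"
is defined explicitly since only D/P/excluded are defined by the rule;
classifiable-but-neither must land somewhere, and the strict inequalities
put the boundaries there. Genus matching is exact string matching with a
small alias map for spelling variants. Multi-sample subjects collapse to
one call with clear (D/P) calls prioritised over mixed. Scaling (nD, nP)
by c ≥ 1 can only move a sample from unclassified to classified, never
flip D/P/mixed — property-tested.

## Diversity and PERMANOVA

Shannon uses the natural log (documented constant); Pielou is defined as 0
at richness 1. Bray-Curtis is computed on counts, Jaccard on
presence/absence. PERMANOVA is the distance-based linear model: Gower
centring G = J(−D²/2)J, SVD-based projectors, SS from trace identities;
p = (1 + #{F* ≥ F}) / (1 + n_perm) so 0 is never reported. Marginal tests
compute the focal term's SS as the gain over the covariate-only model and
permute only the focal factor's labels, holding covariate assignments
fixed (a simple scheme chosen over Freedman-Lane for transparency; the
calibration test shows nominal type-I error under the null). The default
permutation count is 999. The single-factor pseudo-F is cross-checked
against scikit-bio's PERMANOVA in the test suite.

## Differential abundance

Wilcoxon rank-sum with exact enumeration for combined n ≤ 20 without
ties, normal approximation with tie correction otherwise (the switch point
is standard practice). BH families are per (stratum, group-pair) —
matching per-panel reporting conventions — rather than one global family.
Age strata are empirical tertiles with ties to the lower tertile.
Direction is the natural-log fold change of mean relative abundance with a
1e-6 stabiliser. ANCOM-BC2 is *not* reimplemented: `ancombc2_hook`
merges externally computed results into the report where they would slot
in. Zero-denominator Basidiomycota/Ascomycota ratios get a +0.5
continuity correction on both phyla and are flagged.

## Network inference

The chain is prevalence filter → CLR per kingdom → column concatenation →
covariance → StARS-selected graphical lasso → partial-correlation edges.
Three numerical choices deserve explanation:

1. **Basis-covariance de-centring.** The CLR transform centres each
   sample, so its covariance is S = FΣF with F = I − J/p: even independent
   taxa acquire exact off-diagonal covariance ≈ −σ²/p. At large p this is
   negligible; at desk scale (p ≈ 30-150) it masquerades as stable negative
   association. Assuming the basis covariance is sparse, the centring is
   undone in closed form (solve diag(Σ) from diag(S), add back the
   rank-one terms); the correction is exact for diagonal Σ with residual
   error O(‖offdiag‖/p). The corrected matrix is clipped to a spectrum
   floor of 1e-3 of its largest eigenvalue for solver conditioning.
2. **Path processing and tolerances.** The λ path is 30 log-spaced values
   from λ_max = max|S_offdiag| down to λ_max/100. Because StARS monotonises
   instability by a running maximum from the sparse end, the selected λ is
   fully determined at the first β-crossing, so the path is processed
   λ-by-λ across all subsamples and stops there — an exact shortcut.
   Subsample fits use tol 1e-3 / 10 sweeps (they contribute only edge
   supports, which stabilise well before the objective); the final refit at
   λ* uses the contract tolerance 1e-4. Warm starts carry along the path.
   An ill-conditioned coordinate-descent failure falls back to LARS mode.
3. **StARS at the prescribed subsample size.** Subsampling is 80% with 50
   repetitions and β = 0.05 (the classical default threshold). The
   classical calibration of β assumes subsamples of size ~10√n; 80%
   subsamples overlap heavily, so full-dataset sampling noise persists
   across subsamples, registers as *stable*, and makes selection liberal:
   at p = 30, n = 200 a diagonal-precision null typically retains a
   handful (≈3-18) of noise edges at the selected λ rather than an empty
   graph. This is a property of the prescribed parameter combination, not
   of the implementation; the recovery F1 on structured truth is
   unaffected (≥ 0.8 on band precision). Users wanting stricter null
   behaviour should lower β or increase n.

Edge weights are partial correlations from the selected-λ precision; the
sign convention (positive weight = positive association) matches the
pink/blue display convention, the magnitude is an extension. Per-group
networks apply the 20% prevalence filter within the group.

## Network statistics

- Path-based metrics use 1/|weight| edge lengths (strong association =
  short path); an unweighted mode exists. Disconnected graphs compute path
  metrics on the largest component and flag it.
- Closeness is harmonic centrality normalised by (n−1), well-defined on
  disconnected graphs. Eigenvector centrality and hub score are computed
  by dense symmetric eigendecomposition on |weight| — deterministic, and
  identical to each other on undirected graphs (both reported, as both
  names circulate).
- Signed modularity is Q⁺ − Q⁻ (positive-layer modularity minus
  negative-layer modularity, resolution on the positive layer), optimised
  by Leiden on a two-layer multiplex with layer weights +1/−1; deterministic
  given a seed. Note Q⁺ − Q⁻ may exceed 1 when the partition
  anti-aligns with negative edges.
- Keystones: z-score degree, betweenness, closeness, eigenvector centrality
  across nodes (population SD; numerically constant metrics contribute
  zeros), sum, take the top ⌈0.05n⌉. Ties at the cutoff are included and
  flagged, except the degenerate case where the cutoff equals the minimum
  score (hub-and-spokes, vertex-transitive graphs): then only nodes
  strictly above the cutoff are kept (or, if all scores are equal, the
  first ⌈0.05n⌉ in stable order), flagged.
- Robustness: curves run on the largest connected component, normalised by
  its initial size. Targeted attack removes the currently
  highest-betweenness node, recomputed after each removal (adaptive — the
  stronger, conventional attack; static ranking available). AUC is the
  trapezoid over the fraction-removed grid 0, 1/n, …, 1; R50 is the
  smallest fraction with LCC ≤ ½. Random attack averages 50 seeded
  permutations. Isolated vertices are pruned before metrics; components of
  ≤ 2 nodes are dropped only from visualisation exports, never from the
  metric input.

## Synthetic cohort generator

The generator emulates the study conditions every stage assumes, at desk
scale:

- **Groups** default to control/IBS/UC/CD with sizes 9/29/31/30 (99
  samples).
- **Bacterial counts** come from a two-component Dirichlet-multinomial
  mixture over 250 genera: a steep lognormal rank-abundance baseline with
  a dominant *Bacteroides*-like head, concentration 60, weights
  0.55/0.45, and a 10-genus block shifted 10-fold between components
  (half up, half down, renormalised) — two separable community states on a
  shared backbone.
- **Succinotypes** are written into the *Dialister* /
  *Phascolarctobacterium* columns after DMM sampling: each sample draws a
  class from the target fractions (43/30/18/9% D/P/mixed/unclassified),
  then (nD, nP) consistent with its class — combined load 2-5% of depth
  (at least 50 reads, so classes survive desk-scale rarefaction), rD in
  (0.94, 0.995) for D, (0.005, 0.06) for P, (0.25, 0.75) for mixed, and a
  combined total below 10 reads for unclassified, matching the exclusion
  rule by construction. A per-group odds parameter can tilt D-type
  membership; the default is independence so group tests have a true null.
- **Fungal counts** are an independent single-component draw over 150
  genera; phylum labels alternate 2:1 Basidiomycota:Ascomycota so the
  cohort-level ratio lands in the ~2:1 regime the dysbiosis ratio operates
  in.
- **Metadata** uses group-typical rates (ages with CD youngest, higher
  calprotectin positivity in UC/CD, IBS-skewed abdominal pain, high
  carriage of the protozoan in controls with subtype mix 77/22/1).
  Metadata is generated independently of composition by default, so
  host-factor tests are calibrated under a true null.
- **Network scenarios** draw logistic-normal-multinomial counts from known
  sparse precision matrices (band, block-cluster, preferential-attachment
  tree), with diagonal inflation to guarantee positive definiteness.
- **Depths** are lognormal with medians 5000 (bacterial) and 3000
  (fungal). Real cohort depths are 1-2 orders of magnitude larger; the
  statistical structure, not the scale, is what downstream stages need,
  and small depths keep the full pipeline to a few minutes on one CPU.

What the generator does *not* emulate: ASV-level structure (tables are
genus-level; ASV aggregation is exercised on constructed tables in tests),
read-level artefacts (chimeras, primer effects), compositional covariance
between the succinotype layer and the rest of the community, fungal-
bacterial coupling (a joint cross-kingdom precision is possible via the
network scenario but is not the cohort default), and real-world
metadata-composition confounding unless explicitly switched on. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated generative assumptions, not performance on real sequencing
data.

## Pipeline and determinism

Every stage's seed is `blake2b("<master>:<stage>") mod 2^31`, so adding
stages never shifts existing streams. All writers use fixed float formats
and sorted JSON keys; no timestamps enter outputs. The manifest hashes
every file, and two runs with the same config and master seed are
byte-identical (asserted in the test suite). The full default run — 99
samples, 250 + 150 genera, seven networks (four cross-kingdom group
networks, three bacterial succinotype networks) — takes roughly 3-4
minutes on one CPU.

## Known limitations

- The DMM Laplace score uses a diagonal curvature; on wide tables it is
  flatter than BIC (see above).
- StARS with 80% subsamples is liberal on nulls at moderate n (see
  network section); edge-level inference should not be over-read, which is
  also why per-edge confidence is out of scope.
- Network inference does not adjust for host covariates; inferred edges
  are conditional dependencies among taxa given the data, nothing more.
- The marginal PERMANOVA permutation scheme is the simple label-permutation
  variant; exact exchangeability under covariates holds only approximately
  (calibration verified by simulation at the sizes used here).
- The parametric (t-test) branch exists as an option but the pipeline
  default is the nonparametric path throughout.
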