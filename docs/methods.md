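# Methods

This note documents the statistical procedures implemented in `xyyphen`,
the modelling choices behind the synthetic-cohort generator, and the
numerical conventions adopted where the underlying methodology leaves
room for interpretation.

## Normality-gated univariate testing (`descriptives`)

Each variable is screened with the Shapiro-Wilk test at α = .05
(`summarize_variable`); the gate decides both the descriptive form
(mean ± SD vs median [IQR]) and the test family. Conventions:

- **Two-sample t** (`two_sample_t`): the default `folded_f` variance rule
  follows the SAS convention — a folded-F test of the variance ratio at
  α = .05 selects the pooled statistic when equal variances are tenable
  and the Satterthwaite (Welch) statistic otherwise, which is why
  fractional degrees of freedom appear in output tables exactly when the
  variance test rejected. `variance_rule="welch"` forces Satterthwaite
  throughout. A zero-variance group makes the variance ratio undefined
  and raises rather than silently pooling.
- **Wilcoxon rank-sum** (`wilcoxon_rank_sum`): mid-ranks for ties,
  tie-corrected permutation variance, and a 0.5 continuity correction in
  the normal approximation (again the SAS default; switchable). When the
  combined sample is ≤ 10 the two-sided p comes instead from full
  enumeration of all group assignments of the pooled ranks, with
  p = min(1, 2·min(P≤, P≥)). On continuous data the two paths agree to
  within 0.02 at the crossover size; with heavy ties the enumerated p is
  the defensible one, which is why the exact path keys on sample size,
  not tie structure.
- **Pearson χ²** is computed *without* the Yates continuity correction:
  the uncorrected statistic is what reproduces the published contingency
  values from their printed counts. A zero margin raises with a pointer
  to `fisher_exact`, whose two-sided p sums hypergeometric probabilities
  no larger than the observed table's.
- **No multiplicity adjustment** is applied anywhere; α = .05 throughout,
  matching the descriptive reporting style of the cohort literature this
  package serves.
- **Classification rules** (`classify_delays_and_sld`): milestone delay
  means age *strictly greater* than 24 months — the boundary convention
  is not dictated by the source conventions, so exactly-24 counts as on
  time and is pinned by a unit test. Continence thresholds default to
  36 months (daytime/bowel) and 48 (nighttime) and are configurable.
  SLD = (any achievement standard score < 78) AND (FSIQ > 70); a missing
  FSIQ yields a missing flag, never False, and all cohort rates are
  reported with explicit denominators ("25/53 (47%)" style). FSIQ bands:
  average ≥ 85, borderline 70–84, mild 55–69, moderate 40–54.

## Diagnostic psychometrics (`psychometrics`)

Confidence intervals for sensitivity/specificity are Clopper-Pearson
(beta-quantile inversion of the binomial tails). The choice matters: with
9 diagnosed participants the printed intervals of diagnostic-accuracy
tables (9/9 → 0.66–1.00; 8/9 → 0.52–1.00; 7/9 → 0.40–0.97) are exactly
the Clopper-Pearson bounds, and at the returned endpoints the binomial
tail mass equals (1 − level)/2 to 1e-8 — the property the test suite
asserts.

AUC is the rank statistic (probability a random case outscores a random
control, ties ½). Its interval is a stratified bootstrap — cases and
controls resampled separately, 2000 draws, percentile bounds — keeping
one resampling framework rather than mixing in a DeLong variance. Both a
`score` mode (continuous instrument totals) and a `call` mode (the binary
cut-off calls) are exposed, defaulting to `score`; instrument positivity
cut-offs are configuration, not constants. Strata are defined by CBCL
internalizing/externalizing T ≥ 64; strata partition the evaluated
sample, and a stratum with an empty class keeps its row with NaN metrics
rather than disappearing.

## Reference-normalized profiles (`profiles`)

Z-normalization is the exact affine map z = (x − μ_ref)/σ_ref and is
invertible given the norms (`invert_z`); norms with σ ≤ 0 are rejected at
construction. "Younger than 18" is implemented strictly (age < 18.0);
the age cutoff is a parameter because reference cohorts differ in
coverage. Variables where higher scores mean more impairment can be
sign-flipped (`harmonize_direction`) so profile plots point one way;
the raw Z is what the contrast machinery consumes. Subgroup contrasts
reuse the descriptives gate verbatim, so a profile table and a cohort
table disagree only if their inputs do.

## Phenotype network (`network`)

- **Filter**: each variable's mean off-diagonal Pearson correlation m_i
  is standardized over variables; z_i < τ = −2 removes the variable. The
  filter runs *once* on the full-sample matrix, not per bootstrap draw
  and not iterated — re-standardizing after removal could cascade, and
  the removed set is meant to be a global statement about the battery.
- **Bootstrap co-clustering**: per draw, participants are resampled with
  replacement (n = 64 by default), pairwise-complete correlations are
  recomputed, the cluster number k is chosen by the gap statistic, and
  the variables are cut from an average-linkage tree on d = 1 − r. Raw r
  (not |r|) is the default, consistent with the filter's ability to
  produce negative mean correlations; an |r| mode exists. The consensus
  entry (i, j) is the fraction of valid draws co-clustering i and j; a
  variable constant within a draw drops out of that draw only, with
  per-pair denominators tracked.
- **Gap statistic**: variables are represented by their correlation
  profiles (rows of the correlation matrix). Dispersion W_k is the
  Tibshirani sum of within-cluster pairwise squared Euclidean distances
  over 2·cluster size; the reference distribution draws profiles
  uniformly over each coordinate's observed range (the simple reference
  box), n_ref = 50 draws, clustered by average linkage on Euclidean
  distance. Selection takes the smallest k with
  Gap(k) ≥ Gap(k+1) − s(k+1). Observed partitions use the same 1 − r
  tree that produces the draw's final partition, so the k that is
  selected is the k that is used.
- **Consensus Louvain**: L seeded Louvain runs at resolution γ on the
  weighted consensus graph; if runs disagree, the run-association matrix
  (pairwise co-assignment fraction) is itself reclustered by another L
  runs, iterating until all runs agree — the standard consensus-clustering
  reduction. γ defaults to 1.2 and can be chosen from the versatility
  curve.
- **Versatility**: for node i and a pair of runs, agreement on partner j
  means the runs concur on whether i and j co-occur in a module;
  versatility(i) = 1 − mean agreement over partners and run pairs. It is
  0 when every run assigns i identically and approaches 1 under maximal
  instability. The curve reports the global mean per γ; γ* is the first
  interior local minimum (ties toward smaller γ), a perfectly flat curve
  returns the grid midpoint with a warning. On strongly modular
  consensus matrices the curve is flat at 0 across a wide γ-plateau — any
  γ* inside the plateau reproduces the planted partition, which is the
  property the acceptance suite checks. The versatility formula is a
  documented, swappable choice: node-level assignment-consistency
  definitions vary across the community-detection literature.
- **Export**: GraphML plus an edge-list TSV and node table; node
  `strength` is the variable's mean off-diagonal correlation (the
  node-size convention of consensus-network figures), coordinates come
  from a seeded Fruchterman-Reingold layout.
- **RNG discipline**: one master seed; draw b uses
  `SeedSequence([seed, b])`, so extending B preserves earlier draws and
  results are independent of execution order.

## Synthetic cohort generator (`cohort`)

The generator emulates the study conditions of a densely phenotyped
single-center XYY cohort: n = 64 (25 prenatal/birth vs 39 later
diagnoses), 29 variables spanning six instrument families, DSM-5 ASD
prevalence 9/63, and an external ASD reference population of declared
size 1877 males.

- **Copula + marginals**: latent scores are multivariate normal with a
  block target correlation (within-module r_in, between-module r_out,
  r_out < r_in enforced; defaults r_in = 0.5, r_out = 0.15 — values
  typical of correlated clinical batteries, chosen once). Standard-score
  variables map affinely to their published cohort mean/SD; milestones
  and skewed symptom totals map through exp(μ + σz) with μ at the
  published median and σ from the IQR, preserving the rank structure
  while producing the right-skew real milestone distributions show. For
  normal marginals the observed Pearson correlation converges to the
  latent target; for log-normal marginals the copula preserves rank
  correlation and attenuates Pearson r slightly — planted-recovery tests
  therefore use normal-marginal variables.
- **Group effects** are standardized postnatal-deficit shifts applied on
  the latent scale, centred so the full-sample marginal is preserved
  (prenatal + (1 − f)δ, postnatal − fδ). Defaults are back-computed from
  the published group means (e.g. 0.72 SD for processing speed, 0.86 for
  SRS-2 total); direction follows each variable's higher-is-worse flag.
- **Diagnosis**: a latent liability (weighted sum of ASD-feature latents
  plus unit noise) thresholded at its empirical quantile, so the target
  prevalence is hit exactly; community ASD diagnosis adds an
  over-diagnosed tail on top of all true cases, emulating the observed
  gap between community labels and research-criteria diagnoses.
- **Screeners** are binary calls with planted sensitivity/specificity;
  questionnaire screeners optionally lose specificity among participants
  with CBCL T ≥ 64, planting the behavior-problem vulnerability the
  stratified evaluation is designed to detect.
- **Missingness** is MCAR per variable at rates mirroring published
  per-row denominators (heaviest for achievement subscales), with an
  optional by-group multiplier. **Clipping** to instrument floors and
  ceilings is applied last and recorded per cell so tests can exclude
  clipped entries. A non-PSD block target is repaired by eigenvalue
  clipping with a warning (or rejected, naming the offending blocks, when
  repair is disabled).

What the generator does *not* emulate: item-level responses, longitudinal
trajectories, informant disagreement, non-random missingness beyond the
group multiplier, and any dependence of measurement error on ability.
Passing recovery tests therefore demonstrates that the pipeline machinery
is correct and calibrated under a known truth, not that real XYY data
have three modules.

## Problem sizes and determinism

Published-depth runs use B = 1000 bootstrap draws and L = 1000 Louvain
runs (the full-scale acceptance computation uses exactly that). The test
suite exercises the same pipeline at reduced depth — B = 200, L = 200
across 50 seeds for planted-module recovery; 1000 replicates for type-I
calibration; 10,000 for interval coverage — sizes chosen so the whole
suite completes in minutes while keeping Monte-Carlo error well inside
the asserted tolerances. Identical config and seed reproduce
byte-identical CSV/TSV/GraphML outputs; the pipeline manifest records
SHA-256 checksums to make that checkable.

## Known limitations

- The gap-statistic reference clusters uniform profile draws on Euclidean
  distance while observed variables are cut on 1 − r; the mild mismatch
  is deliberate (1 − r is undefined for box-uniform reference points) and
  documented rather than hidden behind a different observed-side metric.
- Louvain run-to-run randomness is driven through Python's `random`
  module (the igraph binding's RNG), so consensus results are
  reproducible per seed but not portable across igraph major versions.
- Fisher's exact test and the Wilcoxon exact path are enumerated, which
  is exact but only practical at the small counts where they are used.
- The AUC bootstrap can be optimistic when a stratum holds very few
  cases; rows with ≤ 5 cases should be read through their (wide) exact
  proportion intervals instead.
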