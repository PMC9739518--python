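# Methods

## The model

The package treats spirit quality grading as a two-group classification and
association problem over volatile-compound profiles. Its core quantity is
the odor activity value, `OAV_i = c_i / t_i`, the concentration of compound
*i* divided by its odor threshold in the matrix at hand (here 53% v/v
ethanol); `OAV ≥ 1` is the conventional bar for a compound to contribute to
perceived aroma, and the contributor count uses this inclusive comparison.
Because a compound may carry several odor descriptors (furfural: nutty,
sweet, bread), descriptor-level profiles use the accumulated OAV
`OAVsum_d = Σ OAV_i` over compounds carrying descriptor *d*; a
multi-descriptor compound deliberately contributes its full OAV to each of
its descriptors, so descriptor totals deliberately double-count — the totals
are odor-exposure profiles, not a partition of mass.

The central hypothesis is that *balances* — ratios of OAVs between different
odors — carry the quality signal. Features are `log2(OAV_a / OAV_b)` for
every ordered pair of compounds whose descriptor sets differ (same-set pairs
carry no between-odor information and are excluded), plus
`log2(OAVsum_d / OAVsum_e)` over all ordered descriptor pairs. Both
orientations are kept as separate columns: the forest may split on either,
and reporting both makes reciprocal balances visible in the importance
ranking. Log ratios of non-positive OAVs are undefined; such cells are
missing, features missing in more than half the samples are dropped, and
remaining gaps are median-imputed — the same "more than half" convention as
the compound sparsity filter. The feature count is configuration-dependent
(it follows from the odor map): the packaged 41-compound map yields 1602
compound-level plus 1122 descriptor-level ratios.

## Cleaning

Order is fixed: sparse-compound filter, then outlier removal; the pair is
idempotent on its own output. "Zero in more than half the samples" is a
strict inequality, and missing cells count as zeros because a below-LOD
measurement and a truly absent compound are indistinguishable downstream.
Outliers are scored per quality group with the local outlier factor on
within-group z-scored concentrations (without standardization, ethyl
acetate-scale compounds dominate the distance metric). LOF has no stated
contamination rate in this design, so the cut is the conventional score
threshold 1.5; `n_neighbors` defaults to 20 and is clamped to group size − 1.
The algorithm is deterministic, so no seed is involved.

## Classification

A random forest is tuned by exhaustive grid search — tree count {100, 300,
500}, maximum depth {3, 5, 10, ∞}, minimum leaf size {1, 2, 5}; a small,
standard grid spanning under- and over-fitting regimes at n ≈ 60 — scored by
stratified k-fold accuracy (k = 10, clamped to the minority class size).
Reported accuracy is the mean cross-validated accuracy of the best setting;
the ROC curve pools out-of-fold predicted probabilities; importances are
Gini importances of the best setting refit on the full cohort, with ties
broken lexicographically so rankings are stable. Class imbalance (39 vs 27
by default) is handled by stratification only, with no reweighting.
Everything is reproducible for a fixed seed.

## Screening and networks

Two-group screening uses the Kruskal–Wallis rank test with tie correction
(equivalent to a two-sided Mann–Whitney test at two groups) against a
chi-square with 1 df; the all-equal degenerate case takes the tie-corrected
limit H = 0, p = 1. Significance is the raw p < 0.05 rule; a
Benjamini–Hochberg option exists but is off by default, matching the
uncorrected screening convention. Co-abundance networks connect variable
pairs with |Pearson r| > 0.6; negative edges are kept and sign-annotated.
The r-threshold is the edge criterion — p-values are attached as annotations
only, with no multiplicity correction. Compound networks are built on
concentrations; since OAV is a per-compound rescaling, Pearson r is
identical on OAVs, and descriptor networks use the accumulated OAVs. PCA
(for ordination) z-scores variables by default and fixes component signs by
the largest-absolute-loading-positive convention.

## The synthetic cohort generator

The generator emulates the cohort design the pipeline assumes: two groups
(default 39 vs 27 samples) over the packaged 41-compound reference table,
with per-compound, per-group log-normal OAVs whose arithmetic mean and sd
match the reference moments (`σ² = ln(1 + s²/m²)`, `μ = ln m − σ²/2`).
Log-normal marginals fit positive, right-skewed concentration data and
accommodate the several reference compounds whose sd exceeds the mean.
Correlation blocks are imposed through a Gaussian copula (correlated latent
normals exponentiated through each marginal); the realized Pearson r on the
log-normal scale is attenuated relative to the latent ρ — a ρ = 0.8 block
lands near r ≈ 0.75–0.8 for moderate coefficients of variation — which the
recovery tests account for. Below-LOD zeros are injected independently per
cell *after* correlation imposition so sparsity does not distort the copula
calibration. A planted ratio effect scales the numerator's second-group
mean and sd together by 2^shift; scaling both preserves the coefficient of
variation, making the expected between-group difference in
`log2(OAV_num / OAV_den)` exactly the shift rather than approximately so.
OAVs become concentrations by multiplying each compound's threshold, so a
round trip through the OAV engine recovers the generated values.

What the generator does *not* emulate: instrument-side effects (detector
response, drift, censoring at the LOD rather than random zeros), the
esterification/hydrolysis chemistry that couples ester/acid pairs in real
spirits, heavy-tailed contamination, and any group difference beyond the
reference moments and explicitly planted effects. Passing recovery tests
therefore demonstrates that the pipeline detects the structures it targets
at realistic sample sizes and noise levels — not that real cohorts contain
such structures.

## Numerical and scale choices

- z-scoring uses the population (ddof = 0) convention, so standardized
  columns have sd exactly 1 at finite n.
- Correlation p-values use the t-transform of r with n − 2 df; |r| = 1 maps
  to p = 0 and constant columns to NaN.
- Calibration lines require ≥3 points with distinct concentration ratios;
  inversion of a flat line is refused.
- Simulation-heavy tests and the acceptance script run the classifier with a
  single-point grid (300 trees, unlimited depth, leaf 1) and few folds when
  only importances or planted-effect recovery are measured — importances
  come from the refit on the full cohort, so the fold count does not affect
  them — while the full default grid with 10 folds is exercised on a small
  matrix. Moment-recovery checks use n = 10,000 per group; null calibration
  uses 50 seeds × 100 variables; end-to-end recovery uses 20 seeds at the
  default 66-sample design.

## Known limitations

- Recovery of a *specific* planted ratio pair in the importance top-10 is
  unreliable by construction: scaling one compound's distribution shifts
  every ratio involving it (~80 compound ratios plus the descriptor ratios
  it feeds), and Gini importance splits across these correlated informative
  features, systematically favouring ratios against low-variance
  denominators. The pipeline reliably detects the planted effect (high CV
  accuracy, planted-numerator ratios dominating the importance head, the
  pair flagged by the rank test) without reliably ranking that exact pair
  first; interpretation of single ratio features should always be made
  jointly with their correlated neighbours.
- Perceptual interactions (masking, synergy) are out of scope; networks and
  ratios describe co-abundance, not perception.
- The Kruskal–Wallis chi-square reference is asymptotic; at very small group
  sizes its p-values are coarse relative to the exact permutation law (the
  tests quantify this on 3-vs-3 splits).
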