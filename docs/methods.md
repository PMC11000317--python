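# Methods

## Problem setting

The package models a small longitudinal biomarker study: 20 amyloid-positive
older adults, 12 of whom remained cognitively stable over follow-up and 8 of
whom declined by at least 2 points on the MMSE (the decliner rule, applied
first-to-last visit by default; baseline-to-minimum is available). Two omics
blocks are measured on baseline plasma: a ^1H-NMR bucket table (~102
variables; several buckets can report the same metabolite, e.g. four buckets
for 3-hydroxybutyrate) and an SFC-HRMS lipidomics table (~290 species).
Neither block alone supports a valid supervised model at this sample size;
the package's core claim is that integrating the blocks recovers a small,
stable metabolite signature that discriminates future decliners.

## Preprocessing

NMR bucket tables are normalized to total intensity (each spectrum divided
by its summed bucket area), removing overall-concentration differences.
Lipid intensities arrive relative to per-subclass internal standards and are
not re-normalized (configurable). Pareto scaling — centering and dividing by
the square root of the per-feature SD, the intermediate between centering
and unit-variance scaling — is the single-block convention. Scaling
parameters are always learned on training rows only and reapplied verbatim
to held-out rows; this is enforced by tests that mutate held-out rows and
assert the learned parameters are unchanged. Fold changes
(mean Decline / mean NoDecline) are computed on normalized, unscaled
intensities, so they remain ratios on the measurement scale.

## Single-block models

PCA is a thin SVD on the column-centered matrix, used for structure and
outlier inspection. PLS-DA is NIPALS against a centered two-column class
indicator: per component, a unit-norm weight vector maximizing covariance
with the outcome scores; X deflated by regression on the scores; Y kept
intact. Predictive validity is gated by cumulative Q2 from stratified 7-fold
CV,

    Q2cum(h) = 1 − Π_{a≤h} PRESS(a) / SS(a−1),

with PRESS pooling held-out indicator residuals and SS(a−1) the in-sample
residual sum of squares after a−1 components (SS(0) = total centered SS).
A model is valid only when max-over-h Q2cum exceeds 0.4, strictly. Fold
assignment is random, stratified, seeded, and deliberately symmetric under
class relabeling (one global permutation dealt round-robin within class);
the exact fold scheme of commercial PLS software is proprietary, so Q2
values on identical data may differ from it in the second decimal.

## Multiblock sparse discriminant model

The integrator is a design-weighted, cardinality-constrained multiblock
sparse PLS-DA. Per latent component it seeks one unit-norm weight vector
a_b per block maximizing the design-weighted sum of covariances among block
scores t_b = X_b a_b and the outcome scores t_Y = Y c. The inner loop
updates each block against the design-weighted sum of the other blocks' and
the outcome's scores, soft-thresholds at the (keepX+1)-th largest absolute
weight so exactly keepX features stay nonzero (threshold ties resolve to
the lowest feature index), and L2-normalizes; initialization is the
dominant singular direction of X_bᵀY. Convergence is a 1e-6 maximum score
change with at most 100 iterations (non-convergence returns the model with
a warning). After each component the block matrices are deflated by
regression on their own scores; the outcome indicator is reused for every
component. The design matrix defaults to "full" (weight 1 between blocks
and to the outcome), configurable.

Each block is standardized internally to unit variance on the training rows
(Pareto and center-only available). Unit variance is the convention of the
reference multiblock implementations, and it matters here: with Pareto
scaling the covariance objective inherits residual feature-scale weights
(variance = SD after Pareto), and high-baseline noise features crowd
low-baseline informative ones out of the selection.

Prediction projects held-out samples with the training scaling and the
deflation-aware rotation W(PᵀW)⁻¹ (training rows reproduce their training
scores exactly), assigns per-block classes by the nearest training class
centroid in score space (robust at n = 20; Euclidean distance), and
aggregates blocks by a vote weighted with |corr(t_b, t_Y)| on the training
data; vote ties go to the block with the larger weight. New blocks given as
data frames are aligned to training feature ids by column name. Performance
is the balanced error rate, BER = mean of the two per-class error rates,
insensitive to the 12:8 imbalance.

## Hyperparameter tuning and stability selection

The published protocol is bootstrap stability selection. Per stratified
bootstrap replicate (resampling within class, preserving class sizes):
first the component count is chosen from 1–5 with all features kept, then
keepX per block over the grids 1–9 (step 1) and 10 up to the block size
(step 5) — 28 NMR and 66 lipid candidates — both by minimizing pooled
4-fold-CV BER, ties to the smaller value. The keepX search is
blockwise-sequential by default (first block scanned with the second at
full size, then the second at the first's optimum); the exhaustive joint
grid is available. The replicate then refits on its whole bootstrap sample
and records which features carry nonzero loadings.

Two numerical choices matter at this scale. CV folds inside a replicate are
grouped: every copy of an original sample lands in one fold, because a
duplicate on both sides of a split rewards overfitting (without grouping
the modal component count drifts to 3–5 on one-factor data). And the CV
path runs the solver at tolerance 1e-4 with at most 30 iterations —
candidate ranking is stable well before the final-fit tolerance, and each
replicate costs ~400 fits. Fold counts clamp to the number of unique
samples per class in the replicate (a replicate whose minority class
collapses to one unique sample is redrawn; probability ≈ 8⁻⁷).

Frequencies aggregate per feature as (replicates selecting it)/(total
replicates), and collapse to metabolite level through the bucket
annotation: a metabolite counts as selected when any of its buckets is.
The final model is fitted on the entire sample with the modal component
count and modal keepX. The reported signature is the metabolite-level set
of final-model variables whose selection frequency reaches 60% — "the most
frequently selected variables of the final model". The frequency-only set
is also exposed (`TuningResult.frequent_metabolites`), but it is not the
signature: replicates whose BER argmin lands at a large keepX select
hundreds of features and push stable noise features past any frequency
threshold.

## Evaluation

Per-block ROC scores are the component-1 latent scores, oriented so the
Decline class has the higher mean (orientation logged). AUC uses the rank
(Mann-Whitney) formulation with midranks; the p-value is the two-sided
Mann-Whitney test — exact enumeration when n₁·n₂ ≤ 400 and tie-free, normal
approximation with tie correction otherwise. The choice of a rank-based
p-value follows the convention of the reference toolchain. Optimism is
estimated by stratified 2-fold CV repeated 10 times (20 held-out AUC
values): bias = mean cv AUC − apparent AUC. The clustered image map
clusters samples and selected features (Euclidean distance, complete
linkage, deterministic leaf order) and carries its row/column permutations
as data alongside the rendered figure.

Baseline clinical statistics use Fisher's exact test (two-sided
point-probability rule, which reproduces the published baseline table's six
2×2 p-values to three decimals; exact r×c enumeration available behind a
flag for multi-level rows) and the Mann-Whitney U test for continuous
covariates; per-row N reflects missing values.

## Synthetic data generator

The generator emulates the study design: 12 + 8 samples, 102 NMR buckets,
290 lipids, 9 informative metabolites (7 polar, one spanning 4 buckets, so
10 NMR buckets, plus 2 lipids), a clinical table with no planted group
differences, and MMSE trajectories that the decliner rule relabels exactly.
On the log-intensity scale a per-block latent factor carries the class
effect,

    L_b = (effect/α)·c + √r_b·F + √(1−r_b)·G_b,

with F shared across blocks (r_b = block_corr), and each informative
feature loads on it with a per-metabolite sign, plus per-metabolite shared
noise and idiosyncratic noise with the variance split α² = 1/(1+noise_sd²),
α²+β² = ρ, γ² = 1−ρ. This makes the within-class feature variance exactly
1 — so effect_size is the class-mean separation in feature-SD units — and
the within-metabolite bucket correlation exactly ρ; combinations with
ρ < α² are rejected as non-positive-semi-definite. Intensities are
exp(0.25·z + b_j) with fixed per-feature baselines, giving strictly
positive, right-skewed, log-normal-like values on which total-intensity
normalization and fold changes behave as on real bucket tables.

Defaults: effect_size 1.5, within_metabolite_corr 0.9, block_corr 0.7,
noise_sd 1.0 (so half of each informative feature's noise variance is the
shared latent), log-scale 0.25. block_corr and noise_sd are assumptions —
no within-block correlation structure is published for data of this kind at
this scale — and are configurable. Because the class effect travels through
the shared latent, the latent's own sampling noise at n = 20 puts a floor
under in-sample separability: even an oracle discriminant restricted to the
planted features attains training BER exactly 0 in only ~3 out of 4
datasets (mean training BER ≈ 0.01). The generator does not simulate
chemical-shift drift, peak overlap, batch effects, or missing values, so
passing recovery tests says nothing about robustness to those; ground truth
is returned separately from the dataset so no pipeline stage can read it.

## Problem sizes used in tests

The test suite and the acceptance script run the full procedure at the
study's scale: 100 bootstrap replicates over the full grids on 5
independent synthetic datasets for signature recovery; 50 replicates for
null calibration; exhaustive enumeration oracles for the exact tests
(all 2×2 tables against hypergeometric enumeration, rank tests against
full permutation enumeration for group sizes up to 8). Property tests with
randomized inputs are derandomized for reproducibility.

## Known limitations

Two classes only; no missing-value handling; no orthogonal-PLS variant; the
design matrix, prediction distance and vote weighting of the original
analysis are not published, so defaults are declared rather than matched —
exact numeric agreement with any particular historical run is not expected,
and the acceptance checks are therefore property-based (recovery, nulls,
oracles) rather than value-matching. The bootstrap-BER landscape at n = 20
is noisy; the per-replicate argmin over keepX is faithful to the protocol
but individual replicates can select very large keepX, which is why the
signature is anchored to the final model's variables.
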