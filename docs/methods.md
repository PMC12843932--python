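# Methods

## Data model and the unit of independence

A feature table holds raw ion abundances for `n_obs` chromatograms over
`n_feat` lipid features, with per-observation metadata (individual,
replicate index, class, gender, acquisition batch) and per-feature metadata
(name, m/z, retention time, metabolite id). Every statistical operation in
the package treats the **individual**, not the row, as the unit of
independence: technical replicates of one serum extract are strongly
correlated, so fold assignment, label permutation and outlier planting all
operate on individuals. Missing intensities are carried as an explicit
boolean mask (NaN in the value matrix), never as a numeric sentinel.

## Pretreatment

The canonical order is impute → log10 → autoscale.

- **Imputation** runs along the observation axis within each feature
  column, in table row order (replicates adjacent), because missingness in
  LC-MS peak tables is per-feature ion detection. `linear` interpolates
  between the nearest observed neighbours; edge gaps take the nearest
  observed value, since a line is undefined with one support point.
  `moving_median` applies a centred 3-point window, ignoring missing
  entries, only at missing positions. Observed cells are never altered, and
  linear imputations stay inside the column's observed range.
- **log10** maps multiplicative measurement noise to additive noise;
  non-positive cells are an error rather than being silently offset.
- **Autoscaling** (mean-centre, divide by sample sd, `n−1` denominator)
  gives every feature unit variance. Because centring and scaling depend on
  the sample, they are *not* baked into the stored table: every
  cross-validation training split re-estimates them and applies them to its
  held-out fold, so no information leaks from test individuals.

Quality control uses coefficients of variation on **raw** intensities (the
standard LC-MS convention): intra-day CV% per batch averaged over batches,
inter-day CV% over all QC injections, with a 30% retention threshold. Batch
drift is operationalized as a permutation test on the mean pairwise distance
between batch centroids in the leading PCA scores (≥999 label permutations);
the package applies no drift correction or normalization beyond this check.

## Outlier screening

ROBPCA combines projection pursuit with a reweighted minimum-covariance-
determinant (MCD) step:

1. SVD reduction to the data's affine span;
2. Stahel–Donoho outlyingness `max_v |x·v − med| / MAD` over directions
   through pairs of observations (250·k random pairs, plus all exact pairs
   when n ≤ 50); the `h = ⌈α·n⌉` least outlying points are kept (α = 0.75);
3. classical PCA of the kept subset fixes the k-dimensional subspace;
4. a reweighted MCD fit (scikit-learn's `MinCovDet`) of the projected scores
   supplies the robust centre and eigenvalues.

Each observation gets a **score distance** (robust Mahalanobis distance
within the subspace; cutoff `√χ²_{k,0.975}`) and an **orthogonal distance**
(residual to the subspace; cutoff from the Wilson–Hilferty approximation —
OD^{2/3} is treated as normal with median/MAD location and scale). Points
beyond both cutoffs are *bad leverage points* and are what the screening
policy removes; `robust_plus_classical` additionally removes classical-PCA
points with large score distance that are extreme (|score| > 3 sd) on some
leading component. The number of components comes from a scree rule
(smallest k reaching 80% of the provided robust eigenvalue mass, capped at
10). Removals are reported by observation id, and screening is idempotent on
its own output at fixed cutoffs.

A caveat observed in simulation: an outlier individual shifted in a *random*
direction of a high-dimensional feature space projects only partially into
any low-dimensional subspace, so moderate shifts can be flagged as
orthogonal outliers rather than bad leverage points. Detection of planted
individuals is essentially exact once the shift is large (≈2 log10 units
per feature against 0.2 biological), and the Gaussian operating
characteristics (≥95% detection of planted bad-leverage points at ≤7% false
flags; n = 200, p = 10, k = 3) hold with wide margin.

## OPLS-DA

Single-response O-PLS: each orthogonal round computes `w ∝ X'y` (normalized),
`t = Xw`, `p = X't/(t't)`, the orthogonal weight `w_orth ∝ p − (w'p)w`, and
deflates X by the orthogonal component; the single predictive component is
fitted on the fully deflated matrix. Three total latent variables therefore
means one predictive plus two orthogonal components (`n_orth = 2` by
default, configurable). Two consequences are asserted after every fit:
orthogonal scores are uncorrelated with the response (< 1e-8), and fitted
values coincide with NIPALS PLS1 at `n_orth + 1` components (< 1e-8),
which the tests verify against an independent PLS1 implementation and
scikit-learn's `PLSRegression`.

VIP is computed from the predictive component (`vip_mode="predictive"`,
default), giving `VIP_j = √p·|w_j|/‖w‖` and the invariant `Σ VIP² = p`; an
SSY-weighted multi-component variant is available (`"total"`), though
orthogonal components explain essentially no response variance and both
modes agree in practice.

Continuous predictions are converted to labels by **Bayesian thresholds**:
Gaussian class-conditional densities with empirical priors fitted to the
cross-validated predictions; the decision boundary is the posterior-0.5
point nearest the midpoint of the class means (handling the two-root case of
unequal variances). Thresholds are reported per class on each class's own
coding scale, so symmetric data yields complementary thresholds summing
to 1. Classification by threshold is identical to argmax-posterior
classification.

## Cross-validation and subsampling

`make_block_folds` shuffles individuals (seeded) within class and deals them
into F contiguous blocks, stratified so every fold contains both classes;
fold sizes differ by at most one individual. Venetian-blinds assignment
(row i → fold i mod F) is provided for comparison runs only and warns when
replicates straddle folds.

The two-level subsampling index re-randomizes the partition `iter1` times
and, per partition × fold, draws `iter2` training sets holding exactly one
uniformly chosen replicate of every individual outside the test fold —
a logical matrix of shape `(iter1·iter2·F, N)` in (iter1, iter2, fold)
lexicographic order, with a memory cap that redirects oversized requests to
a streaming iterator. Test folds always contain **all** replicates of the
held-out individuals. `run_cv_ensemble` turns the index into
`iter1 · iter2` CV models, each contributing one complete cross-validated
prediction vector, Bayesian thresholds, a metric record (accuracy,
sensitivity, specificity, class error, AUROC, RMSECV) and a fold-averaged
VIP vector; a leakage guard asserts on every mask row that no training row
belongs to the test fold.

The default ensemble for tests and examples is 100 models (10 partitions ×
10 draws); study-scale runs (100 × 500) are a parameter choice away and
stream if the materialized mask would exceed the cap.

## Model-complexity selection

`select_lv_count` fits, for every CV model of an ensemble, OPLS-DA models
with 2..max_lv total latent variables, and records three votes per model:
the LV minimizing RMSECV, the LV minimizing class error, and the LV
maximizing AUROC; the mode of the pooled votes (smallest LV on ties) is the
selected complexity. The synthetic construction used to validate this
(`generate_latent_cohort`) plants one class-predictive latent direction and
two class-orthogonal structured directions that overlap the predictive
direction (cosine 0.7) at clearly separated variance scales (8 and 3 vs 0.3
unstructured noise). The separation of scales matters: equal orthogonal
variances form a single covariance eigenvalue cluster that one extra PLS
component absorbs, whereas two separated clusters overlapping the
predictive direction genuinely require two orthogonal components — total
complexity three. With these defaults the pooled vote selects 3 in the
large majority of random seeds (individual cohorts occasionally vote 2
or 4, which is why votes are pooled across cohorts rather than taking a
mode of modes).

## Feature selection

1. **Ranking.** Each CV-ensemble model orders features by its fold-averaged
   VIP; orderings are aggregated by **Borda count** (a feature earns one
   point per feature ranked below it, per model), with ties broken by mean
   VIP then feature index.
2. **Validation curves.** Cumulative prefixes of the ranking are evaluated
   with independent CV ensembles (seeds derived from (master seed, size));
   the first evaluated size is `n_lv + 1` because a model needs more
   features than components. The default grid is dense (step 1) up to 16
   features and geometric (×1.3) beyond, and the curve's *best point*
   minimizes the rank-sum over mean accuracy (desc), AUROC (desc), class
   error (asc) and RMSECV (asc), ties to the smallest size.
3. **Refinement.** Per pass: truncate at the best point; collect removal
   candidates from (a) flat-or-worse arrivals in the dense early region —
   which is what catches a collinear duplicate of an earlier feature — and
   (b) plateaus (≥5 consecutive evaluated sizes with mean-AUROC steps
   < ε = 0.002) whose features are repositioned to the front and re-scored;
   each candidate is removed singly and the curve re-run under the same
   derived seed as its baseline. A removal that worsens the best point on
   **any** of the four metrics by more than ε is reverted and the feature
   locked. The guard deliberately watches all four metrics: when classes
   are fully separable, AUROC and accuracy saturate at 1 and only RMSECV
   still registers the loss of a true biomarker — an AUROC-only guard
   silently cannibalizes real signal in that regime. The procedure stops
   when a pass changes nothing (or after `max_passes`), emitting candidate
   subsets in decreasing size.
4. **Best model and the biomarker call.** On the smallest subset a fresh
   ensemble is fitted; histograms (bin width 0.02) of accuracy, sensitivity
   and specificity define modal bins, the candidate set is the intersection
   of modal-bin membership (relaxed to ≥2 then ≥1 when empty), and the
   highest-AUROC candidate wins (lowest index on ties). Features with
   VIP > 1 in that model are the called biomarkers.
5. **Permutation test.** Class labels are permuted at the **individual**
   level (replicates move together) and a reduced CV ensemble is refit per
   permutation; the statistic is the cross-validated fraction of response
   variance explained (Q²-style), with the calibration fraction and the
   |correlation| between permuted and true labels recorded alongside.
   `p = (1 + #{Q²_perm ≥ Q²_obs}) / (n_perm + 1)`. Exchangeability demands
   that the CV geometry ignore the labels, so the permutation test uses
   non-stratified fold partitions — with stratified folds the observed
   labels would be privileged (perfectly balanced across folds) and the
   test measurably anticonservative (~12–14% rejections at nominal 5% in
   simulation; ~2.5–9% after the fix, consistent with binomial noise
   around 5%). Because the splits are label-independent they are scaled
   once and reused across permutations.
6. **PCA confirmation.** Classical PCA restricted to the selected features,
   with the absolute standardized mean difference of class scores on each
   leading component compared against the all-features PCA, mirrors the
   expectation that a genuinely informative subset sharpens unsupervised
   class separation.

## Synthetic cohorts: what they emulate and what they do not

`generate_cohort` builds intensities as
`10^(base_f + batch_{b,f} + effect·1[SCH, gender match] + bio_{i,f} + tech_{i,r,f})`
with `base_f ~ U(3,7)` log10 units, biological (between-individual) sd 0.2,
technical (replicate) sd 0.05 (a raw-scale CV of ≈12%, inside the usual QC
band), batch shifts of sd 0.02, completely-at-random missingness, and
outlier individuals shifted by a per-feature N(0, outlier_shift_sd²) common
to all their replicates. Batches are contiguous blocks of a *randomized*
acquisition order: assigning batches in class order would confound the
batch signature with class and hand the classifier a spurious multivariate
signal, which is a generator artifact no careful acquisition design would
produce. Defaults mirror the target study design (31 BD + 30 SCH × 3
replicates, 183 features, 129 metabolite ids, 4 batches). Planted effects
are parameterized on the log10 scale so detectability maps directly to the
standardized mean difference.

The generator does **not** emulate chromatographic peak shapes, adducts,
retention-time drift, missingness that depends on intensity, or correlated
lipid co-regulation; feature noise is independent across features. Passing
tests therefore establish the *procedural* correctness and calibration of
the pipeline under its own assumptions — homoscedastic log-normal noise,
exchangeable individuals — not performance on real serum lipidomes.

Two calibration facts worth knowing when interpreting runs:

- A single cohort has only 61 independent individuals, so a null cohort's
  cross-validated median AUROC scatters around 0.5 with sd ≈ 0.075 *between
  cohorts* (within one cohort the ensemble repeatedly sees the same chance
  separation). Null-calibration checks therefore pool models across several
  independent cohorts.
- Ranking features on the full cohort and validating prefixes by CV on the
  same cohort is selection-biased: on pure-noise data the selected point's
  apparent AUROC is far above 0.5. The bias is inherent to wrapper
  selection at this sample size; the honest null property — verified in the
  tests — is that chance-selected features carry nothing into an
  independent cohort, and the individual-level permutation test (applied to
  the full feature set) stays calibrated.

## Numerical choices and degenerate inputs

Sample statistics use the n−1 denominator; skewness is adjusted
Fisher–Pearson and kurtosis the matching small-sample-adjusted excess form;
rank-sum comparisons are exact for small tie-free samples and
normal-approximated with tie correction otherwise. Zero-variance columns,
all-missing features, single-class training splits, empty prediction
vectors and sub-minimal QC designs raise named errors rather than producing
silent NaNs (single-class splits inside an ensemble are skipped and
counted). All randomness flows through explicit integer seeds; child seeds
derive via `SeedSequence` and stay below 2³¹. Fitted models expose their
scaling parameters so held-out data is always brought to the training scale.

## Known limitations

- ROBPCA's direction search is stochastic (seeded); pathological geometries
  could in principle evade a 250·k-direction budget.
- The refinement procedure is greedy with a bounded trial budget per pass;
  it makes no optimality claim about the returned subset, only that
  recorded metrics never silently degrade past ε.
- The best-model "modal bin" construction depends on the 0.02 bin width;
  very small ensembles make modal bins noisy (≥100 models recommended).
- With fully separable classes the smallest subset tends to shed its
  low-weight companions, and the VIP > 1 rule on a pure-signal subset
  flags only the above-average half of it (Σ VIP² = p is a zero-sum
  budget); recovery statements are therefore phrased against the selected
  subset, with the VIP call as the shortlist within it.
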