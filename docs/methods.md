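# Methods

This note documents the models and procedures implemented in `modfuse`,
the assumptions behind them, the defaults and why they were chosen, what
the synthetic cohort generator does and does not emulate, and the
numerical decisions a maintainer should know about.

## Phenotype and preprocessing

The binary phenotype derives from the MNSI examination score (0–10):
prevalent case at baseline score ≥ 3; the incident task is defined only
for baseline controls, with a case at follow-up score ≥ 3 and exclusion
when the follow-up score is missing.  A missing baseline excludes the
sample from both tasks.

Modality-specific cleaning follows the cohort protocol:

* **Genotypes** (allele dosages 0/1/2): drop SNPs with missing rate ≥ 1%,
  minor allele frequency < 1%, or Hardy–Weinberg chi-square (1 df)
  p < 1e−10; then drop samples whose heterozygosity rate (fraction of
  dosage-1 calls among non-missing calls; genotype QC pipelines vary in
  this definition, so it is fixed here explicitly) deviates more than 3 SD
  from the cohort mean.  The HWE test is the chi-square goodness-of-fit
  against expected proportions at the observed allele frequency, with
  monomorphic SNPs assigned p = 1; a test cross-checks it against the
  exact Levene–Haldane distribution.  SNP→gene annotation uses 1-based
  inclusive coordinates and strand-aware windows, default 2 kb upstream /
  0.5 kb downstream (both configurable; published annotation window
  choices vary by orders of magnitude, and the smaller pair is the
  default here).
* **Metabolites**: drop features with > 70% missing values, impute the
  rest by k nearest neighbours (k = 10 by default; the protocol names the
  algorithm but not k).  Distances are root mean squared differences over
  features observed in both samples, so sparsely overlapping pairs are not
  penalised for vector length; each missing cell takes the mean of the k
  nearest samples observing that feature.  Samples with standardised
  Mahalanobis distance > 4 are then removed.  "Standardised" Mahalanobis distance has no single
  convention; here it means distance divided by √p, with p the
  dimension used, computed on principal components capturing 95% of
  variance whenever p ≥ n/2, and with diagonal shrinkage if the covariance
  is singular.
* **Clinical**: one-hot encode categorical variables (L observed levels →
  L indicators; single-level columns dropped), then drop variables with
  > 10% missing values.
* **All molecular layers** are z-scored per feature (sample SD, observed
  entries only, missing preserved); constant features are dropped rather
  than raising, since both synthetic and real data produce them.
  Technical covariates can be regressed out feature-wise by least squares
  with an intercept; rank-deficient covariate designs are rejected naming
  the collinear columns.

## Univariate ranking

Continuous layers use a two-group linear model with empirical-Bayes
variance moderation: residual variances are shrunk toward a scaled-F prior
(d₀, s₀²) fitted by method of moments on log variances, giving
t = Δ/√(s²_post(1/n₁+1/n₀)) with d₀ + d degrees of freedom.  With the
prior disabled the statistic reduces exactly to the pooled two-sample t
(tested against the closed form).  A feature identical to the label has
zero residual variance: the unmoderated t is capped at 1e8; the moderated
t is finite by construction because the prior dominates the posterior
variance.

Genotypes are scored per gene: principal components of the gene's
(mean-imputed, centred) SNP dosages up to 99.9% cumulative variance —
capped at min(n_snps, n_samples/10, n_samples − 2) components — are
regressed on the label by ordinary least squares, and the overall F-test
p-value maps one-sided to z = Φ⁻¹(1 − p).  Linear rather than logistic
regression of the binary label is deliberate, mirroring the gene-analysis
convention this step reproduces.  A competitive gene-set test (regress z
on set membership plus log unit count, one-sided p on the membership
coefficient) is available for gene-level set analysis.

Methylation probes are first scored like continuous features; each gene
then receives the minimum beta order-statistic score ρ of its CpGs'
normalised positions in the global p-value ranking, converted to a
calibrated gene p-value via the exact null distribution of ρ (see below),
and to z = Φ⁻¹(1 − p/2) signed by the mean member t.  The sign convention
is the package's choice — enrichment needs signed input and the
gene-level aggregation alone does not define one.

## Preranked enrichment

Features are ordered by statistic descending (ties by id).  The running
sum rises by |stat|^q / Σ_members|stat|^q at member positions (q = 1 by
default, classic weighted form) and falls by 1/(N − n_set) elsewhere; the
enrichment score is the extreme deviation, and the leading edge is the
members at or before the peak (up) or at or after it (down).  The public
single-set scorer enumerates the walk position by position so it agrees
bit-for-bit with a brute-force oracle; permutations use an equivalent
vectorised closed form over sorted member positions (identical to ~1e−13).
Significance comes from random same-size member draws — gene-label
permutation, fixed count (default 2000, minimum 100), not an adaptive
scheme — with the one-sided p computed among same-sign permutation scores,
which keeps null p-values uniform.  BH adjustment at FDR < 20% selects
sets; this lenient threshold intentionally admits weak effects for the
multivariate steps downstream.  Sets are size-filtered to [5, 500]
present members.  The provided set collection is assumed non-redundant;
no hierarchy pruning is performed.

## Robust rank aggregation

For an item with observed ascending normalised ranks r₍₁₎…r₍ⱼ₎ out of L
tested lists, ρ = min_{k≤j} P(Beta(k, L−k+1) ≤ r₍ₖ₎).  Normalised rank is
position divided by the ranked universe size, so partial lists are
handled naturally; an item absent from a list contributes no beta
candidate, but the order-statistic null and the ×L multiplicity factor
count **all** tested lists — including resamples screened out for
non-predictive models, which are tested lists that contribute no ranks.
This "missing at worst rank" treatment is what keeps sporadic appearances
conservative: counting only the lists an item appears in would let a set
that is top-ranked in 3 of 25 resamples reach ρ ≈ 1e−3 and break null
calibration (the resampled lists are strongly dependent, since resamples
share 80% of the data).  Corrected scores are BH-adjusted across items;
the 5% FDR cutoff defines the consensus.  An explicit Monte-Carlo
permutation mode estimates each order-statistic probability from random
rank vectors and must agree with the analytic betas within Monte-Carlo
error (tested).

ρ itself is a minimum over correlated candidates and is therefore not a
p-value.  Where a calibrated per-item p is required — the CpG→gene
aggregation — the exact null CDF of ρ is computed by a boundary-crossing
recursion on the counts N(b_k), with b_k the rank at which candidate k
equals ρ (O(n³), used for n ≤ 100; beyond that the Bonferroni bound is
numerically indistinguishable).  The consensus stages keep the simple ×L
bound, the convention of the aggregation literature this follows.

Rankings fed to aggregation order sets by adjusted enrichment p ascending.
Permutation p-values are discrete, so ties are common with small
collections; ties break by |ES| descending before set id.  Breaking by id
alone would park the lexicographically first set at rank 1 in every tied
list and inject systematic rank bias into the aggregation null.

## Cohort partitioning and selection protocol

Samples present in every modality form the final-training pool; samples
missing at least one modality form the per-modality selection pools, so
the two never overlap (audited).  Selection runs on stratified 80/20
resamples (default 100; class proportions within one sample of the cohort
ratio; stratified 5-fold splits inside each training part).  Per resample:
rank on the training split, enrich at FDR < 20%, train a class-weighted
elastic net on the union of significant sets' leading-edge features, and
screen at held-out AUROC > 0.5.  The kept resamples' set rankings are
aggregated at FDR 5%, and a final enrichment on the full selection pool,
restricted to the surviving sets, supplies the leading-edge feature panel.
The final enrichment uses the whole pool, which maximises power for the
surviving sets.  A `single_pass` flag (default
for the proteomic layer, which is too small to resample) replaces the
consensus with one enrichment on all selection samples.  The screen-stage
elastic net is tuned on a compact 5 × 5 grid (`screen_grid_size`); the
full 20 × 20 grid is specified for the integration stage, and the screen
only needs a reasonable model, not an optimal one.

Clinical selection tunes an elastic net per resample, refits the non-zero
coefficient features without penalty, ranks them by |Wald t| (the
`importance='coef'` mode ranks by |standardised coefficient| instead;
zero-coefficient features contribute no rank), and aggregates at FDR 5%.
Where the unpenalised refit is degenerate (perfect separation), the
penalised coefficients serve as the fallback importance, logged.

## Elastic net, metrics, calibration

The learner minimises mean weighted log-loss plus
λ(α‖β‖₁ + (1−α)/2‖β‖₂²) with balanced class weights w_c = n/(2 n_c).
Tuning enumerates `grid_size` evenly spaced values per axis on [0,1]²
(default 20 → 400 parameter sets — the λ grid is intentionally linear on
[0,1], not a log path, a deliberate fidelity choice), scored by
mean weighted log-loss across the stratified folds, ties toward larger λ
then larger α.  λ is swept descending with warm starts; λ = 0 is the
unpenalised fit (checked against a generic convex optimiser), and a fully
shrunk model gets its intercept set analytically to the weighted log-odds,
where the stochastic solver is imprecise.  AUROC is the Mann–Whitney
statistic (ties count ½), identical to trapezoidal ROC integration.
Platt scaling is a one-dimensional unpenalised logistic fit of the label
on the raw score, fitted on inner-CV held-out predictions (never on test
data) and applied as a strictly monotone map, so it cannot change AUROC.

## Integration

Forward selection starts from the configured baseline modality (clinical
by default; without one, the best single modality) and greedily adds the
candidate with the highest mean inner-CV AUROC of a freshly tuned model at
each step, until all modalities are included.  Hyperparameters are
re-tuned at every step, so each candidate is judged by the best model
its features support.  Each step's model is refit on the full
80% split, calibrated, and scored once on the 20% split.  Complexity k* is
the largest k whose test-AUROC distribution beats k−1 by one-sided
Wilcoxon rank-sum at p < 0.05 with no later significant step (rank-sum is
used although resamples are matched — a paired test would be the
natural alternative; k* = 1
when nothing improves).  The per-resample k*-model importances
(|coefficient| ranks, zero coefficients contributing no rank) are
aggregated at FDR 5%, and the final model is a tuned elastic net on all
training samples restricted to the consensus, with signed Wald
t-statistics from an unpenalised refit as reported importance.

Comparators: concatenation (one model on all panels' columns, duplicate
ids suffixed by modality) and ensemble stacking (per-modality out-of-fold
predictions feed an elastic-net meta model; the meta design is z-scored so
meta coefficient magnitudes are comparable — a heavily shrunk base model
emits near-constant predictions whose raw-scale coefficient is otherwise
meaningless; constant predictions are excluded).  A univariate p < 0.05
selector is included as the feature-selection baseline.

Every randomised stage derives its seed from
`master_seed + stage name (+ indices)` via a hash, so a full run is
bit-for-bit reproducible at a fixed seed and thread count 1, and an
instrumented usage log records which samples each fit, tuning and
evaluation consumed; tests assert that held-out ids appear only under
evaluation.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes —
not the biology.  Labels arise from a latent liability: standardised
planted-SNP dosages (weighted to a total contribution of `effect_size`)
plus standard normal noise, thresholded at the case-fraction quantile
(default 0.2, matching an imbalance of about 1:4).  Continuous layers are
unit-variance noise; members of a planted set additionally share an
equicorrelated factor (c = 0.3) and gain a class-mean shift of
`effect_size` SD.  The shift and the shared factor constitute one signal
module: at `effect_size = 0` the module is absent and every feature is
independent noise.  This matters because gene-label permutation
enrichment is structurally miscalibrated for correlated sets, and the
miscalibration would persist across the 80%-overlapping resamples —
keeping the factor under the null makes the pipeline's null behaviour
untestable rather than more realistic.  Methylation adds bimodal
M-value-like offsets (±3); genotypes are Binomial(2, MAF) with MAF
uniform in [0.05, 0.5]; SNPs and CpGs group into genes (2 per gene) so
the gene-level rankers are exercised; the clinical table mixes continuous
and thresholded-latent binary features.  Missingness is completely at
random per modality (genotypes at 0.2%, below the QC threshold), and
whole-modality blocks drop per sample at one minus the coverage
probability, with at least one modality always retained.  Per-modality
set counts are capped by feasibility (small panels carry fewer sets), at
default 10 non-overlapping sets of 10–20 members.

Not emulated: linkage disequilibrium, batch effects, longitudinal score
trajectories, realistic metabolite distributions, and informative
missingness.  Passing tests therefore demonstrate the pipeline's
statistical behaviour under its own assumptions, not performance on real
cohort data.

## Problem sizes in the test suite and acceptance script

The end-to-end properties run at desk scale, chosen to keep the default
suite and the acceptance script comfortably runnable on one CPU: null
calibration uses 25 seeded cohorts (15 in the script) of n = 400 with
five molecular modalities and 25 resamples each; planted-signal recovery
uses 10 cohorts (8 in the script) of n = 300 with a 20-member set at
1 SD; forward-selection checks use 20–25 resamples with a reduced 6 × 6
tuning grid and small panels; permutation counts are 300 in pipeline runs.
The genomic PC-regression ranker, the slowest per resample, is exercised
in its own unit tests rather than inside the resampled pipeline runs.
Thresholds (FDR 20%/5%, AUROC screen 0.5, effect 1 SD) are the protocol's
values, not tuned quantities.

## Known limitations

* The resampled lists feeding rank aggregation are dependent (80% shared
  data); the aggregation model assumes independence.  The
  total-list-count convention above is what keeps the procedure
  conservative in practice, and the null-calibration test measures
  exactly this.  The residual false-positive mode is a chance
  cohort-level enrichment that recurs across the overlapping resamples
  and therefore looks like consistent evidence; on null cohorts this
  affects a few percent of per-modality selections, within the 5% FDR the
  aggregation controls per selection.
* Gene-label permutation enrichment ignores inter-feature correlation
  within sets; correlated-but-null pathways in real data will inflate
  enrichment, as they do for the tools this step mirrors.
* The λ grid on [0,1] cannot express very weak penalties between 0 and
  1/19; a log-spaced path would be conventional but is deliberately not
  the default.
* The exact ρ null CDF is O(n³) and switches to the Bonferroni bound
  above n = 100 lists.
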