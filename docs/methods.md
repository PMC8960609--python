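# Methods

## The two-phase screening-before-testing design

`lncsurv` implements a two-phase strategy for finding expression features
(genes, here generically "lncRNAs") whose level — or whose pairwise
product — predicts right-censored overall survival, while adjusting for
clinical covariates throughout.

**Discovery phase.**

1. *Quality control.* Genes are removed if every observed value is zero or
   if more than 10% of values are missing (strictly greater than; exactly
   10% is kept). Samples are restricted to those with complete clinical
   covariates present in every input table, ordered by sorted sample id
   for run-to-run reproducibility.
2. *Screening.* A random survival forest ranks genes by permutation
   variable importance. Covariate adjustment is structural: at every
   internal node the candidate split set is the union of **all** clinical
   covariates and `mtry` randomly drawn genes, so no tree can avoid the
   covariates. Splits maximize the log-rank statistic over midpoints of
   sorted unique values; leaves carry the Nelson–Aalen cumulative-hazard
   mortality of their in-bag members. The out-of-bag (OOB) error of a
   forest is 1 − Harrell's C between ensemble OOB mortality and the
   observed outcomes (prediction ties count 1/2). Sliding-window
   sequential forward selection (SWSFS) then adds genes one at a time in
   importance order, refits the forest on the top-*k* set, smooths the
   OOB-error-versus-*k* curve with a centered moving average (default
   width 5, truncated at the boundaries), and selects the *k* minimizing
   the smoothed error (smallest *k* on ties).
3. *Testing.* Each candidate gene is tested by a covariate-adjusted Cox
   proportional-hazards model, `h(t) = h0(t)·exp(α1·gene + Σ βi·covi)`,
   and every unordered candidate pair by
   `h(t) = h0(t)·exp(α1·g1 + α2·g2 + α3·g1·g2 + Σ βi·covi)` with the
   product term as the focal coefficient. Benjamini–Hochberg FDR is
   applied separately within the main-effect family (k tests) and the
   interaction family (C(k,2) tests); a pooling switch exists but is off
   by default.
4. *Sensitivity intersection.* The same scans are rerun on the
   TMM-normalized count branch; a term is carried forward only if its
   FDR-q ≤ 0.05 in **both** branches with the same focal-coefficient
   sign. Direction agreement is the package's reading of "robustly
   significant" and can be disabled.

**Validation phase.** A discovery hit whose gene is not measured on the
validation platform is represented by a *surrogate*: the gene present on
both platforms with the maximum |Pearson r| (computed in the discovery
data on the modelling scale — the only dataset where target and candidate
are both observed) among those whose correlation FDR-q ≤ 0.05, BH-adjusted
per target; |r| ties break to the smallest gene id; Spearman is available
as an option. The retained models are refitted on the validation cohort
with surrogate expressions, and a term validates iff its focal p ≤ 0.05
and its focal log-HR has the same sign as in discovery. Consistency is
required of the focal term only — constituent main effects of a validated
interaction may flip. Histology-stratified refits (LUAD-only/LUSC-only,
histology dropped from the covariates) flag fits with fewer than 10
events per coefficient as unstable.

**Model comparison.** A basic Cox risk model (clinical covariates only)
is compared with an optimized model (covariates + validated genes and
interaction products) by time-dependent AUC at the 3- and 5-year
horizons. The ROC estimator is the cumulative-case/dynamic-control form
with Kaplan–Meier handling of censoring: cases are events by the horizon,
controls are survivors past it, and sensitivity/specificity at each score
cut point use conditional KM estimates of S(horizon) within the
score-defined groups; the AUC is the trapezoidal integral over all unique
cut points (on uncensored data this reduces exactly to the Mann–Whitney
statistic with ties counted 1/2). Inference for the AUC difference is a
percentile bootstrap (default 1,000 replicates): subjects are resampled
with replacement and **both models are refitted in every replicate**, so
refitting optimism is part of the resampled distribution (the
conservative reading); p is the two-sided sign-flip percentile p-value
with a +1/(B+1) continuity correction. Design columns that become
constant inside a resample (a rare indicator level vanishing) are dropped
for that replicate — a constant column only shifts the linear predictor,
leaving risk ranks and the AUC unchanged.

## Cox fitting

Newton–Raphson on the partial likelihood with Efron tie correction
(vectorized with segment sums), step-halving, a step cap of 5 in max-norm,
tolerance 1e-9 on the coefficient change, at most 50 iterations. When
every event time is distinct the Efron, Breslow and exact likelihoods
coincide and a faster cumulative-sum evaluation is used. Monotone partial
likelihood (an indicator level with no events is the common case under
the default clinical marginals) is accepted at the likelihood plateau
(|Δll| ≤ 1e-9·(|ll|+1)) and the drifting terms are reported in
`CoxFit.monotone_terms`; their Wald tests are uninformative but the other
coefficients are estimated normally, mirroring the behavior of standard
survival software. Scans discard a result only when the focal term itself
is monotone. Wald SEs come from the inverse observed information; 95% CIs
use the 1.96 normal quantile.

## TMM normalization

The trimmed mean of M-values between each library and a reference: the
reference is the sample whose upper quartile of nonzero relative
abundances is closest to the mean upper quartile (ties to the smallest
sample id). Per-gene M (log2 ratio of library-normalized abundances) and
A (average log2 abundance) are computed over genes expressed in both
libraries, double-trimmed at 30% (M) and 5% (A) using average-rank
boundaries, and combined by the precision-weighted mean with binomial
delta-method weights; factors are rescaled to geometric mean 1. The trim
proportions and weighting are the published defaults of the method — only
the method name is prescribed upstream. Note one property is only
approximate: multiplying one library by a constant leaves all M values
unchanged but slightly perturbs the precision weights, so factors move at
the ~1e-3 level (the Bioconductor reference implementation behaves
identically); the corresponding test uses a 5e-3 tolerance.

## The synthetic-data generator

The generator produces the statistical structure the pipeline needs, with
known truth:

* **Expression.** Latent log2 expression is blockwise-equicorrelated
  Gaussian (default blocks of 2 at r = 0.9), giving every informative
  gene a correlated partner — the surrogate that validation must find.
  The FPKM-like matrix is 2^latent (log-normal, positive); the count
  matrix is Poisson with mean `fpkm × count_depth × library_multiplier`,
  library multipliers log-normal (sd 0.3). `count_depth` defaults to 50,
  putting a few hundred reads on a typically expressed gene so that
  Poisson measurement noise is small relative to biological variation —
  the count branch then probes normalization, not a second, noisier
  assay. (At depth 10 the count branch attenuated interaction z-scores by
  ~40% and the sensitivity intersection discarded true interactions about
  half the time; the revision and its rationale are deliberate.)
* **Clinical covariates.** Age ~ N(66.02, 9.55²); pack-years a truncated
  normal (47.38 ± 29.96, ≥ 0); gender 58.8/41.2, race 89.6/9.1/1.3,
  smoking 68.9/31.1, stage 54.3/28.3/14.6/2.8, histology 48.7/51.3 —
  the discovery-cohort marginals of a 604-patient NSCLC study. The rare
  race level is kept deliberately: it exercises the monotone-likelihood
  machinery exactly as real data would.
* **Survival.** The linear predictor sums per-SD gene effects on z-scored
  log2 expression (the per-SD convention is a package choice; effect
  scales are not prescribed upstream), the interaction as the product of
  standardized expressions, and covariate effects (defaults: age 0.025/y,
  stage II/III/IV 0.4/0.8/1.1, male 0.15). Event times invert a Weibull
  baseline (default shape 1.2, scale 5.3 years, giving a ~3.9-year null
  median), chosen for its closed-form inverse; exponential is the
  shape-1 special case used in closed-form tests. Censoring is
  independent exponential with its scale root-found (Brent) so the
  realized censoring rate matches the target (59.60% discovery, 55.66%
  validation by default) — only realized rates are observable in real
  studies, so calibration is on the realized rate. All-event or
  all-censored draws raise rather than pass silently.
* **Truth placement.** Informative main-effect genes sit in distinct
  blocks (defaults: 3 genes at per-SD log HR 0.5); the interaction pair
  occupies the next two blocks with product log HR 0.6 **and own main
  effects (−0.37, 0.26)** — emulating the empirical situation in which a
  validated interaction pair's constituents are themselves prognostic
  (discovery HRs ≈ 0.69 and 1.30). A pure product signal with no
  constituent effects is nearly invisible to marginal log-rank splits, so
  the forest screen would have nothing to find; the constituent effects
  are what make a screening-then-interaction-testing design coherent.
* **Platforms.** The validation cohort is an independent subject draw
  from the same gene landscape; its platform keeps exactly
  floor(overlap × n_genes) genes (default overlap 0.7) and, with the
  force-missing flag (default on in the two-phase generator), all truth
  genes are dropped while their block partners are guaranteed kept, so
  validation must run through surrogates.

What the generator does **not** emulate: batch effects, probe-level
artifacts, platform-specific dynamic ranges, gene-length effects,
non-proportional hazards, or realistic lncRNA zero-inflation. Passing
tests therefore demonstrate that the pipeline recovers its own model
class under calibrated censoring and cross-platform missingness — not
robustness to those real-data pathologies.

## Problem sizes and seeds

Replicated studies in the test-suite and acceptance script use desk-scale
sizes chosen as the package's own defaults for a reproducible regression
suite: type-I error on 25 null replicates (100 genes, n=400); signal
recovery and two-phase validation on 10 shared replicates (60 genes,
n=700 discovery / 839 validation, ranking forest 150 trees, SWSFS forests
60 trees, k_max 15); the null pipeline on 10 replicates (30 genes,
n=604/839); bootstrap AUC power on 10 seeds (n=600, 200 bootstrap
replicates) and null CI coverage on 50 seeds (n=400). All randomness
flows through `numpy.random.SeedSequence` streams derived from a single
base seed per stage, so every stage is independently reproducible and
rerunning any stage from cached inputs reproduces the full-pipeline
artifact bit for bit.

## Known limitations

* The forest is a single-threaded reference implementation (numba kernels
  for the split search); it implements exactly one split rule
  (all-midpoints log-rank) and permutation importance, not the full
  feature set of production random-forest packages.
* Screening among tightly correlated twins (r = 0.9 partners) is
  intrinsically unstable in the sense that which twin of a pair enters
  the candidate set can be a coin flip; importance is shared. The
  recovery criteria average over replicates for this reason.
* The time-dependent ROC is the KM-weighted cumulative/dynamic estimator;
  it is not guaranteed monotone under heavy censoring (a known property
  of that estimator), and no nearest-neighbor smoothing is offered.
* BH-FDR assumes positive-dependence-compatible p-values; block
  correlation of genes satisfies this in simulation, but no attempt is
  made at dependence-adjusted FDR.
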