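# lncsurv

Two-phase *screening-before-testing* survival analysis of expression
features, for statisticians and computational biologists who want to find
genes — and gene–gene interactions — associated with right-censored
overall survival in expression cohorts, and to confirm them on a second
platform that may not even measure the same genes.

The pipeline, end to end:

1. **QC** — drop all-zero genes, genes with >10% missingness, and samples
   with incomplete clinical covariates.
2. **Screening** — a random survival forest in which every clinical
   covariate is a candidate at *every* split (structural covariate
   forcing), ranked by permutation variable importance (VIS); then
   sliding-window sequential forward selection (SWSFS): add genes in VIS
   order, track the out-of-bag error `1 − C`, smooth the error-vs-k curve
   with a centered moving window, and keep the top *k*\* genes at the
   smoothed minimum.
3. **Testing** — covariate-adjusted Cox models for each candidate,
   `h(t) = h₀(t)·exp(α₁·lncRNA + Σᵢ βᵢ·Covᵢ)`,
   and for every candidate pair,
   `h(t) = h₀(t)·exp(α₁·lncRNA₁ + α₂·lncRNA₂ + α₃·lncRNA₁·lncRNA₂ + Σᵢ βᵢ·Covᵢ)`,
   with Benjamini–Hochberg FDR per scan family, plus a TMM-normalized
   count branch; only terms with FDR-q ≤ 0.05 *and the same direction* in
   both branches go forward.
4. **Trans-platform validation** — genes absent from the validation
   platform are replaced by their *surrogates* (maximum significant
   correlation in discovery data); a term validates iff its focal p ≤ 0.05
   with direction consistent across phases. Histology-stratified refits
   check subgroup consistency.
5. **Model comparison** — basic (covariates-only) vs optimized
   (+ validated genes) Cox risk scores compared by time-dependent AUC
   (cumulative-case / dynamic-control, Kaplan–Meier censoring weights) at
   3- and 5-year horizons, with percentile-bootstrap CIs and p-values in
   which both models are refitted per replicate.

A fully tested synthetic-data generator produces two-platform cohorts
with known planted truth (block-correlated log-normal expression, Poisson
counts, Weibull-baseline Cox survival with root-finding-calibrated
censoring, clinical marginals of a large NSCLC cohort), so every stage
has a recoverable signal and a null. See `docs/methods.md` for the model
details and design choices.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
two-platform data (604 discovery / 839 validation subjects, 100 genes,
three planted main effects at per-SD log HR 0.5, one planted interaction
pair at log HR 0.6, all five truth genes forced off the validation
platform):

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_discovery_phase.py
python analysis/03_validation_phase.py
python analysis/04_km_and_modifier.py
```

`02_discovery_phase.py` prints (abridged):

```
SWSFS selected k = 10 (min smoothed OOB error 0.314)
planted genes among candidates: ['G0000', 'G0002', 'G0004', 'G0006', 'G0008'] (5/5)
retained main effects (significant in both branches):
  G0000: HR 1.63 (1.41, 1.89), q = 3.12e-10  <- planted
  ...
retained interactions:
  G0006:G0008: HR 2.31 (1.93, 2.77), q = 8.37e-18  <- planted pair
```

The forest screen kept all five planted genes (their correlated block
partners ride along, as they must at r = 0.9), and the planted pair has
the strongest interaction. `03_validation_phase.py` then maps the
off-platform truth genes to their partners (e.g. `G0008 -> G0009`,
r = 0.92) and re-tests on the validation cohort:

```
  G0000: PASS (validation p = 3.94e-14; both criteria met) <- planted
  G0006:G0008: PASS (validation p = 2.75e-09; both criteria met) <- planted
model comparison (discovery cohort):
  3-year: AUC_optimized 0.860 vs AUC_basic 0.630 (36.4% increase, 95% CI of delta [0.166, 0.290], p = 2.00e-03)
```

Every planted term validates through surrogates, and adding the validated
genes to the covariates-only risk model raises the 3-year time-dependent
AUC from 0.63 to 0.86. Finally `04_km_and_modifier.py` shows the
planted effect modification: the first pair gene is strongly protective
in the low stratum of its modifier (HR 0.29, p = 2.5e-14) and null in
the high stratum (HR 1.04) — the classic crossing-KM-curves pattern.

The same pipeline is scriptable from the shell (`lncsurv simulate`,
`qc`, `normalize`, `screen`, `test`, `validate`, `predict`, `run-all`)
over plain TSV/CSV dataset directories.

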