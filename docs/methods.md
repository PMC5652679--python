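# Methods

## The analysis

`grsurv` implements the standard weighted-allele-count genetic risk score
(GRS) workflow for post-prostatectomy biochemical recurrence (BCR):

- **Per-SNP association.** For each biallelic SNP, the effect allele is the
  cohort minor allele (variants are flipped and flagged if the supplied
  orientation is the major allele). With minor-allele frequencies `p1` in
  recurrent and `p0` in non-recurrent patients, the allelic odds ratio is
  `OR = [p1/(1−p1)]/[p0/(1−p0)]`. The standard error of `ln OR` is the
  Woolf estimate `sqrt(1/a + 1/b + 1/c + 1/d)` over the four allele-table
  cells (reconstructed as `2n × MAF` rounded to the nearest integer so that
  published, rounded frequencies can be used directly); the 95% CI is
  `exp(ln OR ± 1.96 SE)` and the p-value is the two-sided normal tail of
  `ln OR / SE`. When a cell is zero the Haldane–Anscombe +0.5 correction is
  applied and flagged. The alternative `logistic` method fits an additive
  (0/1/2) logistic regression by maximum likelihood (statsmodels Newton/IRLS)
  with optional covariates; complete separation yields a flagged,
  non-converged result. The allelic method is the default because it
  reproduces the published panel's odds ratios from their printed group
  MAFs to four significant figures, which identifies the published
  estimates as allele-table odds; the logistic path is retained as the
  textbook alternative.
- **Selection** keeps SNPs with p strictly below `alpha` (default 1e-3),
  ordered by p then rsID. No multiple-testing adjustment enters selection
  (mirroring the source procedure); Bonferroni and Benjamini–Hochberg
  columns are reported for information only.
- **Scoring.** `GRS = Σ g_j · w_j` with `w_j = ln OR_j`. Keeping the minor
  allele as the counted allele for protective SNPs (OR < 1, negative
  weight) is deliberate: it makes typical scores negative, consistent with
  the published score distribution (median ≈ −2.1, observed range
  −7.19…1.61, inside the attainable bounds ±2·Σ of same-signed weights,
  here −12.28…+4.05). Missing genotypes at a score SNP are imputed as twice
  the sample-set effect-allele frequency (an `omit` policy is available);
  the per-sample imputation count is reported. Risk groups split at a fixed
  cutoff of −2.0 (ties go to "high"); a cohort-median cutoff is available.
- **Survival.** Kaplan–Meier estimation and the k-group log-rank test use
  lifelines. The Cox proportional-hazards fit is a Newton–Raphson
  maximization of the partial likelihood written in-package so that both
  Efron (default; more accurate under the heavy ties of months-resolution
  follow-up) and Breslow tie handling are available, along with the score
  test at β = 0 (which equals the log-rank statistic for a single binary
  covariate when event times are untied). Convergence is max |Δβ| < 1e-9
  within 100 iterations with step halving; monotone likelihoods
  (separation) return a flagged non-converged model; exactly collinear
  covariates raise an error naming the pair. The fit agrees with lifelines
  to ≤1e-4 on tied data and exactly matches grid-search maximization of a
  hand-written partial likelihood on small fixtures.
- **The two nested models** use age (years), initial PSA (ng/ml), a
  high-grade Gleason indicator (≥8 vs ≤7; a single published HR for
  "Gleason score" implies one term — an ordinal coding is available), ECE,
  SVI and PSM; the clinico-genetic model adds the GRS as a continuous
  covariate (per-unit hazard ratio). The dichotomized GRS is used only for
  KM/log-rank. pT stage and bladder-neck invasion are carried in the
  phenotype table but excluded from the default models, matching the
  published multivariate table.
- **Incremental value.** In-sample predicted probabilities from the two
  logistic models feed ROC AUCs (Mann–Whitney with ties counted 1/2). The
  paired AUC difference is tested with the DeLong structural-components
  variance; a subject-resampling bootstrap (stratified by outcome) is the
  cross-check. The source software's "Mantel-Haenszel" ROC comparison is
  not an identifiable correlated-AUC method, so DeLong — the field
  standard — stands in for it. AUCs are apparent (in-sample) by default to
  match the published procedure; `cv_folds` switches to stratified
  cross-validated probabilities, which are less optimistic.

## Quality control

Samples are filtered first (the published order), then markers are
re-assessed on the surviving samples:

- sample call rate < 0.95; heterozygosity outside mean ± 3 SD (the filter
  is named in the source without a cutoff; ±3 SD is the conventional
  default and configurable); cryptic relatedness, implemented as the robust
  heterozygote/opposite-homozygote kinship estimator reported as π̂ ≈ 2φ
  with a 0.1875 ceiling — the lower-call-rate member of a flagged pair is
  dropped. π̂ needs many markers to be estimable (its SD at 100 markers is
  ~0.19, swamping the threshold), so the screen requires
  `relatedness_min_markers` (default 500) and is skipped with a warning
  below that.
- markers: monomorphic; missing call rate > 0.05; exact Hardy–Weinberg
  p < 1e-6.

The HWE test is the exact conditional (Levene–Haldane) test: conditioning
on the observed allele totals, the probability of every attainable
heterozygote count (same parity) is computed in log space and the p-value
sums those no more probable than observed (ties matched with a 1e-12
relative epsilon). No mid-p correction is applied — the plain exact test is
the common chip-QC default. The implementation is verified against
exact-rational enumeration for every genotype table with total ≤ 50.

The heterozygosity filter is single-pass: outlier limits come from the
input cohort, not recomputed iteratively, so applying QC twice is a no-op
on realistic data.

## The cohort simulator

The simulator generates cohorts with the statistical structure of the
source study: n = 912, event rate 212/912 = 23.2%, 16 signal SNPs at the
published control-group MAFs and allelic ORs plus 84 null markers at
uniform random MAFs, chip-like missingness (1.3e-4, i.e. a 99.987% call
rate), and clinical covariates at the published per-group prevalences (ECE
21.6%/71.7%, SVI 3.6%/32.5%, PSM 21.6%/60.8% in non-recurrent/recurrent
patients, group-specific Gleason and pT-stage tables, lognormal PSA with
group medians 7.4/15.4 ng/ml). The same seed always yields a bit-identical
cohort.

**Why the default outcome model is retrospective.** The published per-SNP
odds ratios are marginal, single-SNP estimates. Odds ratios are
non-collapsible: if all 16 SNPs entered one joint ("prospective") logistic
model at those coefficients, each SNP's marginal odds ratio would be
attenuated by roughly 25% at the panel's total genetic variance, and
single-SNP re-estimation could not recover the generating values. The
default generator therefore draws case status first (Bernoulli at the
target rate), then genotypes group-conditionally under HWE — controls at
`q0`, cases at the `q1` implied by `OR`, independently across SNPs — which
reproduces the published group MAFs and odds ratios exactly in
expectation. The joint logistic model remains available as
`outcome_model="prospective"` (all covariate terms mean-centered so the
baseline log-odds sets the event rate); it is the natural null/recovery
model for single-SNP logistic analyses.

Follow-up is in months. Event times are exponential with rate
`exp(η)/event_time_scale` where `η` shares the SNP score weights scaled by
`hazard_scale` (default ln 1.630, the published adjusted per-unit GRS
hazard ratio) plus the clinical log-hazards (defaults taken from the
published multivariate HRs: Gleason≥8 2.428, ECE 3.090, SVI 2.637, PSM
1.972, age 0.990, PSA 1.003), truncated to a 120-month horizon
(`event_time_scale` = 40 months baseline). Non-events are censored
uniformly on (1, 120) months. `censoring_rate` additionally forces that
fraction of subjects to non-event status.

What the simulator does **not** emulate: linkage disequilibrium (SNPs are
independent, so three published SNPs that are near-duplicates in the real
panel are independent here), genotype–covariate correlation, correlation
among clinical covariates within outcome group (drawing them independently
per group makes the simulated clinical model discriminate somewhat better,
AUC ≈ 0.93, than the published 0.844), population stratification, and
relatedness. Passing tests therefore demonstrate correctness of the
statistical machinery under a clean generative model, not robustness to
those real-data features.

## Numerical choices and edge cases

- Genotypes are float matrices with NaN as missing; half-calls in VCF
  (`0/.`) are missing (conservative chip-QC practice).
- HWE: monomorphic input returns p = 1 (single attainable configuration);
  all-zero counts are an error.
- Allelic OR: `p0 = p1` gives OR = 1 exactly (computed from frequencies,
  not reconstructed counts); inversion symmetry OR(p0,p1)·OR(p1,p0) = 1
  holds to machine precision.
- Cox: covariates are mean-centered internally (coefficients unaffected);
  |β| > 50 is treated as monotone likelihood.
- DeLong with zero variance (e.g. identical score vectors) returns p = 1
  when the difference is 0.
- Ties at the GRS cutoff are assigned to the high-risk group (fixed,
  documented choice).
- Pipeline stage failures halt with the stage name; artifacts from earlier
  stages are preserved, and an empty SNP selection is an explicit
  empty-model error at the scoring stage, not a silent success.

## Test problem sizes

The test and acceptance suites choose sizes that keep the full run in the
tens of seconds while leaving Monte-Carlo margins wide: odds-ratio CI
coverage uses 100 replicates at n = 2000 (coverage ≥ 90% per SNP);
HWE-oracle equality sweeps all tables with total ≤ 50; paired-AUC type-I
calibration uses 400 null replicates at n = 300 (acceptance band
0.02–0.085 around the nominal 0.05); the directional check (clinico-genetic
AUC above clinical, GRS Cox CI excluding 1) uses 20 seeds at the study size
n = 912 and requires 19/20.

## Known limitations

- The per-SNP p-values of the published panel sit just below the 1e-3
  selection threshold, so a fresh cohort of the same size selects only a
  subset of the 16 (a winner's-curse effect inherent to replication, not a
  defect); the published panel weights themselves are available in
  `grsurv.panel` for scoring without re-selection.
- Group-conditional genotype simulation fixes the *case/control* structure;
  it does not model disease incidence prospectively, so absolute-risk
  quantities (e.g. baseline hazard) are conventional, not estimates.
- The Woolf/Wald allelic p-values are slightly more conservative than the
  published per-SNP p-values (which appear to come from logistic Wald
  tests); the odds ratios and CIs agree.
- In-sample AUCs are optimistic by construction; use `cv_folds` for
  honest discrimination estimates.
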