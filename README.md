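# grsurv

Genetic risk scores for predicting **biochemical recurrence (BCR) after
radical prostatectomy** in prostate cancer.

After surgical removal of the prostate, a rising PSA (two consecutive rises
above 0.2 ng/ml) signals recurrence. Clinicopathological predictors — PSA,
Gleason score, extracapsular extension (ECE), seminal vesicle invasion
(SVI), positive surgical margins (PSM) — have limited accuracy, and exome
chip studies have proposed adding a polygenic **genetic risk score (GRS)**
built from SNPs associated with recurrence. `grsurv` implements that whole
analysis as a tested, reusable pipeline for statistical geneticists and
biostatisticians:

1. **QC** — marker filters (monomorphic, missing call rate > 5%, exact
   Hardy–Weinberg test p < 1e-6) and sample filters (call rate < 95%,
   heterozygosity outliers, cryptic relatedness);
2. **association** — per-SNP case–control tests against BCR status:
   allelic odds ratios
   `OR = [p1/(1−p1)] / [p0/(1−p0)]`
   from the group minor-allele frequencies (with Woolf SE, Wald CI and
   normal p), or additive logistic regression; SNP selection at p < 1e-3;
3. **scoring** — `GRS = Σ_j g_j · ln(OR_j)` over the selected SNPs, where
   `g_j ∈ {0,1,2}` counts copies of the cohort minor allele (protective
   SNPs contribute negative terms); dichotomization at a −2.0 cutoff;
4. **survival** — Kaplan–Meier curves and log-rank test by GRS group, and
   multivariate Cox proportional-hazards models (Newton–Raphson partial
   likelihood, Efron/Breslow ties) with and without the GRS;
5. **evaluation** — paired comparison of the clinical vs clinico-genetic
   logistic-model ROC AUCs by the DeLong structural-components test (with a
   bootstrap alternative).

Because no cohort of this kind is publicly deposited, the package ships a
**cohort simulator** that reproduces the published study structure: 912
subjects, 23.2% recurrence, a 16-SNP risk panel at the published group
minor-allele frequencies and odds ratios plus null markers, and Table-style
clinical covariate prevalences per outcome group. Everything downstream is
therefore testable end-to-end with no downloads.

## Worked example

```sh
grsurv run --out out/ --seed 1
```

prints (numbers are exact for this seed; every run is deterministic):

```
pipeline complete; report at out/run_report.json
  cohort: {'n_samples': 912, 'n_markers': 100, 'n_events': 217}
  qc: {'samples_before': 912, 'samples_after': 909, 'markers_before': 100, 'markers_after': 100}
  assoc: {'n_tested': 100, 'n_selected': 11}
  score: {'n_snps': 11, 'median_grs': -2.3501..., 'median_grs_no_bcr': -2.6537..., 'median_grs_bcr': -1.2776..., 'n_high': 339, 'n_low': 570}
  survival: {'logrank_chi2': 134.619..., 'logrank_p': 3.99e-31, 'grs_hr': 1.9398..., 'grs_hr_ci': [1.722..., 2.185...], 'grs_p': 1.03e-27}
  evaluate: {'auc_clinical': 0.9259..., 'auc_clinico_genetic': 0.9491..., 'auc_diff': 0.0231..., 'p_value': 3.06e-05}
```

Reading the output: of 912 simulated patients, 217 recur; QC drops 3
samples; 11 of the 100 markers reach p < 1e-3 at this cohort size (the 16
signal SNPs have true p-values near the threshold, so a fresh cohort
selects a subset); the score built from their ln(OR) weights has median
−2.35 overall and separates recurrent (−1.28) from non-recurrent (−2.65)
patients; the high-GRS group recurs much faster (log-rank p ≪ 0.001) and
the GRS keeps an adjusted hazard ratio of 1.94 per unit after controlling
for age, PSA, Gleason, ECE, SVI and PSM; adding the GRS raises the
in-sample AUC from 0.926 to 0.949 (DeLong p = 3×10⁻⁵).

All stage artifacts (`association.tsv`, `grs_model.tsv`, `grs_scores.tsv`,
`km_*.tsv`, `cox_*.tsv`, `auc_comparison.tsv`, `run_report.json`) are plain
TSV/JSON in the output directory; each stage can also be run in isolation
(`grsurv simulate|qc|assoc|score|survival|evaluate`). A fully commented
config with every key is at `examples/config.yaml`.

Library use mirrors the CLI:

```python
from grsurv.simulate import SimulationConfig, simulate_cohort
from grsurv.assoc import run_association, select_snps
from grsurv.grs import build_model, score_samples

genotypes, phenotypes = simulate_cohort(SimulationConfig(seed=1))
results = run_association(genotypes, phenotypes)           # sorted by p
model = build_model(select_snps(results, alpha=1e-3))      # ln(OR) weights
scores = score_samples(genotypes, model, cutoff=-2.0)
```

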