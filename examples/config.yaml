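# Full grsurv run configuration (all keys shown with their defaults).
# Run with:  grsurv run --config examples/config.yaml --out out/

# --- cohort: either point at files, or leave null to simulate -------------
genotypes: null        # path to a .vcf or genotype .tsv (null -> simulate)
phenotypes: null       # path to a phenotype .tsv
n_samples: 912         # simulated cohort size
outcome_model: retrospective   # or: prospective (joint logistic model)
n_null_variants: 84    # non-causal markers added to the 16-SNP signal panel
event_rate_target: 0.2324561403508772   # biochemical recurrence rate
censoring_rate: 0.0    # extra forced censoring fraction
missing_rate: 0.00013  # chip-like genotype missingness
hazard_scale: 0.4885800148186709        # per-GRS-unit log hazard (~ln 1.63)
event_time_scale: 40.0 # months; baseline mean event time
t_max: 120.0           # months; censoring horizon (10 years)

# --- quality control ------------------------------------------------------
marker_max_missing: 0.05       # drop markers with >5% missing calls
sample_min_call_rate: 0.95     # drop samples with <95% call rate
hwe_alpha: 1.0e-06             # exact Hardy-Weinberg p threshold
het_sd_limit: 3.0              # sample heterozygosity outlier limit (SDs)
relatedness_max_pihat: 0.1875  # cryptic-relatedness ceiling (pi-hat)

# --- association, scoring, survival, evaluation ---------------------------
assoc_method: allelic          # or: logistic
alpha: 0.001                   # strict p < alpha SNP selection
grs_cutoff: -2.0               # high/low risk-group split
gleason_coding: binary         # Gleason >=8 indicator (or: ordinal)
ties_method: efron             # Cox tie handling (or: breslow)
auc_method: delong             # paired-AUC test (or: bootstrap)
seed: 0
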