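"""Published 16-SNP biochemical-recurrence risk panel and cohort constants.

These are the exome-chip SNPs reported as associated (p < 1e-3) with
biochemical recurrence (BCR) after radical prostatectomy in a prospective
cohort of 912 Korean prostate-cancer patients, together with the printed
group minor-allele frequencies (no-BCR vs BCR), allelic odds ratios with
95% CIs, and p-values.  The panel doubles as the default signal set of the
cohort simulator and as the input for desk-scale reproduction of the
published odds ratios.

Alleles are written major/minor as published: ``other_allele`` is the major
allele, ``effect_allele`` the cohort minor allele whose frequency is
tabulated.  Negative ln(OR) weights (protective minor alleles) are kept as
such when the panel is turned into a score model.
"""

from __future__ import annotations

import math

import pandas as pd

from .io import VariantRecord

# variant_id, chr, other(major), effect(minor), gene, maf no-BCR, maf BCR,
# OR, CI low, CI high, p
_PANEL_ROWS = [
    ("rs4965121", "15", "G", "C", "", 0.05824, 0.1152, 2.106, 1.455, 3.047, 5.75e-05),
    ("rs1128966", "17", "C", "G", "NT5C3B", 0.1871, 0.1083, 0.5278, 0.379, 0.735, 0.000127),
    ("rs1046404", "17", "C", "G", "NT5C3B", 0.1871, 0.1083, 0.5278, 0.379, 0.735, 0.000127),
    ("rs1046403", "17", "A", "G", "NT5C3B", 0.1871, 0.1088, 0.5306, 0.381, 0.7388, 0.000145),
    ("rs781831", "17", "T", "C", "ZZEF1", 0.3565, 0.2593, 0.6317, 0.4963, 0.804, 0.000176),
    ("rs7009549", "8", "A", "G", "", 0.5121, 0.4124, 0.6689, 0.5379, 0.8316, 0.000283),
    ("rs12871532", "13", "C", "T", "", 0.3663, 0.2742, 0.6536, 0.5156, 0.8285, 0.000417),
    ("rs16964211", "15", "G", "A", "CYP19A1", 0.2952, 0.2097, 0.6335, 0.4895, 0.82, 0.000489),
    ("rs3133745", "8", "C", "T", "C8orf37-AS1", 0.2401, 0.1613, 0.6088, 0.4585, 0.8083, 0.000551),
    ("rs2071286", "6", "G", "A", "NOTCH4", 0.1693, 0.1019, 0.5565, 0.3955, 0.7831, 0.000672),
    ("rs10853489", "18", "A", "G", "", 0.4041, 0.4954, 1.448, 1.166, 1.797, 7.73e-04),
    ("rs7439186", "4", "C", "T", "AMBN", 0.1349, 0.2005, 1.607, 1.214, 2.127, 0.000842),
    ("rs2144425", "6", "A", "G", "OR12D3, OR5V1", 0.3113, 0.2281, 0.6539, 0.5087, 0.8406, 0.000866),
    ("rs3935295", "1", "G", "A", "PTPN7", 0.1607, 0.09677, 0.5594, 0.3948, 0.7927, 0.000959),
    ("rs4745571", "9", "T", "C", "PRUNE2", 0.1712, 0.2419, 1.545, 1.192, 2.004, 0.000966),
    ("rs17168761", "7", "T", "C", "AGMO", 0.3623, 0.2765, 0.6726, 0.5307, 0.8523, 0.000987),
]

PANEL_COLUMNS = [
    "variant_id",
    "chromosome",
    "other_allele",
    "effect_allele",
    "gene",
    "maf_no_bcr",
    "maf_bcr",
    "odds_ratio",
    "ci_low",
    "ci_high",
    "p_value",
]


def reference_panel() -> pd.DataFrame:
    """The 16-SNP panel as a DataFrame (one row per SNP, published order)."""
    return pd.DataFrame(_PANEL_ROWS, columns=PANEL_COLUMNS)


def panel_variants() -> list[VariantRecord]:
    """VariantRecords for the panel.

    Chip positions were not published; synthetic 1-based placeholder positions
    (ordinal within the panel) are assigned so the records are well formed.
    """
    return [
        VariantRecord(
            variant_id=row[0],
            chromosome=row[1],
            position=1000 * (i + 1),
            effect_allele=row[3],
            other_allele=row[2],
            gene=row[4],
        )
        for i, row in enumerate(_PANEL_ROWS)
    ]


def panel_weights() -> dict[str, float]:
    """ln(OR) score weight per panel SNP (negative for protective alleles)."""
    return {row[0]: math.log(row[7]) for row in _PANEL_ROWS}


# Cohort summary constants (prospective radical-prostatectomy cohort, n=912).
COHORT_N = 912
COHORT_N_BCR = 212
COHORT_N_NO_BCR = 700
EVENT_RATE = COHORT_N_BCR / COHORT_N  # 0.2324...

# Exome chip marker yield: successfully genotyped / attempted.
MARKERS_GENOTYPED = 242_186
MARKERS_ATTEMPTED = 242_901

# Clinicopathological covariate structure of the cohort (whole-cohort column).
CLINICAL_SUMMARY = {
    "age_mean": 66.24,
    "age_sd": 6.63,
    "psa_median": 8.30,
    "psa_log_sd": 0.90,             # lognormal spread matched to the printed SD
    "prostate_volume_mean": 36.91,
    "prostate_volume_sd": 16.04,
    "ece_rate": 303 / 912,          # extracapsular extension, ~33.2%
    "svi_rate": 94 / 912,           # seminal vesicle invasion, ~10.3%
    "bni_rate": 40 / 912,           # bladder neck invasion, ~4.4%
    "psm_rate": 280 / 912,          # positive surgical margin, ~30.7%
    "pt_stage_probs": {"pT2": 598 / 912, "pT3": 301 / 912, "pT4": 13 / 912},
    "gleason_probs": {6: 62 / 912, 7: 712 / 912, 8: 42 / 912, 9: 96 / 912},
}

# The same covariates split by recurrence status, for group-conditional
# simulation (no-BCR n=700, BCR n=212).
CLINICAL_SUMMARY_BY_GROUP = {
    0: {
        "age_mean": 66.33, "age_sd": 6.72,
        "psa_median": 7.40, "psa_log_sd": 0.86,
        "prostate_volume_mean": 36.44, "prostate_volume_sd": 16.14,
        "ece_rate": 151 / 700, "svi_rate": 25 / 700,
        "bni_rate": 11 / 700, "psm_rate": 151 / 700,
        "pt_stage_probs": {"pT2": 542 / 700, "pT3": 154 / 700, "pT4": 4 / 700},
        "gleason_probs": {6: 60 / 700, 7: 586 / 700, 8: 23 / 700, 9: 31 / 700},
    },
    1: {
        "age_mean": 65.99, "age_sd": 6.37,
        "psa_median": 15.43, "psa_log_sd": 0.98,
        "prostate_volume_mean": 38.46, "prostate_volume_sd": 20.45,
        "ece_rate": 152 / 212, "svi_rate": 69 / 212,
        "bni_rate": 29 / 212, "psm_rate": 129 / 212,
        "pt_stage_probs": {"pT2": 56 / 212, "pT3": 147 / 212, "pT4": 9 / 212},
        "gleason_probs": {6: 2 / 212, 7: 126 / 212, 8: 19 / 212, 9: 65 / 212},
    },
}

# Multivariate Cox hazard ratios of the clinical covariates (clinical model);
# used as default log-hazard effects by the cohort simulator.
CLINICAL_LOG_HAZARDS = {
    "age_years": math.log(0.990),
    "psa_ng_ml": math.log(1.003),
    "gleason_high": math.log(2.428),  # Gleason >= 8 indicator
    "ece": math.log(3.090),
    "svi": math.log(2.637),
    "psm": math.log(1.972),
}

# Per-unit hazard ratio of the risk score in the adjusted Cox model.
GRS_LOG_HAZARD = math.log(1.630)
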