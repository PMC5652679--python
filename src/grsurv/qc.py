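"""Marker and sample quality control for chip genotype matrices.

Filters follow standard exome-chip practice: samples are screened first
(call rate, heterozygosity outliers, cryptic relatedness), then markers are
screened on the surviving samples (monomorphic, missingness, deviation from
Hardy-Weinberg equilibrium by an exact test).  Every removal is recorded
with its reason(s) in a :class:`QCReport`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import GenotypeMatrix


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds.

    marker_max_missing: drop markers with missing-call fraction above this.
    sample_min_call_rate: drop samples with call rate below this.
    hwe_alpha: drop markers whose HWE exact p falls below this.
    het_sd_limit: drop samples whose heterozygosity is more than this many
        SDs from the cohort mean.
    relatedness_max_pihat: drop one member of each pair whose estimated
        genome-sharing proportion (pi-hat, ~2x kinship) exceeds this.
    relatedness_min_markers: pi-hat is only meaningful when estimated from
        many markers; the screen is skipped (with a warning) below this count.
    drop_monomorphic: drop markers with a single observed allele.
    """

    marker_max_missing: float = 0.05
    sample_min_call_rate: float = 0.95
    hwe_alpha: float = 1e-6
    het_sd_limit: float = 3.0
    relatedness_max_pihat: float = 0.1875
    relatedness_min_markers: int = 500
    drop_monomorphic: bool = True

    def __post_init__(self):
        for name in ("marker_max_missing", "sample_min_call_rate", "hwe_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must be in (0,1), got {v}")
        if self.het_sd_limit <= 0:
            raise ValidationError("het_sd_limit must be positive")


@dataclass
class QCReport:
    """Per-marker and per-sample QC statistics with kept flags and reasons."""

    markers: pd.DataFrame  # variant_id, call_rate, maf, hwe_p, monomorphic, kept, reason
    samples: pd.DataFrame  # sample_id, call_rate, heterozygosity, kept, reason
    summary: dict = field(default_factory=dict)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional test for Hardy-Weinberg equilibrium.

    Conditions on the observed allele totals and sums the probabilities of
    every heterozygote count (same parity, same allele counts) whose
    conditional probability does not exceed that of the observed count.
    Returns a p-value in (0, 1].
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValidationError(f"negative genotype count in {counts}")
    n = sum(counts)
    if n == 0:
        raise ValidationError("HWE test requires at least one genotype")
    n_ref = 2 * n_hom_ref + n_het
    n_alt = 2 * n_hom_alt + n_het
    rare = min(n_ref, n_alt)
    if rare == 0:  # monomorphic: a single attainable configuration
        return 1.0

    # Attainable heterozygote counts share the parity of the rare-allele total.
    hets = np.arange(rare % 2, rare + 1, 2)
    # Unnormalized log-probabilities of the conditional (Levene-Haldane)
    # distribution: P(h) ∝ 1 / (h! * ((rare-h)/2)! * ((2n-rare-h)/2)!) * 2^h
    from scipy.special import gammaln

    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln((rare - hets) / 2 + 1)
        - gammaln((2 * n - rare - hets) / 2 + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[np.searchsorted(hets, n_het)]
    # Relative epsilon guards against ties lost to floating-point rounding.
    p = prob[prob <= p_obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def marker_stats(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker call rate, minor-allele frequency, HWE p, monomorphic flag."""
    if genotypes.n_samples < 1:
        raise ValidationError("marker_stats requires at least one sample")
    g = genotypes.counts
    observed = ~np.isnan(g)
    n_obs = observed.sum(axis=0)
    call_rate = n_obs / genotypes.n_samples
    with np.errstate(invalid="ignore"):
        freq = np.nansum(g, axis=0) / (2 * n_obs)
    maf = np.minimum(freq, 1 - freq)
    rows = []
    for j, v in enumerate(genotypes.variants):
        col = g[observed[:, j], j]
        if col.size == 0:
            rows.append((v.variant_id, 0.0, np.nan, np.nan, True))
            continue
        n_hom_ref = int((col == 0).sum())
        n_het = int((col == 1).sum())
        n_hom_alt = int((col == 2).sum())
        mono = (freq[j] == 0.0) or (freq[j] == 1.0)
        hwe_p = hwe_exact_test(n_hom_ref, n_het, n_hom_alt)
        rows.append((v.variant_id, float(call_rate[j]), float(maf[j]), hwe_p, bool(mono)))
    return pd.DataFrame(
        rows, columns=["variant_id", "call_rate", "maf", "hwe_p", "monomorphic"]
    )


def sample_stats(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-sample call rate and heterozygosity (fraction of het calls)."""
    if genotypes.n_variants < 1:
        raise ValidationError("sample_stats requires at least one marker")
    g = genotypes.counts
    observed = ~np.isnan(g)
    n_obs = observed.sum(axis=1)
    call_rate = n_obs / genotypes.n_variants
    with np.errstate(invalid="ignore"):
        het = np.where(n_obs > 0, (g == 1).sum(axis=1) / n_obs, np.nan)
    return pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids,
            "call_rate": call_rate,
            "heterozygosity": het,
        }
    )


def pairwise_relatedness(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Estimated genome-sharing proportion (pi-hat) for every sample pair.

    Uses the robust within-pair kinship estimator built from identity-by-state
    genotype classes: phi = (N_het,het - 2 * N_opposite_homozygote) /
    (N_het_i + N_het_j), reported as pi-hat = 2 * phi.  Duplicates/twins give
    pi-hat ~ 1, first-degree relatives ~ 0.5, unrelated pairs ~ 0.
    """
    g = genotypes.counts
    het = (g == 1) & ~np.isnan(g)
    hom0 = (g == 0)
    hom2 = (g == 2)
    obs = ~np.isnan(g)
    h = het.astype(float)
    n_hh = h @ h.T
    n_opp = hom0.astype(float) @ hom2.astype(float).T
    n_opp = n_opp + n_opp.T
    # heterozygote totals restricted to markers observed in both samples
    het_i = h @ obs.astype(float).T
    denom = het_i + het_i.T
    with np.errstate(divide="ignore", invalid="ignore"):
        kinship = (n_hh - 2 * n_opp) / denom
    pihat = 2 * kinship
    iu = np.triu_indices(genotypes.n_samples, k=1)
    sid = np.asarray(genotypes.sample_ids)
    return pd.DataFrame(
        {
            "sample_1": sid[iu[0]],
            "sample_2": sid[iu[1]],
            "pihat": pihat[iu],
        }
    )


def _join_reason(existing: str, reason: str) -> str:
    return reason if not existing else existing + ";" + reason


def apply_qc(
    genotypes: GenotypeMatrix, thresholds: QCThresholds = QCThresholds()
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter samples then markers; marker statistics are recomputed on the
    surviving samples.  Returns the filtered matrix and a full report."""
    n0_samples, n0_markers = genotypes.n_samples, genotypes.n_variants

    samples = sample_stats(genotypes)
    samples["kept"] = True
    samples["reason"] = ""

    low_call = samples["call_rate"] < thresholds.sample_min_call_rate
    samples.loc[low_call, "kept"] = False
    samples.loc[low_call, "reason"] = samples.loc[low_call, "reason"].apply(
        _join_reason, reason="call_rate"
    )

    het = samples["heterozygosity"]
    het_mean, het_sd = het.mean(), het.std(ddof=1)
    if np.isfinite(het_sd) and het_sd > 0:
        outlier = (het - het_mean).abs() > thresholds.het_sd_limit * het_sd
        outlier = outlier.fillna(False)
        samples.loc[outlier, "kept"] = False
        samples.loc[outlier, "reason"] = samples.loc[outlier, "reason"].apply(
            _join_reason, reason="heterozygosity"
        )

    # Cryptic relatedness among samples still standing: drop the lower-call-rate
    # member of each flagged pair.
    standing = genotypes.subset(sample_mask=samples["kept"].to_numpy())
    if standing.n_samples >= 2 and standing.n_variants < thresholds.relatedness_min_markers:
        warnings.warn(
            f"relatedness screen skipped: {standing.n_variants} markers "
            f"< relatedness_min_markers={thresholds.relatedness_min_markers}"
        )
    elif standing.n_samples >= 2:
        rel = pairwise_relatedness(standing)
        flagged = rel[rel["pihat"] > thresholds.relatedness_max_pihat]
        call = samples.set_index("sample_id")["call_rate"]
        for _, pair in flagged.iterrows():
            s1, s2 = pair["sample_1"], pair["sample_2"]
            drop = s1 if call[s1] <= call[s2] else s2
            idx = samples.index[samples["sample_id"] == drop][0]
            if samples.at[idx, "kept"]:
                samples.at[idx, "kept"] = False
                samples.at[idx, "reason"] = _join_reason(
                    samples.at[idx, "reason"], "relatedness"
                )

    kept_samples = samples["kept"].to_numpy()
    filtered_samples = genotypes.subset(sample_mask=kept_samples)

    if filtered_samples.n_samples == 0:
        warnings.warn("QC removed every sample; returning an empty matrix")
        markers = pd.DataFrame(
            columns=["variant_id", "call_rate", "maf", "hwe_p", "monomorphic", "kept", "reason"]
        )
        report = QCReport(markers, samples, _summary(genotypes, genotypes.subset(
            sample_mask=np.zeros(n0_samples, bool)), n0_samples, n0_markers))
        return filtered_samples, report

    markers = marker_stats(filtered_samples)
    markers["kept"] = True
    markers["reason"] = ""
    if thresholds.drop_monomorphic:
        mono = markers["monomorphic"].fillna(True).astype(bool)
        markers.loc[mono, "kept"] = False
        markers.loc[mono, "reason"] = markers.loc[mono, "reason"].apply(
            _join_reason, reason="monomorphic"
        )
    high_missing = (1 - markers["call_rate"]) > thresholds.marker_max_missing
    markers.loc[high_missing, "kept"] = False
    markers.loc[high_missing, "reason"] = markers.loc[high_missing, "reason"].apply(
        _join_reason, reason="call_rate"
    )
    hwe_fail = markers["hwe_p"] < thresholds.hwe_alpha
    hwe_fail = hwe_fail.fillna(False)
    markers.loc[hwe_fail, "kept"] = False
    markers.loc[hwe_fail, "reason"] = markers.loc[hwe_fail, "reason"].apply(
        _join_reason, reason="hwe"
    )

    kept_markers = markers["kept"].to_numpy()
    result = filtered_samples.subset(variant_mask=kept_markers)
    if result.n_variants == 0:
        warnings.warn("QC removed every marker; returning an empty matrix")

    report = QCReport(markers, samples, _summary(genotypes, result, n0_samples, n0_markers))
    return result, report


def _summary(before, after, n0_samples, n0_markers) -> dict:
    return {
        "samples_before": n0_samples,
        "samples_after": after.n_samples,
        "markers_before": n0_markers,
        "markers_after": after.n_variants,
    }
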