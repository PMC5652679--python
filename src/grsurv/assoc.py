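"""Per-SNP case-control association against biochemical-recurrence status.

The default method is the allelic (2x2 allele table) odds ratio: with minor
allele frequencies p1 in cases and p0 in controls,

    OR = [p1 / (1 - p1)] / [p0 / (1 - p0)],

with the Woolf standard error of ln(OR) from the four allele counts, a 95%
Wald CI on the log scale, and a two-sided normal p-value.  A logistic
alternative (additive 0/1/2 coding, maximum likelihood via IRLS, optional
covariates) is also provided.  Selection of score SNPs uses a strict
p < alpha rule (default alpha = 1e-3).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .errors import ValidationError
from .io import GenotypeMatrix, align_samples

Z_95 = stats.norm.ppf(0.975)


@dataclass
class AssociationResult:
    """One marker's association summary (one output-table row)."""

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    gene: str
    maf_controls: float
    maf_cases: float
    n_controls: int
    n_cases: int
    or_estimate: float
    ci_low: float
    ci_high: float
    ln_or: float
    se_ln_or: float
    p_value: float
    method: str
    flipped: bool = False
    converged: bool = True
    flags: str = ""


def group_maf(genotypes: GenotypeMatrix, phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Effect-allele frequency per outcome group, oriented to the cohort minor allele.

    Variants whose effect allele is the combined-sample major allele are
    flipped in place (counts recoded 2-g, alleles swapped) and flagged in the
    ``flipped`` column.  A group with zero non-missing calls yields NaN and a
    ``no_calls`` flag rather than a silent zero.
    """
    pheno = align_samples(genotypes, phenotypes)
    case = pheno["bcr_event"].to_numpy() == 1
    if case.all() or not case.any():
        raise ValidationError("association requires at least one case and one control")
    rows = []
    for j, v in enumerate(genotypes.variants):
        col = genotypes.counts[:, j]
        obs = ~np.isnan(col)
        total_obs = obs.sum()
        freq_all = np.nansum(col) / (2 * total_obs) if total_obs else np.nan
        flipped = bool(freq_all > 0.5)
        if flipped:
            genotypes.flip_variant(j)
            col = genotypes.counts[:, j]
        v = genotypes.variants[j]
        flags = []
        out = {}
        for label, mask in (("controls", ~case), ("cases", case)):
            sel = obs & mask
            n = sel.sum()
            if n == 0:
                out[label] = np.nan
                flags.append(f"no_calls_{label}")
            else:
                out[label] = float(col[sel].sum() / (2 * n))
        rows.append(
            {
                "variant_id": v.variant_id,
                "effect_allele": v.effect_allele,
                "maf_controls": out["controls"],
                "maf_cases": out["cases"],
                "n_controls": int((obs & ~case).sum()),
                "n_cases": int((obs & case).sum()),
                "flipped": flipped,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)


def allelic_or(
    maf_controls: float, maf_cases: float, n_controls: int, n_cases: int
) -> dict:
    """Allelic odds ratio with Woolf CI and normal-approximation p-value.

    Allele counts are reconstructed as 2n x MAF rounded to the nearest
    integer, so printed (rounded) frequencies can be used directly.  If any
    reconstructed cell is zero, the Haldane-Anscombe correction (add 0.5 to
    every cell) is applied and flagged.
    """
    if n_controls < 1 or n_cases < 1:
        raise ValidationError("both groups need at least one subject")
    for p in (maf_controls, maf_cases):
        if not 0.0 <= p <= 1.0 or math.isnan(p):
            raise ValidationError(f"MAF {p!r} outside [0,1]")
    a = round(2 * n_cases * maf_cases)        # effect alleles, cases
    b = 2 * n_cases - a
    c = round(2 * n_controls * maf_controls)  # effect alleles, controls
    d = 2 * n_controls - c
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
        or_est = (a / b) / (c / d)
    else:
        # point estimate straight from the frequencies (no rounding loss)
        or_est = (maf_cases / (1 - maf_cases)) / (maf_controls / (1 - maf_controls))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ln_or = math.log(or_est)
    z = ln_or / se
    return {
        "or_estimate": or_est,
        "ln_or": ln_or,
        "se_ln_or": se,
        "ci_low": math.exp(ln_or - Z_95 * se),
        "ci_high": math.exp(ln_or + Z_95 * se),
        "p_value": float(2 * stats.norm.sf(abs(z))),
        "continuity_corrected": corrected,
    }


def logistic_fit(
    counts: np.ndarray,
    outcome: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> dict:
    """Additive-coding logistic regression of a binary outcome on allele counts.

    Fit by iteratively reweighted least squares; returns the genotype
    coefficient as ln(OR) with Wald CI and p.  Complete separation yields a
    flagged non-converged result instead of a spurious estimate.
    """
    counts = np.asarray(counts, float)
    outcome = np.asarray(outcome, float)
    if np.unique(outcome[~np.isnan(outcome)]).size < 2:
        raise ValidationError("outcome must take two distinct values")
    obs = ~np.isnan(counts)
    x = counts[obs]
    y = outcome[obs]
    if np.unique(x).size < 2:
        raise ValidationError("genotype predictor is constant")
    X = pd.DataFrame({"const": 1.0, "count": x})
    if covariates is not None:
        cov = pd.DataFrame(covariates).loc[obs].reset_index(drop=True)
        X = pd.concat([X.reset_index(drop=True), cov], axis=1)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(method="newton", maxiter=max_iter, tol=tol, disp=0)
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        return {
            "ln_or": np.nan, "se_ln_or": np.nan, "or_estimate": np.nan,
            "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan,
            "converged": False,
        }
    beta = float(fit.params["count"])
    se = float(fit.bse["count"])
    return {
        "ln_or": beta,
        "se_ln_or": se,
        "or_estimate": math.exp(beta),
        "ci_low": math.exp(beta - Z_95 * se),
        "ci_high": math.exp(beta + Z_95 * se),
        "p_value": float(fit.pvalues["count"]),
        "converged": bool(fit.mle_retvals["converged"]),
    }


def run_association(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    method: str = "allelic",
    covariates: list[str] | None = None,
) -> list[AssociationResult]:
    """Associate every marker with BCR status; returns results sorted by p.

    Per-marker failures (monomorphic markers, separation) are flagged on the
    result rather than aborting the scan.
    """
    if method not in ("allelic", "logistic_additive", "logistic"):
        raise ValidationError(f"unknown method {method!r}")
    method = "logistic_additive" if method.startswith("logistic") else "allelic"
    mafs = group_maf(genotypes, phenotypes)  # flips variants in place
    pheno = align_samples(genotypes, phenotypes)
    outcome = pheno["bcr_event"].to_numpy(float)
    cov = pheno[covariates] if covariates else None
    results = []
    for j, v in enumerate(genotypes.variants):
        row = mafs.iloc[j]
        base = dict(
            variant_id=v.variant_id,
            chromosome=v.chromosome,
            position=v.position,
            effect_allele=v.effect_allele,
            other_allele=v.other_allele,
            gene=v.gene,
            maf_controls=row["maf_controls"],
            maf_cases=row["maf_cases"],
            n_controls=int(row["n_controls"]),
            n_cases=int(row["n_cases"]),
            method=method,
            flipped=bool(row["flipped"]),
        )
        flags = [f for f in str(row["flags"]).split(";") if f]
        col = genotypes.counts[:, j]
        observed = col[~np.isnan(col)]
        est = None
        if observed.size == 0 or np.unique(observed).size < 2:
            flags.append("monomorphic")
        elif method == "allelic":
            try:
                est = allelic_or(
                    row["maf_controls"], row["maf_cases"],
                    int(row["n_controls"]), int(row["n_cases"]),
                )
                if est.pop("continuity_corrected"):
                    flags.append("continuity_corrected")
            except ValidationError as exc:
                flags.append(f"error:{exc}")
        else:
            try:
                est = logistic_fit(col, outcome, covariates=cov)
                if not est.pop("converged"):
                    flags.append("not_converged")
                    est = None
            except ValidationError as exc:
                flags.append(f"error:{exc}")
        if est is None:
            est = dict(or_estimate=np.nan, ci_low=np.nan, ci_high=np.nan,
                       ln_or=np.nan, se_ln_or=np.nan, p_value=np.nan)
            converged = False
        else:
            converged = True
        results.append(
            AssociationResult(**base, **est, converged=converged, flags=";".join(flags))
        )
    results.sort(key=lambda r: (not math.isfinite(r.p_value) if r.p_value is not None
                                else True, r.p_value if math.isfinite(r.p_value) else 1.0,
                                r.variant_id))
    return results


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Tabular view of association results with informational multiple-testing
    columns (Bonferroni and Benjamini-Hochberg); selection itself uses raw p."""
    columns = [f.name for f in __import__("dataclasses").fields(AssociationResult)]
    df = pd.DataFrame([r.__dict__ for r in results], columns=columns)
    ok = df["p_value"].notna()
    df["p_bonferroni"] = np.nan
    df["p_bh"] = np.nan
    if ok.any():
        p = df.loc[ok, "p_value"].to_numpy()
        df.loc[ok, "p_bonferroni"] = np.minimum(p * ok.sum(), 1.0)
        df.loc[ok, "p_bh"] = multipletests(p, method="fdr_bh")[1]
    return df


def manhattan_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Plain per-SNP (chromosome, position, p) table for plotting elsewhere."""
    return pd.DataFrame(
        [(r.chromosome, r.position, r.p_value) for r in results],
        columns=["chromosome", "position", "p_value"],
    )


def select_snps(
    results: list[AssociationResult], alpha: float = 1e-3
) -> list[AssociationResult]:
    """Markers with p strictly below alpha, ordered by ascending p then id."""
    if not results:
        raise ValidationError("no association results to select from")
    selected = [
        r for r in results
        if r.p_value is not None and math.isfinite(r.p_value) and r.p_value < alpha
    ]
    selected.sort(key=lambda r: (r.p_value, r.variant_id))
    if not selected:
        warnings.warn(f"no markers pass p < {alpha}")
    return selected
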