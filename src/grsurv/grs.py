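"""Weighted genetic risk score construction and per-sample scoring.

GRS = sum over selected SNPs of (effect-allele count in {0,1,2}) x ln(OR).
The effect allele is the cohort minor allele, so protective SNPs (OR < 1)
contribute negative terms and typical scores are negative.  Samples are
dichotomized at a fixed cutoff (default -2.0; ties go to the high-risk
group), with a cohort-median cutoff available as an alternative.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import AssociationResult
from .errors import EmptyModelError, OrientationError, ValidationError
from .io import GenotypeMatrix

DEFAULT_CUTOFF = -2.0


@dataclass(frozen=True)
class ModelEntry:
    variant_id: str
    effect_allele: str
    weight: float  # ln(OR)


@dataclass
class GRSModel:
    entries: list[ModelEntry]
    alpha_used: float | None = None
    provenance: list[AssociationResult] | None = field(default=None, repr=False)

    def __post_init__(self):
        ids = [e.variant_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate variant in score model")
        for e in self.entries:
            if not math.isfinite(e.weight) or e.weight == 0.0:
                raise ValidationError(
                    f"{e.variant_id}: weight must be finite and nonzero, got {e.weight}"
                )

    @property
    def variant_ids(self) -> list[str]:
        return [e.variant_id for e in self.entries]

    def score_bounds(self) -> tuple[float, float]:
        """Attainable score range: [2*sum(min(0,w)), 2*sum(max(0,w))]."""
        lo = 2 * sum(min(0.0, e.weight) for e in self.entries)
        hi = 2 * sum(max(0.0, e.weight) for e in self.entries)
        return lo, hi


def build_model(
    selected: list[AssociationResult], alpha_used: float | None = None
) -> GRSModel:
    """One entry per selected SNP with weight ln(OR); rejects OR <= 0 or = 1."""
    if not selected:
        raise EmptyModelError("cannot build a score model from zero SNPs")
    entries = []
    for r in selected:
        if not (r.or_estimate and math.isfinite(r.or_estimate)) or r.or_estimate <= 0:
            raise ValidationError(f"{r.variant_id}: OR must be positive, got {r.or_estimate}")
        if r.or_estimate == 1.0:
            raise ValidationError(f"{r.variant_id}: OR of exactly 1 carries no weight")
        entries.append(ModelEntry(r.variant_id, r.effect_allele, math.log(r.or_estimate)))
    return GRSModel(entries, alpha_used=alpha_used, provenance=list(selected))


def score_samples(
    genotypes: GenotypeMatrix,
    model: GRSModel,
    cutoff: float = DEFAULT_CUTOFF,
    missing_policy: str = "impute",
) -> pd.DataFrame:
    """Score every sample; returns columns sample_id, grs, group, n_imputed.

    Missing genotypes at a model SNP are imputed as twice the sample-set
    effect-allele frequency (``missing_policy='impute'``, default) or the
    term is omitted (``'omit'``); the per-sample count of affected entries is
    reported either way.
    """
    if not model.entries:
        raise EmptyModelError("score model has no entries")
    if missing_policy not in ("impute", "omit"):
        raise ValidationError(f"unknown missing_policy {missing_policy!r}")
    absent = [e.variant_id for e in model.entries if e.variant_id not in genotypes.variant_ids]
    if absent:
        raise ValidationError(f"model variants absent from genotypes: {absent}")

    dosage = np.zeros((genotypes.n_samples, len(model.entries)))
    weights = np.array([e.weight for e in model.entries])
    n_imputed = np.zeros(genotypes.n_samples, dtype=int)
    for k, entry in enumerate(model.entries):
        j = genotypes.variant_index(entry.variant_id)
        v = genotypes.variants[j]
        col = genotypes.counts[:, j].copy()
        if entry.effect_allele == v.effect_allele:
            pass
        elif entry.effect_allele == v.other_allele:
            col = 2.0 - col
        else:
            raise OrientationError(
                f"{entry.variant_id}: model effect allele {entry.effect_allele} "
                f"not among alleles {v.effect_allele}/{v.other_allele}"
            )
        miss = np.isnan(col)
        n_imputed += miss
        if miss.any():
            if miss.all():
                fill = 0.0
            else:
                fill = float(col[~miss].mean())  # = 2 x effect-allele frequency
            col[miss] = fill if missing_policy == "impute" else 0.0
        dosage[:, k] = col
    grs = dosage @ weights
    scores = pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids,
            "grs": grs,
            "n_imputed": n_imputed,
        }
    )
    scores["group"] = dichotomize(scores, cutoff)
    return scores


def dichotomize(scores: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF) -> pd.Series:
    """'high' iff grs >= cutoff else 'low' (ties at the cutoff are high-risk)."""
    if len(scores) == 0:
        raise ValidationError("no scores to dichotomize")
    return pd.Series(
        np.where(scores["grs"].to_numpy() >= cutoff, "high", "low"),
        index=scores.index,
        name="group",
    )


def median_cutoff(scores: pd.DataFrame) -> float:
    """Cohort-median cutoff alternative to the fixed default."""
    return float(scores["grs"].median())


def write_model(model: GRSModel, path: str | os.PathLike) -> None:
    pd.DataFrame(
        [(e.variant_id, e.effect_allele, e.weight) for e in model.entries],
        columns=["variant_id", "effect_allele", "weight"],
    ).to_csv(path, sep="\t", index=False)


def read_model(path: str | os.PathLike) -> GRSModel:
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "effect_allele": str})
    entries = [
        ModelEntry(r.variant_id, r.effect_allele, float(r.weight))
        for r in df.itertuples()
    ]
    return GRSModel(entries)


def write_scores(scores: pd.DataFrame, path: str | os.PathLike) -> None:
    scores[["sample_id", "grs", "group", "n_imputed"]].to_csv(path, sep="\t", index=False)


def read_scores(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
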