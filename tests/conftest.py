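import numpy as np
import pandas as pd
import pytest

from grsurv.io import GenotypeMatrix, VariantRecord
from grsurv.simulate import SimulationConfig, simulate_cohort


def make_variant(vid="rs1", chrom="1", pos=100, ea="A", oa="G", gene=""):
    return VariantRecord(vid, chrom, pos, ea, oa, gene)


def make_matrix(counts, sample_ids=None, variants=None):
    counts = np.asarray(counts, dtype=float)
    n, m = counts.shape
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    if variants is None:
        variants = [make_variant(f"rs{j}", pos=100 + j) for j in range(m)]
    return GenotypeMatrix(sample_ids, variants, counts)


def make_phenotypes(sample_ids, events, times=None, **overrides):
    n = len(sample_ids)
    df = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "bcr_event": events,
            "followup_months": times if times is not None else [51.0] * n,
            "age_years": [66.0] * n,
            "psa_ng_ml": [8.3] * n,
            "prostate_volume_ml": [37.0] * n,
            "gleason": [7] * n,
            "ece": [0] * n,
            "svi": [0] * n,
            "bni": [0] * n,
            "psm": [0] * n,
            "pt_stage": ["pT2"] * n,
        }
    )
    for k, v in overrides.items():
        df[k] = v
    return df


@pytest.fixture(scope="session")
def cohort():
    """Default-size simulated cohort (912 subjects, 16 signal + 84 null SNPs)."""
    return simulate_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def scored_cohort(cohort):
    """The same cohort scored with the published-panel weight model."""
    from grsurv.grs import GRSModel, ModelEntry, score_samples
    from grsurv.panel import panel_variants, panel_weights

    genotypes, phenotypes = cohort
    weights = panel_weights()
    model = GRSModel(
        [ModelEntry(v.variant_id, v.effect_allele, weights[v.variant_id])
         for v in panel_variants()]
    )
    scores = score_samples(genotypes, model)
    return genotypes, phenotypes, scores
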