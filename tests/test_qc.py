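import math
from fractions import Fraction
from math import factorial

import numpy as np
import pytest

from grsurv.errors import ValidationError
from grsurv.io import GenotypeMatrix
from grsurv.qc import (
    QCThresholds,
    apply_qc,
    hwe_exact_test,
    marker_stats,
    pairwise_relatedness,
    sample_stats,
)
from grsurv.simulate import SimulationConfig, simulate_genotypes

from conftest import make_matrix


def hwe_enumeration_oracle(n_hom_ref, n_het, n_hom_alt):
    """Exact-rational enumeration of the conditional heterozygote distribution."""
    n = n_hom_ref + n_het + n_hom_alt
    rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if rare == 0:
        return 1.0
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        n_rr = (rare - h) // 2
        n_cc = (2 * n - rare - h) // 2
        probs[h] = Fraction(
            factorial(n) * 2**h, factorial(n_cc) * factorial(h) * factorial(n_rr)
        )
    total = sum(probs.values())
    p_obs = probs[n_het]
    return float(sum(v for v in probs.values() if v <= p_obs) / total)


class TestHweExactTest:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(100, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 7) == 1.0

    def test_small_table_matches_enumeration(self):
        assert hwe_exact_test(1, 2, 1) == pytest.approx(
            hwe_enumeration_oracle(1, 2, 1), rel=1e-12
        )

    def test_large_table_matches_enumeration(self):
        got = hwe_exact_test(1469, 138, 5)
        assert got == pytest.approx(hwe_enumeration_oracle(1469, 138, 5), rel=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            hwe_exact_test(0, 0, 0)
        with pytest.raises(ValidationError):
            hwe_exact_test(-1, 2, 0)

    def test_exhaustive_sweep_small_totals(self):
        # every genotype table with total <= 25 (the acceptance suite sweeps
        # totals <= 50); p-values must match exact-rational enumeration
        for total in range(1, 26):
            for a in range(total + 1):
                for b in range(total - a + 1):
                    c = total - a - b
                    assert hwe_exact_test(a, b, c) == pytest.approx(
                        hwe_enumeration_oracle(a, b, c), rel=1e-9
                    ), (a, b, c)

    def test_extreme_het_deficit_is_significant(self):
        # strong heterozygote deficit, the classic genotyping-failure signature
        assert hwe_exact_test(50, 0, 50) < 1e-6


class TestMarkerSampleStats:
    def test_marker_call_rate_and_maf(self):
        gm = make_matrix(
            np.array([[0, 0, 0], [0, 1, 1], [1, 1, 1], [np.nan, 2, 1]])
        )
        stats = marker_stats(gm)
        assert stats.loc[0, "call_rate"] == pytest.approx(0.75)
        assert stats.loc[1, "maf"] == pytest.approx(0.5)  # counts [0,1,1,2]
        assert not stats.loc[1, "monomorphic"]

    def test_all_reference_marker_is_monomorphic(self):
        stats = marker_stats(make_matrix([[0], [0], [0]]))
        assert bool(stats.loc[0, "monomorphic"])
        assert stats.loc[0, "maf"] == 0.0

    def test_sample_heterozygosity(self):
        gm = make_matrix([[1, 1, 1], [0, 2, np.nan], [np.nan, np.nan, np.nan]])
        stats = sample_stats(gm)
        assert stats.loc[0, "heterozygosity"] == 1.0
        assert stats.loc[1, "call_rate"] == pytest.approx(2 / 3)
        assert stats.loc[1, "heterozygosity"] == 0.0
        assert stats.loc[2, "call_rate"] == 0.0
        assert np.isnan(stats.loc[2, "heterozygosity"])


def _qc_fixture(seed=0, n=400):
    return simulate_genotypes(SimulationConfig(n_samples=n, seed=seed, missing_rate=0.0))


class TestApplyQc:
    def test_high_missing_marker_removed_with_reason(self):
        rng = np.random.default_rng(0)
        counts = rng.binomial(2, 0.3, size=(200, 40)).astype(float)
        counts[:12, 3] = np.nan  # 6% missing at marker 3; samples keep 39/40 calls
        gm = make_matrix(counts)
        out, report = apply_qc(gm, QCThresholds())
        row = report.markers.set_index("variant_id").loc["rs3"]
        assert not row["kept"]
        assert "call_rate" in row["reason"]
        assert "rs3" not in out.variant_ids

    def test_hwe_violating_marker_removed_with_reason(self):
        rng = np.random.default_rng(1)
        counts = rng.binomial(2, 0.3, size=(300, 5)).astype(float)
        # all-heterozygote marker: gross HWE violation
        counts[:, 2] = 1.0
        gm = make_matrix(counts)
        assert hwe_exact_test(0, 300, 0) < 1e-6
        out, report = apply_qc(gm, QCThresholds())
        row = report.markers.set_index("variant_id").loc["rs2"]
        assert not row["kept"]
        assert "hwe" in row["reason"]

    def test_monomorphic_marker_removed(self):
        gm = make_matrix(np.column_stack([np.zeros(50), np.tile([0, 1, 2, 1, 0], 10)]))
        out, report = apply_qc(gm, QCThresholds())
        assert report.markers.loc[0, "reason"] == "monomorphic"
        assert out.n_variants == 1

    def test_permissive_thresholds_are_a_no_op(self):
        gm = _qc_fixture(seed=2)
        loose = QCThresholds(
            marker_max_missing=0.99, sample_min_call_rate=1e-9,
            hwe_alpha=1e-300, het_sd_limit=1e6, drop_monomorphic=False,
        )
        out, report = apply_qc(gm, loose)
        assert out.equals(gm)

    def test_idempotent_on_realistic_cohort(self):
        gm = _qc_fixture(seed=3)
        once, _ = apply_qc(gm, QCThresholds())
        twice, _ = apply_qc(once, QCThresholds())
        assert twice.equals(once)

    def test_marker_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        counts = rng.binomial(2, 0.2, size=(150, 20)).astype(float)
        miss = rng.random(counts.shape) < 0.04
        counts[miss] = np.nan
        gm = make_matrix(counts)
        strict, _ = apply_qc(gm, QCThresholds(marker_max_missing=0.02))
        loose, _ = apply_qc(gm, QCThresholds(marker_max_missing=0.10))
        assert set(strict.variant_ids) <= set(loose.variant_ids)

    def test_low_call_rate_sample_removed(self):
        rng = np.random.default_rng(5)
        counts = rng.binomial(2, 0.3, size=(50, 40)).astype(float)
        counts[0, :4] = np.nan  # sample s0 call rate 0.9
        gm = make_matrix(counts)
        out, report = apply_qc(gm, QCThresholds(sample_min_call_rate=0.95))
        row = report.samples.set_index("sample_id").loc["s0"]
        assert not row["kept"] and row["reason"] == "call_rate"
        assert "s0" not in out.sample_ids

    def test_empty_result_warns_not_silent(self):
        gm = make_matrix(np.zeros((5, 3)))  # all monomorphic
        with pytest.warns(UserWarning, match="every marker"):
            out, _ = apply_qc(gm, QCThresholds())
        assert out.n_variants == 0


class TestRelatedness:
    def test_duplicate_sample_flagged_and_dropped(self):
        rng = np.random.default_rng(6)
        counts = rng.binomial(2, 0.3, size=(30, 600)).astype(float)
        counts[1] = counts[0]  # s1 duplicates s0
        counts[0, :30] = np.nan  # s0 has the lower call rate
        gm = make_matrix(counts)
        rel = pairwise_relatedness(gm)
        pair = rel[(rel.sample_1 == "s0") & (rel.sample_2 == "s1")]
        assert pair["pihat"].iloc[0] > 0.9
        out, report = apply_qc(gm, QCThresholds())
        assert "s0" not in out.sample_ids and "s1" in out.sample_ids
        assert "relatedness" in report.samples.set_index("sample_id").loc["s0", "reason"]

    def test_screen_skipped_with_few_markers(self):
        rng = np.random.default_rng(7)
        gm = make_matrix(rng.binomial(2, 0.3, size=(30, 50)).astype(float))
        with pytest.warns(UserWarning, match="relatedness screen skipped"):
            out, _ = apply_qc(gm, QCThresholds())
        assert out.n_samples == 30
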