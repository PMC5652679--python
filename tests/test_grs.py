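import math

import numpy as np
import pytest

from grsurv.errors import EmptyModelError, OrientationError, ValidationError
from grsurv.grs import (
    GRSModel,
    ModelEntry,
    build_model,
    dichotomize,
    median_cutoff,
    read_model,
    score_samples,
    write_model,
)
from grsurv.panel import panel_variants, panel_weights

from conftest import make_matrix, make_variant
from test_assoc import _stub_result


def panel_model():
    weights = panel_weights()
    return GRSModel(
        [ModelEntry(v.variant_id, v.effect_allele, weights[v.variant_id])
         for v in panel_variants()]
    )


class TestBuildModel:
    def test_weights_are_log_odds_ratios(self):
        r = _stub_result("rs4965121", 1e-4)
        r.or_estimate = 2.106
        model = build_model([r])
        assert model.entries[0].weight == pytest.approx(0.7447, abs=1e-4)

    def test_symmetric_ors_give_symmetric_weights(self):
        r1 = _stub_result("a", 0.1)
        r1.or_estimate = 2.0
        r2 = _stub_result("b", 0.1)
        r2.or_estimate = 0.5
        model = build_model([r1, r2])
        w = [e.weight for e in model.entries]
        assert w[0] == pytest.approx(math.log(2)) and w[1] == pytest.approx(-math.log(2))

    def test_unit_or_rejected(self):
        r = _stub_result("a", 0.1)
        r.or_estimate = 1.0
        with pytest.raises(ValidationError):
            build_model([r])

    def test_nonpositive_or_rejected(self):
        r = _stub_result("a", 0.1)
        r.or_estimate = -2.0
        with pytest.raises(ValidationError):
            build_model([r])

    def test_empty_selection_rejected(self):
        with pytest.raises(EmptyModelError):
            build_model([])


class TestScoreSamples:
    def test_zero_counts_score_zero(self):
        model = GRSModel([ModelEntry("rs0", "A", 0.5), ModelEntry("rs1", "A", -0.3)])
        gm = make_matrix(np.zeros((3, 2)))
        scores = score_samples(gm, model)
        assert (scores["grs"] == 0).all()

    def test_hand_computed_two_snp_score(self):
        # one risk copy at OR 2.106, two protective copies at OR 0.5278
        model = GRSModel(
            [
                ModelEntry("rs4965121", "C", math.log(2.106)),
                ModelEntry("rs1128966", "G", math.log(0.5278)),
            ]
        )
        gm = make_matrix(
            [[1, 2]],
            variants=[
                make_variant("rs4965121", ea="C", oa="G"),
                make_variant("rs1128966", ea="G", oa="C", pos=200),
            ],
        )
        scores = score_samples(gm, model)
        expected = math.log(2.106) + 2 * math.log(0.5278)
        assert scores.loc[0, "grs"] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(-0.534, abs=0.005)

    def test_published_panel_bounds(self):
        model = panel_model()
        lo, hi = model.score_bounds()
        # frozen from direct arithmetic: 2*sum of the 12 negative ln(OR)
        # weights and 2*sum of the 4 positive ones
        assert lo == pytest.approx(-12.279, abs=0.02)
        assert hi == pytest.approx(4.049, abs=0.02)
        # the published observed range sits inside the attainable bounds
        assert lo < -7.19 and hi > 1.61

    def test_protective_homozygote_hits_lower_bound(self):
        model = panel_model()
        counts = np.array(
            [[2.0 if e.weight < 0 else 0.0 for e in model.entries]]
        )
        gm = make_matrix(
            counts, variants=[v for v in panel_variants()], sample_ids=["s0"]
        )
        scores = score_samples(gm, model)
        assert scores.loc[0, "grs"] == pytest.approx(model.score_bounds()[0])

    def test_missing_genotype_imputed_as_twice_frequency(self):
        model = GRSModel([ModelEntry("rs0", "A", 1.0)])
        gm = make_matrix([[0], [1], [2], [np.nan]])
        scores = score_samples(gm, model)
        assert scores.loc[3, "grs"] == pytest.approx(1.0)  # 2 x freq 0.5
        assert scores.loc[3, "n_imputed"] == 1
        omitted = score_samples(gm, model, missing_policy="omit")
        assert omitted.loc[3, "grs"] == 0.0

    def test_opposite_orientation_recoded(self):
        model = GRSModel([ModelEntry("rs0", "G", 1.0)])  # G is other_allele
        gm = make_matrix([[0], [2]])
        scores = score_samples(gm, model)
        assert list(scores["grs"]) == [2.0, 0.0]

    def test_allele_mismatch_is_orientation_error(self):
        model = GRSModel([ModelEntry("rs0", "T", 1.0)])
        gm = make_matrix([[0]])
        with pytest.raises(OrientationError):
            score_samples(gm, model)

    def test_absent_model_variant_listed(self):
        model = GRSModel([ModelEntry("rs_missing", "A", 1.0)])
        gm = make_matrix([[0]])
        with pytest.raises(ValidationError, match="rs_missing"):
            score_samples(gm, model)

    def test_tiny_extra_snp_barely_moves_scores(self):
        model = panel_model()
        extra = GRSModel(model.entries + [ModelEntry("null0001", "G", 1e-4)])
        rng = np.random.default_rng(0)
        variants = panel_variants() + [make_variant("null0001", ea="G", oa="A", pos=99)]
        counts = rng.integers(0, 3, size=(20, 17)).astype(float)
        gm = make_matrix(counts, variants=variants)
        s1 = score_samples(gm, model)["grs"]
        s2 = score_samples(gm, extra)["grs"]
        assert np.max(np.abs(s2 - s1)) <= 2e-4 + 1e-12


class TestDichotomize:
    def test_tie_at_cutoff_is_high(self):
        scores = score_samples(
            make_matrix([[2], [0]]), GRSModel([ModelEntry("rs0", "A", -1.0)]),
            cutoff=-2.0,
        )
        assert scores.loc[0, "grs"] == -2.0
        assert scores.loc[0, "group"] == "high"

    def test_cutoff_below_minimum_makes_all_high(self):
        model = GRSModel([ModelEntry("rs0", "A", 0.5)])
        gm = make_matrix([[0], [1], [2]])
        scores = score_samples(gm, model, cutoff=-99.0)
        assert (scores["group"] == "high").all()

    def test_median_cutoff_balances_groups(self):
        model = GRSModel([ModelEntry("rs0", "A", 1.0)])
        rng = np.random.default_rng(1)
        gm = make_matrix(rng.integers(0, 3, size=(101, 1)).astype(float))
        scores = score_samples(gm, model)
        cut = median_cutoff(scores)
        groups = dichotomize(scores, cut)
        assert (groups == "high").sum() >= 50


class TestModelIo:
    def test_model_tsv_round_trip(self, tmp_path):
        model = panel_model()
        path = tmp_path / "model.tsv"
        write_model(model, path)
        back = read_model(path)
        assert [(e.variant_id, e.effect_allele) for e in back.entries] == [
            (e.variant_id, e.effect_allele) for e in model.entries
        ]
        np.testing.assert_allclose(
            [e.weight for e in back.entries], [e.weight for e in model.entries]
        )


class TestCohortDirection:
    def test_mean_score_higher_in_recurrence_group(self, scored_cohort):
        _, phenotypes, scores = scored_cohort
        merged = scores.merge(phenotypes[["sample_id", "bcr_event"]], on="sample_id")
        means = merged.groupby("bcr_event")["grs"].mean()
        assert means[1] > means[0]
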