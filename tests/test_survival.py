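import math

import numpy as np
import pandas as pd
import pytest

from grsurv.errors import CollinearityError, ValidationError
from grsurv.survival import (
    cox_fit,
    cox_score_test,
    fit_bcr_models,
    km_estimate,
    logrank_test,
)


def km_product_oracle(times, events):
    """Brute-force product over event times on the raw data."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out = {}
    s = 1.0
    for t in sorted(set(times[events == 1])):
        n_at_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1 - d / n_at_risk
        out[t] = s
    return out


def simulate_ph(n, beta, seed, binary=False, round_times=False):
    """Minimal proportional-hazards draw used as a recovery fixture."""
    rng = np.random.default_rng(seed)
    x = rng.binomial(1, 0.5, n).astype(float) if binary else rng.normal(size=n)
    T = rng.exponential(30 * np.exp(-beta * x))
    C = rng.uniform(1, 90, n)
    times = np.minimum(T, C)
    if round_times:
        times = np.round(times, 0) + 0.5
    return x, times, (T <= C).astype(int)


class TestKaplanMeier:
    def test_single_censored_subject_stays_at_one(self):
        curve = km_estimate([12.0], [0])
        assert curve.survival_at(100.0) == 1.0

    def test_three_events_closed_form(self):
        curve = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])

    def test_matches_product_oracle_on_random_cohort(self):
        rng = np.random.default_rng(0)
        times = np.round(rng.exponential(30, 200), 0) + 1
        events = rng.binomial(1, 0.6, 200)
        curve = km_estimate(times, events)
        oracle = km_product_oracle(times, events)
        for t, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx(oracle[t], rel=1e-12)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(10, 100) + 0.1
        curve = km_estimate(times, np.ones(100, int))
        for t in [2.0, 5.0, 20.0]:
            assert curve.survival_at(t) == pytest.approx((times > t).mean())

    def test_step_function_is_right_continuous(self):
        curve = km_estimate([2.0, 4.0, 6.0], [1, 1, 0])
        assert curve.survival_at(1.9) == 1.0
        assert curve.survival_at(2.0) == pytest.approx(2 / 3)
        assert curve.survival_at(3.9) == pytest.approx(2 / 3)

    def test_empty_and_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([], [])
        with pytest.raises(ValidationError):
            km_estimate([0.0, 1.0], [1, 1])


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        times = [3.0, 5.0, 8.0, 12.0]
        events = [1, 0, 1, 1]
        chi2, p = logrank_test(times + times, events + events, [0] * 4 + [1] * 4)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_subject_risk_set_oracle(self):
        # hand enumeration: O-E and hypergeometric variance over risk sets
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 1, 1, 0, 1])
        groups = np.array([0, 1, 0, 1, 0, 1])
        o_minus_e, var = 0.0, 0.0
        for t in times[events == 1]:
            at_risk = times >= t
            n = at_risk.sum()
            n1 = (at_risk & (groups == 1)).sum()
            d = 1
            o = 1 if groups[times == t][0] == 1 else 0
            o_minus_e += o - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        expected = o_minus_e**2 / var
        chi2, _ = logrank_test(times, events, groups)
        assert chi2 == pytest.approx(expected, rel=1e-9)

    def test_double_hazard_detected_across_seeds(self):
        pvals = []
        for seed in range(5):
            x, times, events = simulate_ph(1000, math.log(2.0), seed, binary=True)
            _, p = logrank_test(times, events, x)
            pvals.append(p)
        assert all(p < 1e-3 for p in pvals)

    def test_group_validation(self):
        with pytest.raises(ValidationError):
            logrank_test([1.0, 2.0], [1, 1], [0, 0])


class TestCoxFit:
    def test_eight_subject_grid_search_oracle(self):
        times = np.array([2.0, 4.0, 5.0, 7.0, 9.0, 12.0, 14.0, 20.0])
        events = np.array([1, 1, 0, 1, 1, 0, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 0.0])

        def neg_pl(beta):  # hand-written partial likelihood, no ties
            ll = 0.0
            for t in times[events == 1]:
                risk = times >= t
                ll += beta * x[times == t][0] - math.log(np.exp(beta * x[risk]).sum())
            return -ll

        grid = np.arange(-3.0, 3.0, 1e-4)
        beta_star = grid[np.argmin([neg_pl(b) for b in grid])]
        model = cox_fit(pd.DataFrame({"x": x}), times, events)
        assert model.coef[0] == pytest.approx(beta_star, abs=1e-4)

    def test_breslow_equals_efron_without_ties(self):
        x, times, events = simulate_ph(300, 0.5, seed=2)
        m1 = cox_fit(pd.DataFrame({"x": x}), times, events, ties_method="efron")
        m2 = cox_fit(pd.DataFrame({"x": x}), times, events, ties_method="breslow")
        np.testing.assert_allclose(m1.coef, m2.coef, atol=1e-12)

    def test_agrees_with_lifelines_under_heavy_ties(self):
        from lifelines import CoxPHFitter

        x, times, events = simulate_ph(400, 0.6, seed=3, round_times=True)
        df = pd.DataFrame({"x": x, "T": times, "E": events})
        model = cox_fit(df[["x"]], times, events, ties_method="efron")
        cph = CoxPHFitter().fit(df, "T", "E")
        assert model.coef[0] == pytest.approx(cph.params_["x"], abs=1e-4)
        assert model.se[0] == pytest.approx(cph.standard_errors_["x"], abs=1e-4)

    def test_null_covariate_ci_covers_one(self):
        x, times, events = simulate_ph(2000, 0.0, seed=4)
        m = cox_fit(pd.DataFrame({"x": x}), times, events)
        assert m.ci_low[0] < 1.0 < m.ci_high[0]
        assert abs(m.coef[0]) < 3 * m.se[0]

    def test_recovers_published_scale_hazard_ratio(self):
        beta = math.log(1.630)
        x, times, events = simulate_ph(2000, beta, seed=5)
        m = cox_fit(pd.DataFrame({"x": x}), times, events)
        assert abs(m.coef[0] - beta) < 3 * m.se[0]

    def test_score_test_equals_logrank_for_binary_covariate(self):
        x, times, events = simulate_ph(500, 0.4, seed=6, binary=True)
        chi_s, _ = cox_score_test(pd.DataFrame({"x": x}), times, events)
        chi_l, _ = logrank_test(times, events, x)
        assert chi_s == pytest.approx(chi_l, abs=1e-6)

    def test_collinear_pair_named(self):
        x, times, events = simulate_ph(100, 0.3, seed=7)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(CollinearityError, match="'a' and 'b'"):
            cox_fit(X, times, events)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            cox_fit(pd.DataFrame({"x": [1.0, 1.0, 1.0]}), [1, 2, 3], [1, 1, 0])

    def test_monotone_likelihood_flagged_not_silent(self):
        # perfectly separating covariate: all early events have x=1
        times = np.array([1.0, 2.0, 3.0, 4.0, 10.0, 11.0, 12.0, 13.0])
        events = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        x = np.array([1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0])
        m = cox_fit(pd.DataFrame({"x": x}), times, events)
        assert not m.converged


class TestNestedModels:
    def test_grs_effect_detected_in_simulated_cohort(self, scored_cohort):
        _, phenotypes, scores = scored_cohort
        clinical, genetic = fit_bcr_models(phenotypes, scores)
        assert clinical.converged and genetic.converged
        row = genetic.summary().set_index("covariate").loc["grs"]
        assert row["ci_low"] > 1.0  # strong positive GRS hazard

    def test_models_share_samples_and_covariates(self, scored_cohort):
        _, phenotypes, scores = scored_cohort
        clinical, genetic = fit_bcr_models(phenotypes, scores)
        assert clinical.n == genetic.n
        assert genetic.covariates == clinical.covariates + ["grs"]

    def test_null_grs_ci_covers_one(self):
        from grsurv.grs import GRSModel, ModelEntry, score_samples
        from grsurv.simulate import SimulationConfig, simulate_cohort, null_variant_specs

        specs = null_variant_specs(5, seed=8)
        cfg = SimulationConfig(
            n_samples=1500, variant_specs=specs, seed=8, missing_rate=0.0,
            hazard_scale=0.0,
        )
        g, p = simulate_cohort(cfg)
        model = GRSModel(
            [ModelEntry(s.variant.variant_id, s.variant.effect_allele, 0.3)
             for s in specs]
        )
        scores = score_samples(g, model)
        _, genetic = fit_bcr_models(p, scores)
        row = genetic.summary().set_index("covariate").loc["grs"]
        assert row["ci_low"] < 1.0 < row["ci_high"]

    def test_ordinal_gleason_coding_runs(self, scored_cohort):
        _, phenotypes, scores = scored_cohort
        clinical, _ = fit_bcr_models(phenotypes, scores, gleason_coding="ordinal")
        assert clinical.converged
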