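import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import pedisrisk as pr
from pedisrisk import published
from pedisrisk.pedis_data import ValidationError
from oracles import auc_pairwise, hdi_exhaustive


class TestHdi:
    def test_constant_samples_zero_width(self):
        interval = pr.hdi(np.full(50, 3.2))
        assert (interval.lower, interval.upper) == (3.2, 3.2)

    def test_outlier_excluded_at_eighty_percent(self):
        interval = pr.hdi([1, 2, 3, 4, 100], mass=0.8)
        assert (interval.lower, interval.upper) == (1.0, 4.0)

    def test_outlier_included_at_ninety_five_percent(self):
        interval = pr.hdi([1, 2, 3, 4, 100], mass=0.95)
        assert (interval.lower, interval.upper) == (1.0, 100.0)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValidationError):
            pr.hdi([1.0])
        with pytest.raises(ValidationError):
            pr.hdi([1.0, np.nan])

    @given(st.integers(0, 10_000), st.sampled_from([0.5, 0.8, 0.9, 0.95]))
    def test_equals_exhaustive_window_search(self, seed, mass):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 300))
        kind = seed % 3
        if kind == 0:
            samples = rng.standard_normal(n)
        elif kind == 1:
            samples = rng.standard_cauchy(n)
        else:
            samples = rng.integers(0, 5, n).astype(float)  # heavy ties
        lo, hi = hdi_exhaustive(samples, mass)
        interval = pr.hdi(samples, mass)
        assert (interval.lower, interval.upper) == (lo, hi)


class TestNullExclusion:
    @pytest.mark.parametrize("bounds,expected", [
        ((0.264, 1.152), True),    # published perfusion interval
        ((-0.483, 0.266), False),  # published infection interval
        ((0.0, 1.0), False),       # boundary counts as covered
    ])
    def test_decision_rule(self, bounds, expected):
        assert pr.null_exclusion(pr.HdiInterval(*bounds)) is expected


class TestTailProbability:
    def test_quarter_below_zero(self):
        assert pr.tail_probability([-1, 1, 2, 3]) == 0.25

    def test_all_positive_gives_zero(self):
        assert pr.tail_probability([0.5, 1.0]) == 0.0

    def test_matches_normal_tail(self):
        rng = np.random.default_rng(12)
        draws = rng.normal(2.0, 1.0, size=30_000)
        from scipy.stats import norm
        assert pr.tail_probability(draws) == pytest.approx(norm.cdf(-2), abs=0.003)


class TestAuc:
    def test_four_point_example(self):
        assert pr.auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_perfect_separation(self):
        assert pr.auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert pr.auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            pr.auc([0.1, 0.2], [1, 1])

    @given(st.integers(0, 5_000))
    def test_equals_pairwise_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 80))
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert pr.auc(scores, labels) == pytest.approx(
            auc_pairwise(scores, labels), abs=1e-12
        )


class TestPosteriorAuc:
    def test_zero_coefficients_give_half(self, small_fit, small_cohort):
        flat = pr.PosteriorDraws(
            np.zeros((2, len(small_fit.names))), np.array([0, 1]),
            small_fit.model_spec, small_fit.config,
        )
        result = pr.posterior_auc(flat, small_cohort)
        assert np.all(result.auc_draws == 0.5)

    def test_replicated_vector_zero_width_distribution(self, small_fit, small_cohort):
        vec = np.median(small_fit.draws, axis=0)
        rep = pr.PosteriorDraws(
            np.tile(vec, (10, 1)), np.repeat([0, 1], 5),
            small_fit.model_spec, small_fit.config,
        )
        result = pr.posterior_auc(rep, small_cohort)
        assert result.hdi.width() == 0.0

    def test_thinning_subsamples_draws(self, small_fit, small_cohort):
        full = pr.posterior_auc(small_fit, small_cohort)
        thinned = pr.posterior_auc(small_fit, small_cohort, thin=10)
        assert thinned.auc_draws.size == math.ceil(full.auc_draws.size / 10)
        assert thinned.median == pytest.approx(full.median, abs=0.01)

    def test_recovers_truth_based_auc(self):
        # the fitted model's apparent AUC should sit near the AUC of the true
        # data-generating probabilities
        cfg = pr.GeneratorConfig(n=2000, seed=31, loss_prob=0.0)
        cohort = pr.generate_cohort(cfg)
        b0 = pr.calibrate_intercept(cfg)
        from pedisrisk.synthetic_cohort import _beta_vector, _design, _sigmoid
        df = cohort.to_frame()
        names, beta = _beta_vector(cfg.true_beta)
        p_true = _sigmoid(b0 + _design(df, cfg, names) @ beta)
        y = df["outcome_any"].to_numpy(int)
        truth_auc = pr.auc(p_true, y)
        draws = pr.fit(None, cohort, pr.ChainConfig(n_chains=2, n_steps=2500,
                                                    burn_in=500, seed=8))
        result = pr.posterior_auc(draws, cohort, thin=4)
        assert result.median == pytest.approx(truth_auc, abs=0.03)


class TestCoefficientSummary:
    def test_or_is_exponentiated_median_and_endpoint_hdi(self, small_fit):
        s = pr.coefficient_summary(small_fit, "perfusion")
        assert s.odds_ratio == math.exp(s.median_beta)
        assert s.or_hdi.lower == math.exp(s.beta_hdi.lower)
        assert s.or_hdi.upper == math.exp(s.beta_hdi.upper)
        assert s.associated == pr.null_exclusion(s.beta_hdi)

    def test_matches_brute_force_recomputation(self, small_fit):
        samples = small_fit.column("extent")
        s = pr.coefficient_summary(small_fit, "extent")
        srt = np.sort(samples)
        assert s.median_beta == float(np.median(srt))
        lo, hi = hdi_exhaustive(samples, 0.95)
        assert (s.beta_hdi.lower, s.beta_hdi.upper) == (lo, hi)
        assert s.prob_below_null == float(np.mean(samples < 0))

    def test_published_or_intervals_from_published_beta_intervals(self):
        # endpoint exponentiation reproduces every printed OR interval
        for table in published.MODEL_SUMMARIES.values():
            for beta, (b_lo, b_hi), or_, (or_lo, or_hi) in table.values():
                for got, printed in [(math.exp(beta), or_),
                                     (math.exp(b_lo), or_lo),
                                     (math.exp(b_hi), or_hi)]:
                    assert abs(got - printed) <= max(0.005, 0.002 * printed)

    def test_unknown_coefficient_rejected(self, small_fit):
        with pytest.raises(KeyError):
            pr.coefficient_summary(small_fit, "toenail")


class TestCompareModels:
    def _auc_post(self, draws):
        draws = np.asarray(draws, dtype=float)
        return pr.AucPosterior(draws, float(np.median(draws)), pr.hdi(draws))

    def test_identical_sets_compare_to_zero(self):
        a = self._auc_post(np.linspace(0.6, 0.8, 100))
        assert pr.compare_models(a, a) == pr.ModelComparison(0.0, 0.0)

    def test_unit_effect_size_closed_form(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0.7, 0.1, 4000)
        base = np.clip(base, 0, 1)
        a = self._auc_post(base)
        b = self._auc_post(np.clip(base + 0.1, 0, 1))
        result = pr.compare_models(a, b)
        assert result.cohens_d == pytest.approx(
            0.1 / float(np.std(np.clip(base, 0, 1), ddof=1)), rel=0.05)

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(4)
        a = self._auc_post(np.clip(rng.normal(0.7, 0.02, 500), 0, 1))
        b = self._auc_post(np.clip(rng.normal(0.75, 0.03, 500), 0, 1))
        fwd = pr.compare_models(a, b)
        rev = pr.compare_models(b, a)
        assert fwd.delta_auc == -rev.delta_auc
        assert fwd.cohens_d == pytest.approx(-rev.cohens_d, rel=1e-12)

    def test_formula_oracle(self):
        rng = np.random.default_rng(5)
        a_draws = np.clip(rng.normal(0.7, 0.02, 1000), 0, 1)
        b_draws = np.clip(rng.normal(0.73, 0.025, 1000), 0, 1)
        result = pr.compare_models(self._auc_post(a_draws), self._auc_post(b_draws))
        pooled = math.sqrt((a_draws.std(ddof=1) ** 2 + b_draws.std(ddof=1) ** 2) / 2)
        assert result.cohens_d == pytest.approx(
            (b_draws.mean() - a_draws.mean()) / pooled, rel=1e-12)
        assert result.delta_auc == pytest.approx(
            float(np.median(b_draws) - np.median(a_draws)), rel=1e-12)


class TestPredictRisk:
    PROFILE_MODERATE = dict(perfusion=2, extent=2, depth=1, infection=1,
                            sensation=1, age=66, gender="male")
    PROFILE_SEVERE = dict(perfusion=3, extent=3, depth=3, infection=1,
                          sensation=1, age=66, gender="male")

    def test_zero_draws_give_half_risk(self, small_fit):
        flat = pr.PosteriorDraws(
            np.zeros((4, len(small_fit.names))), np.array([0, 0, 1, 1]),
            small_fit.model_spec, small_fit.config,
        )
        pred = pr.predict_risk(flat, self.PROFILE_MODERATE)
        assert pred.median_risk == 0.5
        assert pred.hdi.width() == 0.0

    def test_two_draw_closed_form(self, small_fit):
        # construct draws whose linear predictor is exactly +-ln 3
        x = pr.bayes_logistic.design_row(self.PROFILE_MODERATE, small_fit.model_spec)
        d = len(small_fit.names)
        beta = np.zeros((2, d))
        beta[0, 0] = math.log(3)
        beta[1, 0] = -math.log(3)
        draws = pr.PosteriorDraws(beta, np.array([0, 1]),
                                  small_fit.model_spec, small_fit.config)
        pred = pr.predict_risk(draws, self.PROFILE_MODERATE)
        assert sorted(np.round(pred.risk_draws, 10)) == [0.25, 0.75]
        assert pred.median_risk == 0.5
        assert x[0] == 1.0

    def test_severe_profile_dominates_moderate(self, small_fit):
        moderate = pr.predict_risk(small_fit, self.PROFILE_MODERATE)
        severe = pr.predict_risk(small_fit, self.PROFILE_SEVERE)
        assert severe.median_risk > moderate.median_risk
        # stochastic dominance of the risk draws, not just the medians
        assert np.mean(severe.risk_draws > moderate.risk_draws) > 0.95
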