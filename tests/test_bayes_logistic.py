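import math

import numpy as np
import pytest

import pedisrisk as pr
from pedisrisk.bayes_logistic import build_design, design_row
from pedisrisk.pedis_data import ValidationError
from pedisrisk.prior_elicitation import cauchy_log_density

from oracles import quadrature_posterior_1d


class TestLinkFunctions:
    def test_zero_coefficients_give_half(self):
        assert pr.inverse_logit(0.0) == 0.5

    def test_log_three_gives_three_quarters(self):
        assert pr.inverse_logit(math.log(3)) == pytest.approx(0.75)

    def test_extreme_negative_underflows_gracefully(self):
        p = pr.inverse_logit(-745.0)
        assert 0.0 <= p < 1e-300

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValidationError, match="mismatch"):
            pr.linear_predictor(np.zeros(3), np.zeros(4))

    def test_batched_linear_predictor(self):
        beta = np.array([[1.0, 2.0], [0.0, 1.0]])
        x = np.array([[1.0, 1.0], [1.0, 0.0]])
        eta = pr.linear_predictor(beta, x)
        assert eta.shape == (2, 2)
        assert eta[0, 0] == 3.0 and eta[1, 1] == 0.0


class TestLogPosterior:
    def test_single_record_closed_form(self):
        X = np.array([[1.0]])
        y = np.array([1.0])
        lp = pr.log_posterior(np.zeros(1), X, y, np.zeros(1), np.ones(1))
        assert lp == pytest.approx(math.log(0.5) + math.log(1 / math.pi))

    def test_doubling_data_doubles_likelihood_term(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(15, 3))
        y = (rng.random(15) < 0.5).astype(float)
        beta = rng.normal(size=3)
        locs, scales = np.zeros(3), np.ones(3)
        lp1 = pr.log_posterior(beta, X, y, locs, scales)
        lp2 = pr.log_posterior(beta, np.vstack([X, X]), np.concatenate([y, y]),
                               locs, scales)
        prior = float(np.sum(cauchy_log_density(beta, 0.0, 1.0)))
        assert lp2 - prior == pytest.approx(2 * (lp1 - prior), rel=1e-12)

    def test_matches_per_record_brute_force(self):
        # independent oracle: sum Bernoulli log-mass record by record
        rng = np.random.default_rng(42)
        for _ in range(20):
            n, d = rng.integers(2, 30), rng.integers(1, 5)
            X = rng.normal(size=(n, d))
            y = (rng.random(n) < 0.5).astype(float)
            beta = rng.normal(size=d)
            locs = rng.normal(size=d)
            scales = rng.uniform(0.5, 3, size=d)
            expected = 0.0
            for i in range(n):
                p = 1 / (1 + math.exp(-float(X[i] @ beta)))
                expected += math.log(p) if y[i] == 1 else math.log(1 - p)
            for j in range(d):
                z = (beta[j] - locs[j]) / scales[j]
                expected += math.log(1 / (math.pi * scales[j] * (1 + z * z)))
            got = pr.log_posterior(beta, X, y, locs, scales)
            assert got == pytest.approx(expected, rel=1e-10)

    def test_non_finite_beta_rejected(self):
        with pytest.raises(ValidationError):
            pr.log_posterior(np.array([np.nan]), np.ones((1, 1)), np.ones(1),
                             np.zeros(1), np.ones(1))


def intercept_only_cohort(successes=10, failures=10):
    records = []
    for i in range(successes + failures):
        records.append(pr.PedisRecord(
            patient_id=f"p{i}", age=60.0, gender="male",
            perfusion=1, extent=1, depth=1, infection=1, sensation=1,
            outcome_any=1 if i < successes else 0, outcome_major=0,
        ))
    return pr.Cohort(records)


def intercept_only_spec(scale=2.5):
    priors = {"intercept": pr.PriorSpec("intercept", 0.0, scale, "weakly_informative")}
    return pr.ModelSpec(("intercept",), "outcome_any", priors)


class TestFit:
    def test_same_seed_identical_draws(self, small_cohort, light_chains):
        a = pr.fit(None, small_cohort, light_chains)
        b = pr.fit(None, small_cohort, light_chains)
        assert np.array_equal(a.draws, b.draws)
        assert np.array_equal(a.chain_id, b.chain_id)

    def test_constant_outcome_rejected(self):
        cohort = intercept_only_cohort(successes=0, failures=12)
        with pytest.raises(ValidationError, match="constant"):
            pr.fit(intercept_only_spec(), cohort, pr.ChainConfig(n_steps=100, burn_in=10))

    def test_retention_rule_and_subsampling(self, small_cohort):
        cfg = pr.ChainConfig(n_chains=2, n_steps=1500, burn_in=500, seed=1)
        draws = pr.fit(None, small_cohort, cfg)
        assert draws.draws.shape[0] == 2 * 1000
        sub = pr.fit(None, small_cohort,
                     pr.ChainConfig(n_chains=2, n_steps=1500, burn_in=500, seed=1,
                                    retain=500))
        assert sub.draws.shape[0] == 500

    @pytest.mark.parametrize("sampler", ["independence", "rwm"])
    def test_intercept_only_posterior_matches_quadrature(self, sampler):
        # 1-D quadrature is the independent oracle for the sampler
        cohort = intercept_only_cohort(12, 8)
        cfg = pr.ChainConfig(n_chains=2, n_steps=4500, burn_in=500, seed=7,
                             sampler=sampler)
        draws = pr.fit(intercept_only_spec(), cohort, cfg, check_diagnostics=False)
        samples = draws.draws[:, 0]

        def log_post(b):
            return 12 * b - 20 * np.logaddexp(0, b) + float(
                cauchy_log_density(b, 0.0, 2.5))

        _, _, _, q_mean = quadrature_posterior_1d(log_post)
        ess = pr.effective_sample_size(draws.by_chain())[0]
        mcse = samples.std(ddof=1) / math.sqrt(ess)
        assert abs(samples.mean() - q_mean) < 3 * mcse

    def test_flat_prior_large_n_approaches_mle(self):
        # independent IRLS cross-check (statsmodels) at n=5000
        import statsmodels.api as sm

        cohort = pr.generate_cohort(pr.GeneratorConfig(n=5000, seed=17, loss_prob=0.0))
        flat = {
            name: pr.PriorSpec(name, 0.0, 100.0, "weakly_informative")
            for name in pr.bayes_logistic.PREDICTOR_NAMES
        }
        spec = pr.ModelSpec(pr.bayes_logistic.PREDICTOR_NAMES, "outcome_any", flat)
        draws = pr.fit(spec, cohort, pr.ChainConfig(n_chains=2, n_steps=3000,
                                                    burn_in=500, seed=3))
        X, y, _ = build_design(cohort, draws.model_spec)
        mle = sm.Logit(y, X).fit(disp=0).params
        medians = np.median(draws.draws, axis=0)
        assert np.max(np.abs(medians - mle)) < 0.05

    def test_chains_are_exchangeable(self, small_cohort):
        cfg_a = pr.ChainConfig(n_chains=2, n_steps=3000, burn_in=500, seed=101)
        cfg_b = pr.ChainConfig(n_chains=2, n_steps=3000, burn_in=500, seed=202)
        a = pr.fit(None, small_cohort, cfg_a)
        b = pr.fit(None, small_cohort, cfg_b)
        assert not np.array_equal(a.draws, b.draws)
        for j in range(a.draws.shape[1]):
            ess = pr.effective_sample_size(a.by_chain())[j]
            mcse = a.draws[:, j].std(ddof=1) / math.sqrt(ess)
            diff = abs(np.median(a.draws[:, j]) - np.median(b.draws[:, j]))
            # medians agree within Monte-Carlo error (~1.25 sd/sqrt(ess) each)
            assert diff < 6 * mcse


class TestFitUnivariate:
    def test_strong_simulated_effect_excludes_null(self):
        beta = {k: 0.0 for k in pr.synthetic_cohort.default_true_beta()}
        beta["perfusion"] = 1.0
        cohort = pr.generate_cohort(pr.GeneratorConfig(
            n=2000, seed=23, true_beta=beta, loss_prob=0.0))
        draws = pr.fit_univariate("perfusion", cohort,
                                  pr.ChainConfig(n_chains=2, n_steps=2500,
                                                 burn_in=500, seed=5))
        interval = pr.hdi(draws.column("perfusion"))
        assert pr.null_exclusion(interval)
        assert np.median(draws.column("perfusion")) == pytest.approx(1.0, abs=0.15)

    def test_unknown_predictor_rejected(self, small_cohort):
        with pytest.raises(ValidationError):
            pr.fit_univariate("toenail", small_cohort)


class TestDesignCoding:
    def test_profile_requires_explicit_age_and_gender(self, small_fit):
        profile = dict(perfusion=2, extent=2, depth=1, infection=1, sensation=1)
        with pytest.raises(ValidationError, match="age"):
            design_row(profile, small_fit.model_spec)
        profile["age"] = 66
        with pytest.raises(ValidationError, match="gender"):
            design_row(profile, small_fit.model_spec)
        profile["gender"] = "male"
        x = design_row(profile, small_fit.model_spec)
        assert x[0] == 1.0 and x[-1] == 1.0

    def test_gender_coding_male_is_one(self, small_cohort):
        X, _, spec = build_design(small_cohort)
        j = spec.predictor_names.index("gender")
        males = [r.gender == "male" for r in small_cohort.fit_eligible().records]
        assert np.array_equal(X[:, j] == 1.0, np.array(males))
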