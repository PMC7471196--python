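"""Hierarchical model: marginal likelihood, posterior, sampler, summaries."""

import math
import warnings
from math import comb, exp, factorial, inf, log

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit, logit

import dispersaltrials as dt
from dispersaltrials.hbm import _TrialTables


def brute_force_loglik(N, D, C, q, p, r):
    """Independent enumeration oracle built from factorial mass functions."""
    g = 2.0**r - 1.0
    total = 0.0
    for F in range(D + 1):
        lam = F * g
        if lam > 0:
            pois = exp(-lam) * lam**C / factorial(C)
        else:
            pois = 1.0 if C == 0 else 0.0
        total += comb(D, F) * p**F * (1 - p) ** (D - F) * pois
    if total == 0.0:
        return -inf
    return log(comb(N, D) * q**D * (1 - q) ** (N - D) * total)


class TestTrialLoglik:
    def test_small_case_matches_enumeration(self):
        got = dt.trial_loglik_marginal(10, 3, 5, 0.3, 0.5, 2.0)
        want = brute_force_loglik(10, 3, 5, 0.3, 0.5, 2.0)
        assert got == pytest.approx(want, abs=1e-10)

    def test_effectiveness_near_one_degenerates_to_poisson(self):
        """p -> 1 pins the founder count at D."""
        N, D, C, q, r = 20, 8, 30, 0.4, 2.0
        got = dt.trial_loglik_marginal(N, D, C, q, 1 - 1e-12, r)
        lam = D * (2.0**r - 1.0)
        want = stats.binom.logpmf(D, N, q) + stats.poisson.logpmf(C, lam)
        assert got == pytest.approx(float(want), abs=1e-6)

    def test_no_founders_with_no_colonizers(self):
        """p -> 0 with C = 0: the settlement/growth layers contribute 1."""
        N, D, q, r = 20, 8, 0.4, 2.0
        got = dt.trial_loglik_marginal(N, D, 0, q, 1e-14, r)
        assert got == pytest.approx(float(stats.binom.logpmf(D, N, q)), abs=1e-6)

    def test_impossible_event_is_minus_inf(self):
        assert dt.trial_loglik_marginal(10, 0, 3, 0.3, 0.5, 2.0) == -inf

    def test_nonpositive_growth_handled_as_point_mass(self):
        # r <= 0 makes the Poisson rate non-positive: only extinction has mass
        assert np.isfinite(dt.trial_loglik_marginal(10, 3, 0, 0.3, 0.5, -1.0))
        assert dt.trial_loglik_marginal(10, 3, 2, 0.3, 0.5, -1.0) == -inf

    @pytest.mark.parametrize("bad", [{"q": 0.0}, {"q": 1.0}, {"p_i": 0.0}, {"p_i": 1.0}])
    def test_parameter_domain_errors(self, bad):
        kwargs = dict(N=10, D=3, C=5, q=0.3, p_i=0.5, r=2.0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            dt.trial_loglik_marginal(**kwargs)

    def test_sampler_tables_match_scalar_path(self, small_sim_data):
        """The padded vectorized likelihood equals the per-trial scalar one."""
        data, _ = small_sim_data
        tables = _TrialTables(data)
        rng = np.random.default_rng(0)
        eta = rng.normal(size=data.n_trials)
        r = 3.5
        col = tables.col_loglik(eta, r)
        N, D, C = data.n_source, data.dispersers, data.colonizers
        for i in range(data.n_trials):
            want = dt.trial_loglik_marginal(
                int(N[i]), int(D[i]), int(C[i]), 0.4, float(expit(eta[i])), r
            ) - float(stats.binom.logpmf(D[i], N[i], 0.4))
            assert col[i] == pytest.approx(want, abs=1e-9)


class TestLogPosterior:
    def test_hand_assembled_single_trial(self, prior_spec):
        data = dt.HBMData((dt.TrialRecord.from_dispersers("t", 50, 20, 12),))
        params = dt.HBMParams(q=0.35, mu=-0.5, sigma_p=1.2, r=3.8, eta=[-0.9])
        got = dt.log_posterior(data, params, prior_spec)
        want = (
            dt.trial_loglik_marginal(50, 20, 12, 0.35, float(expit(-0.9)), 3.8)
            + stats.norm.logpdf(-0.9, -0.5, 1.2)
            + stats.norm.logpdf(3.8, prior_spec.growth.m, prior_spec.growth.sigma)
            + stats.beta.logpdf(0.35, *prior_spec.q_prior)
            + stats.norm.logpdf(-0.5, *prior_spec.mu_prior)
            - math.log(prior_spec.sigma_p_upper)
        )
        assert got == pytest.approx(float(want), abs=1e-10)

    @pytest.mark.parametrize(
        "params",
        [
            dict(q=0.35, mu=0.0, sigma_p=0.0, r=3.8),
            dict(q=0.0, mu=0.0, sigma_p=1.0, r=3.8),
            dict(q=1.0, mu=0.0, sigma_p=1.0, r=3.8),
            dict(q=0.35, mu=0.0, sigma_p=11.0, r=3.8),
        ],
    )
    def test_outside_support_is_minus_inf(self, prior_spec, params):
        data = dt.HBMData((dt.TrialRecord.from_dispersers("t", 50, 20, 12),))
        p = dt.HBMParams(eta=[0.0], **params)
        assert dt.log_posterior(data, p, prior_spec) == -inf

    def test_r_shift_with_diffuse_prior_is_likelihood_only(self):
        """With a near-flat prior on r, shifting r changes only the likelihood."""
        data = dt.HBMData((dt.TrialRecord.from_dispersers("t", 50, 20, 12),))
        wide = dt.PriorSpec(growth=dt.GrowthPrior(m=4.0, sigma=1e9))
        base = dict(q=0.35, mu=-0.5, sigma_p=1.2, eta=[-0.9])
        delta_post = dt.log_posterior(
            data, dt.HBMParams(r=4.5, **base), wide
        ) - dt.log_posterior(data, dt.HBMParams(r=3.5, **base), wide)
        p_i = float(expit(-0.9))
        delta_lik = dt.trial_loglik_marginal(
            50, 20, 12, 0.35, p_i, 4.5
        ) - dt.trial_loglik_marginal(50, 20, 12, 0.35, p_i, 3.5)
        assert delta_post == pytest.approx(delta_lik, abs=1e-6)


class TestFit:
    def test_deterministic_under_seed(self, prior_spec):
        data = dt.HBMData(
            (
                dt.TrialRecord.from_dispersers("a", 60, 25, 40),
                dt.TrialRecord.from_dispersers("b", 55, 18, 12),
            )
        )
        kwargs = dict(n_chains=2, n_warmup=150, n_draws=150, seed=123)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            one = dt.fit(data, prior_spec, **kwargs)
            two = dt.fit(data, prior_spec, **kwargs)
        assert np.array_equal(one.q, two.q)
        assert np.array_equal(one.r, two.r)
        assert np.array_equal(one.eta, two.eta)
        assert np.array_equal(one.founders, two.founders)

    def test_draw_invariants(self, small_sim_data, prior_spec):
        data, _ = small_sim_data
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            draws = dt.fit(data, prior_spec, n_chains=2, n_warmup=300, n_draws=300, seed=4)
        D = data.dispersers
        assert np.all((draws.q > 0) & (draws.q < 1))
        assert np.all(draws.sigma_p > 0)
        assert np.all((draws.p_trial > 0) & (draws.p_trial < 1))
        assert np.all(draws.founders >= 0)
        assert np.all(draws.founders <= D[None, None, :])

    def test_colonizers_without_dispersers_rejected(self, prior_spec):
        data = dt.HBMData((dt.TrialRecord("t", 10, 10, 3),))
        with pytest.raises(ValueError, match="likelihood is zero"):
            dt.fit(data, prior_spec, n_chains=2, n_warmup=50, n_draws=50, seed=0)

    def test_single_chain_rejected(self, prior_spec):
        data = dt.HBMData((dt.TrialRecord.from_dispersers("t", 50, 20, 12),))
        with pytest.raises(ValueError, match="chains"):
            dt.fit(data, prior_spec, n_chains=1, n_warmup=50, n_draws=50, seed=0)

    def test_prior_recovery_without_information(self, prior_spec):
        """With all D = 0, C = 0 the posterior of r reproduces its prior."""
        data = dt.HBMData(tuple(dt.TrialRecord(f"t{i}", 50, 50, 0) for i in range(5)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            draws = dt.fit(data, prior_spec, n_chains=2, n_warmup=1000, n_draws=2000, seed=9)
        r = draws.flat("r")
        ess = draws.diagnostics["r"]["ess"]
        mcse = r.std() / math.sqrt(ess)
        assert abs(r.mean() - prior_spec.growth.m) < 3 * mcse
        assert abs(r.std() - prior_spec.growth.sigma) < 3 * prior_spec.growth.sigma / math.sqrt(
            2 * ess
        )

    def test_degenerate_trials_still_inform_q(self, prior_spec):
        """Trials with D = 0 pull the dispersal-rate posterior toward zero."""
        data = dt.HBMData(tuple(dt.TrialRecord(f"t{i}", 100, 100, 0) for i in range(4)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            draws = dt.fit(data, prior_spec, n_chains=2, n_warmup=500, n_draws=500, seed=2)
        # Beta(1, 401) posterior: mean ~ 0.0025
        assert draws.flat("q").mean() < 0.01


class TestSummarize:
    def _draws(self, **overrides):
        base = dict(
            q=np.full((2, 500), 0.3),
            mu=np.zeros((2, 500)),
            sigma_p=np.ones((2, 500)),
            r=np.full((2, 500), 2.0),
            eta=np.zeros((2, 500, 1)),
            founders=None,
            seed=0,
        )
        base.update(overrides)
        return dt.PosteriorDraws(**base)

    def test_constant_draws(self):
        s = dt.summarize(self._draws())
        row = s.row("q")
        for key in ("mean", "q2.5", "q97.5"):
            assert row[key] == pytest.approx(0.3, abs=1e-14)

    def test_sequence_mean(self):
        r = np.arange(1.0, 1001.0).reshape(2, 500)
        row = dt.summarize(self._draws(r=r)).row("r")
        assert row["mean"] == pytest.approx(500.5)

    def test_quantile_ordering(self, small_sim_data, prior_spec):
        data, _ = small_sim_data
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            draws = dt.fit(data, prior_spec, n_chains=2, n_warmup=300, n_draws=300, seed=6)
        table = dt.summarize(draws).table
        assert (table["q2.5"] <= table["mean"]).all()
        assert (table["mean"] <= table["q97.5"]).all()

    def test_k_summary_is_per_draw_not_plugin(self):
        """The colonization-potential summary averages p*(2^r - 1) per draw;
        the plug-in of posterior means differs by a Jensen gap."""
        rng = np.random.default_rng(0)
        mu = rng.normal(0.0, 1.0, size=(2, 500))
        r = rng.normal(3.0, 0.8, size=(2, 500))
        draws = self._draws(mu=mu, r=r)
        s = dt.summarize(draws)
        per_draw = expit(mu) * (2.0**r - 1.0)
        assert s.row("k")["mean"] == pytest.approx(per_draw.mean(), rel=1e-12)
        plugin = float(expit(mu.mean()) * (2.0 ** r.mean() - 1.0))
        assert abs(s.row("k")["mean"] - plugin) > 0.1

    def test_too_few_draws_rejected(self):
        tiny = self._draws(
            q=np.full((2, 10), 0.3),
            mu=np.zeros((2, 10)),
            sigma_p=np.ones((2, 10)),
            r=np.full((2, 10), 2.0),
            eta=np.zeros((2, 10, 1)),
        )
        with pytest.raises(ValueError, match="draws"):
            dt.summarize(tiny)


class TestPosteriorPredictive:
    def _constant_draws(self, q, mu, sigma_p, r, n_trials, m=400):
        return dt.PosteriorDraws(
            q=np.full((1, m), q),
            mu=np.full((1, m), mu),
            sigma_p=np.full((1, m), sigma_p),
            r=np.full((1, m), r),
            eta=np.full((1, m, n_trials), mu),
            founders=None,
            seed=0,
        )

    def test_degenerate_chain_gives_poisson_of_n(self):
        """q = p = 1, r = 1 collapses the chain to C* ~ Poisson(N)."""
        data = dt.HBMData((dt.TrialRecord("t", 10, 0, 5),))
        draws = self._constant_draws(1.0 - 1e-12, 40.0, 1e-9, 1.0, 1, m=2000)
        rep = dt.posterior_predictive(draws, data, seed=3)
        mean = rep["C"].mean()
        assert abs(mean - 10.0) < 3 * math.sqrt(10.0 / rep["C"].size)

    def test_no_dispersal_gives_all_zero(self):
        data = dt.HBMData((dt.TrialRecord("t", 10, 0, 5),))
        draws = self._constant_draws(0.0, 0.0, 1.0, 2.0, 1)
        rep = dt.posterior_predictive(draws, data, seed=1)
        assert np.all(rep["D"] == 0) and np.all(rep["C"] == 0)

    def test_replicate_mean_matches_chain_expectation(self):
        """Under sigma_p = 0, E[C] = N q p (2^r - 1)."""
        N, q, mu, r = 40, 0.5, 0.0, 2.0
        data = dt.HBMData((dt.TrialRecord("t", N, 0, 5),))
        draws = self._constant_draws(q, mu, 1e-12, r, 1, m=4000)
        rep = dt.posterior_predictive(draws, data, seed=8)
        expect = N * q * expit(mu) * (2.0**r - 1.0)
        se = rep["C"].std() / math.sqrt(rep["C"].size)
        assert abs(rep["C"].mean() - expect) < 3 * se

    def test_chain_ordering(self, small_sim_data, prior_spec):
        data, _ = small_sim_data
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            draws = dt.fit(data, prior_spec, n_chains=2, n_warmup=200, n_draws=200, seed=5)
        rep = dt.posterior_predictive(draws, data, seed=0)
        assert np.all(rep["F"] <= rep["D"])
        assert np.all(rep["D"] <= data.n_source[None, :])
        assert np.all(rep["C"] >= 0)
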