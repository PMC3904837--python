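"""ML fitting, AIC ranking, LRT, priors, and slice-sampling MCMC."""

import numpy as np
import pytest

from geodiv import (
    FitResult,
    GeoSSELikelihood,
    GeoSSEParams,
    ModelSpec,
    PriorSpec,
    character_independent_model,
    default_priors,
    fit_ml,
    full_model,
    lrt,
    rank_models,
    run_mcmc,
    summarize_posterior,
)
from geodiv.inference import PosteriorSample
from geodiv.simulate import make_dataset


@pytest.fixture(scope="module")
def small_fit_data():
    """~80-tip equal-rates dataset plus a fast likelihood for it."""
    tree, states, truth = make_dataset("equal_rates", seed=11, target_tips=80)
    fn = GeoSSELikelihood(tree, states, rtol=1e-7, atol=1e-9)
    return tree, states, fn


def _dummy_fit(spec, lnL):
    p = GeoSSEParams(0.2, 0.2, 0.0 if not spec.allow_biome_divergence else 0.01,
                     0.1, 0.1, 0.02, 0.02)
    return FitResult(model=spec, params=p, lnL=lnL, converged=True)


class TestRanking:
    def test_aic_arithmetic_and_order(self):
        f7 = _dummy_fit(full_model(), -100.0)  # AIC 214
        f5 = _dummy_fit(ModelSpec(speciation_equal=True, extinction_equal=True), -101.0)  # AIC 212
        tab = rank_models([f7, f5])
        assert tab.iloc[0].AIC == pytest.approx(212.0)
        assert tab.iloc[0].k == 5
        assert tab.iloc[0].dAIC == 0.0
        assert tab.iloc[1].dAIC == pytest.approx(2.0)

    def test_single_fit_delta_zero(self):
        tab = rank_models([_dummy_fit(full_model(), -50.0)])
        assert tab.dAIC.tolist() == [0.0]

    def test_tie_broken_by_fewer_parameters(self):
        # equal AIC: k=5 lnL=-101 vs k=7 lnL=-99
        f7 = _dummy_fit(full_model(), -99.0)
        f5 = _dummy_fit(ModelSpec(speciation_equal=True, extinction_equal=True), -101.0)
        assert f7.aic == f5.aic
        tab = rank_models([f7, f5])
        assert tab.iloc[0].k == 5


class TestLRT:
    def test_chi_square_quantile(self):
        nested = _dummy_fit(ModelSpec(speciation_equal=True), -101.9205)
        full = _dummy_fit(full_model(), -100.0)
        stat, df, p = lrt(nested, full)
        assert df == 1
        assert stat == pytest.approx(3.841, abs=1e-3)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_equal_likelihoods_give_p_one(self):
        nested = _dummy_fit(ModelSpec(speciation_equal=True), -100.0)
        full = _dummy_fit(full_model(), -100.0)
        stat, df, p = lrt(nested, full)
        assert stat == 0.0 and p == 1.0

    def test_two_df_small_statistic(self):
        nested = _dummy_fit(
            ModelSpec(speciation_equal=True, extinction_equal=True), -100.05
        )
        full = _dummy_fit(full_model(), -100.0)
        stat, df, p = lrt(nested, full)
        assert df == 2
        # chi-square survival at 0.1 with 2 df = exp(-0.05)
        assert p == pytest.approx(np.exp(-0.05), abs=1e-6)

    def test_statistic_floored_at_zero(self):
        nested = _dummy_fit(ModelSpec(speciation_equal=True), -99.9)
        full = _dummy_fit(full_model(), -100.0)
        stat, _, p = lrt(nested, full)
        assert stat == 0.0 and p == 1.0

    def test_non_nested_rejected(self):
        a = _dummy_fit(ModelSpec(speciation_equal=True), -100.0)
        b = _dummy_fit(ModelSpec(extinction_equal=True), -100.0)
        with pytest.raises(ValueError, match="not nested"):
            lrt(a, b)


class TestFitML:
    def test_refit_from_optimum_is_idempotent(self, small_fit_data):
        tree, states, fn = small_fit_data
        spec = character_independent_model()
        fit1 = fit_ml(tree, states, spec=spec, starts=2, seed=0, likelihood=fn)
        fit2 = fit_ml(
            tree, states, spec=spec, starts=1, seed=0, likelihood=fn,
            init=fit1.params,
        )
        assert fit2.lnL == pytest.approx(fit1.lnL, abs=1e-4)
        assert fit2.lnL >= fit1.lnL - 1e-6

    def test_nested_model_never_beats_full(self, small_fit_data):
        tree, states, fn = small_fit_data
        nested = fit_ml(
            tree, states, spec=character_independent_model(), starts=2, seed=0,
            likelihood=fn,
        )
        full = fit_ml(
            tree, states, spec=full_model(), starts=2, seed=0,
            likelihood=fn, init=_expand(nested.params),
        )
        assert full.lnL >= nested.lnL - 1e-6

    def test_deterministic_given_seed(self, small_fit_data):
        tree, states, fn = small_fit_data
        spec = character_independent_model()
        f1 = fit_ml(tree, states, spec=spec, starts=2, seed=5, likelihood=fn)
        f2 = fit_ml(tree, states, spec=spec, starts=2, seed=5, likelihood=fn)
        assert f1.lnL == f2.lnL
        assert f1.params == f2.params


def _expand(p):
    return GeoSSEParams(
        p.lambda_temp, p.lambda_trop, p.lambda_tt, p.mu_temp, p.mu_trop,
        p.d_temp, p.d_trop,
    )


class TestPriors:
    def test_rule_mean_twice_net_diversification(self, small_fit_data):
        tree, states, fn = small_fit_data
        prior = default_priors(tree, states, seed=3)
        ci = fit_ml(
            tree, states, spec=character_independent_model(), starts=3, seed=3
        )
        r_hat = ci.params.r_temp
        assert r_hat > 0
        assert prior.mean == pytest.approx(2 * r_hat, rel=0.05)

    def test_rate_arithmetic(self):
        # r_hat = 0.05 -> mean 0.1 -> rate 10
        prior = PriorSpec(rate=1.0 / (2 * 0.05))
        assert prior.mean == pytest.approx(0.1)
        assert prior.rate == pytest.approx(10.0)

    def test_density_at_zero_finite_positive(self):
        prior = PriorSpec(rate=10.0)
        assert np.isfinite(prior.logpdf(np.zeros(3)))
        assert prior.logpdf(np.zeros(3)) == pytest.approx(3 * np.log(10.0))

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            PriorSpec(rate=0.0)


class TestMCMC:
    def test_same_seed_identical_chains(self, small_fit_data):
        tree, states, _ = small_fit_data
        kw = dict(
            spec=character_independent_model(), priors=PriorSpec(rate=10.0),
            steps=40, burnin=5, seed=9,
        )
        s1 = run_mcmc(tree, states, **kw)
        s2 = run_mcmc(tree, states, **kw)
        assert np.array_equal(s1.draws, s2.draws)
        assert np.array_equal(s1.lnL, s2.lnL)

    def test_flat_likelihood_recovers_prior(self, small_fit_data):
        """With the likelihood held flat the sampler's marginal must be
        the exponential prior (QQ / KS check on thinned draws)."""
        from scipy import stats

        tree, states, _ = small_fit_data
        rate = 4.0
        sample = run_mcmc(
            tree, states, spec=character_independent_model(),
            priors=PriorSpec(rate=rate), steps=2500, burnin=200, seed=21,
            loglik_fn=lambda p: 0.0,
        )
        thinned = sample.draws[::5, 1]
        ks = stats.kstest(thinned, "expon", args=(0.0, 1.0 / rate))
        assert ks.pvalue > 0.01
        # QQ agreement in the bulk
        qs = np.linspace(0.1, 0.9, 9)
        got = np.quantile(sample.draws[:, 0], qs)
        want = stats.expon.ppf(qs, scale=1.0 / rate)
        assert np.allclose(got, want, rtol=0.25)

    def test_tight_prior_shrinks_toward_prior_mean(self, small_fit_data):
        tree, states, fn = small_fit_data
        ml = fit_ml(
            tree, states, spec=character_independent_model(), starts=2, seed=13,
            likelihood=fn,
        )
        sample = run_mcmc(
            tree, states, spec=character_independent_model(),
            priors=PriorSpec(rate=2000.0), steps=400, burnin=100, seed=13,
        )
        post = sample.draws.mean(axis=0)
        ml_vec = character_independent_model().pack(ml.params)
        # prior mean 5e-4: every parameter shrinks far below its ML value
        assert np.all(post < np.maximum(0.2 * ml_vec, 5e-3))

    def test_bad_init_rejected(self, small_fit_data):
        tree, states, _ = small_fit_data
        with pytest.raises(ValueError, match="zero posterior"):
            run_mcmc(
                tree, states, spec=character_independent_model(),
                priors=PriorSpec(rate=10.0), steps=10, burnin=1, seed=0,
                init=np.array([0.0, 0.0, 0.0]),  # lambda = 0 is impossible
            )

    def test_time_varying_unsupported(self, small_fit_data):
        tree, states, _ = small_fit_data
        with pytest.raises(ValueError, match="time-constant"):
            run_mcmc(tree, states, spec=full_model().with_time_varying(),
                     priors=PriorSpec(rate=10.0), steps=10, burnin=1)


class TestPosteriorSummary:
    def _sample(self, draws):
        draws = np.asarray(draws, dtype=float)
        return PosteriorSample(
            spec=character_independent_model(),
            names=character_independent_model().free_names(),
            draws=draws,
            lnL=np.zeros(len(draws)),
            prior=PriorSpec(rate=1.0),
            seed=0, steps=len(draws), burnin=0,
        )

    def test_constant_chain_zero_width_interval(self):
        s = self._sample(np.tile([0.2, 0.1, 0.05], (50, 1)))
        out = summarize_posterior(s)
        ci = out["parameters"]["lambda"]["ci"]
        assert ci[0] == ci[1] == pytest.approx(0.2)

    def test_difference_is_zero_under_equal_rates_spec(self):
        # equal-rates spec: r_trop - r_temp is identically 0, never significant
        s = self._sample(np.abs(np.random.default_rng(0).normal(0.2, 0.01, (100, 3))))
        out = summarize_posterior(s)
        assert out["r_trop_minus_r_temp"]["mean"] == 0.0
        assert not out["r_trop_minus_r_temp"]["significant"]

    def test_significance_flag_from_full_model_draws(self):
        spec = full_model()
        rng = np.random.default_rng(1)
        base = np.abs(rng.normal(0.2, 0.005, (80, 7)))
        # all draws: lambda_trop >> lambda_temp, mu equal -> positive diff
        base[:, 0] = 0.1
        base[:, 1] = 0.4
        base[:, 3] = base[:, 4] = 0.05
        s = PosteriorSample(
            spec=spec, names=spec.free_names(), draws=base,
            lnL=np.zeros(80), prior=PriorSpec(rate=1.0), seed=0, steps=80, burnin=0,
        )
        out = summarize_posterior(s)
        assert out["r_trop_minus_r_temp"]["mean"] == pytest.approx(0.3, abs=1e-9)
        assert out["r_trop_minus_r_temp"]["significant"]

    def test_symmetric_draws_not_significant(self):
        spec = full_model()
        rng = np.random.default_rng(2)
        draws = np.abs(rng.normal(0.2, 0.05, (200, 7)))
        # swap-symmetric construction: difference symmetric around 0
        half = draws.copy()
        half[:, [0, 1]] = draws[:, [1, 0]]
        half[:, [3, 4]] = draws[:, [4, 3]]
        s = PosteriorSample(
            spec=spec, names=spec.free_names(),
            draws=np.vstack([draws, half]),
            lnL=np.zeros(400), prior=PriorSpec(rate=1.0), seed=0, steps=400, burnin=0,
        )
        out = summarize_posterior(s)
        assert not out["r_trop_minus_r_temp"]["significant"]

    def test_empty_sample_rejected(self):
        s = self._sample(np.empty((0, 3)))
        with pytest.raises(ValueError, match="empty"):
            summarize_posterior(s)
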