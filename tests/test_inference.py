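"""Likelihood, posterior, sampler and diagnostics for decay-rate inference."""

import numpy as np
import pytest
from scipy import stats

from lakewec import (
    AnnualRecord,
    Chain,
    DegenerateChainError,
    MCMCConfig,
    NutrientSeries,
    PriorSpec,
    convergence_check,
    fit_metrics,
    log_likelihood,
    log_posterior,
    mc_error,
    sample_posterior,
    summarize_posterior,
)
from lakewec.inference import PosteriorSummary
from lakewec.synthetic import SimulationDesign, simulate_series


def brute_force_log_likelihood(decay, sigma, series):
    """Literal product-of-normals evaluation, record by record."""
    product = 1.0
    for rec in series.records:
        r = rec.outflow / series.geometry.volume
        mean = rec.load / (series.geometry.volume * (r + decay))
        product *= stats.norm.pdf(rec.observed_conc, loc=mean, scale=sigma)
    return np.log(product)


class TestLogLikelihood:
    def test_zero_residuals(self, geometry):
        decay, sigma = 1.8, 5.0
        records = []
        for i, (load, q) in enumerate([(4e4, 120.0), (5e4, 140.0), (4.5e4, 130.0)]):
            r = q / geometry.volume
            conc = load / (geometry.volume * (r + decay))
            records.append(AnnualRecord(2000 + i, load, q, conc))
        series = NutrientSeries("TN", records, geometry)
        expected = -len(series) * np.log(sigma * np.sqrt(2 * np.pi))
        assert log_likelihood(decay, sigma, series) == pytest.approx(expected, rel=1e-12)

    def test_additivity_of_one_residual(self, geometry):
        decay, sigma, d = 1.8, 8.0, 12.5
        base = []
        for i, (load, q) in enumerate([(4e4, 120.0), (5e4, 140.0)]):
            r = q / geometry.volume
            conc = load / (geometry.volume * (r + decay))
            base.append(AnnualRecord(2000 + i, load, q, conc))
        r = 150.0 / geometry.volume
        conc = 4.2e4 / (geometry.volume * (r + decay))
        extra = AnnualRecord(2002, 4.2e4, 150.0, conc + d)
        series0 = NutrientSeries("TN", base, geometry)
        series1 = NutrientSeries("TN", base + [extra], geometry)
        delta = log_likelihood(decay, sigma, series1) - log_likelihood(decay, sigma, series0)
        expected = -np.log(sigma * np.sqrt(2 * np.pi)) - d**2 / (2 * sigma**2)
        assert delta == pytest.approx(expected, rel=1e-12)

    def test_matches_brute_force_product(self, synthetic_series):
        for decay, sigma in [(1.4, 15.0), (1.861, 20.0), (2.3, 35.0)]:
            assert log_likelihood(decay, sigma, synthetic_series) == pytest.approx(
                brute_force_log_likelihood(decay, sigma, synthetic_series), abs=1e-9
            )

    def test_invalid_sigma(self, synthetic_series):
        with pytest.raises(ValueError):
            log_likelihood(1.8, 0.0, synthetic_series)


class TestLogPosterior:
    def test_outside_support_is_minus_inf(self, synthetic_series, tn_prior):
        assert log_posterior(0.5, 20.0, synthetic_series, tn_prior) == -np.inf
        assert log_posterior(2.6, 20.0, synthetic_series, tn_prior) == -np.inf

    def test_flat_prior_limit_ratio_equals_likelihood_ratio(self, synthetic_series):
        """With a nearly flat Gamma prior the posterior ratio between two
        points at equal sigma reduces to the likelihood ratio."""
        prior = PriorSpec(1.0, 2.5, sigma_prior_shape=1e-8, sigma_prior_rate=1e-8)
        sigma = 22.0
        lp = log_posterior(1.7, sigma, synthetic_series, prior) - log_posterior(
            2.1, sigma, synthetic_series, prior
        )
        ll = log_likelihood(1.7, sigma, synthetic_series) - log_likelihood(
            2.1, sigma, synthetic_series
        )
        assert lp == pytest.approx(ll, abs=1e-6)

    def test_normalizable_over_grid(self, synthetic_series, tn_prior):
        """2-D quadrature of exp(log-posterior) gives a finite positive mass."""
        s_grid = np.linspace(tn_prior.s_low, tn_prior.s_high, 301)
        sig_grid = np.geomspace(2.0, 200.0, 201)
        logp = np.array(
            [
                [log_posterior(s, sig, synthetic_series, tn_prior) for sig in sig_grid]
                for s in s_grid
            ]
        )
        dens = np.exp(logp - logp.max())
        mass = np.trapezoid(np.trapezoid(dens, sig_grid, axis=1), s_grid)
        assert np.isfinite(mass) and mass > 0


class TestSampler:
    def test_recovers_truth_with_small_noise(self, tn_prior, fast_mcmc):
        design = SimulationDesign(true_s=1.8, true_sigma=5.0, seed=21)
        series = simulate_series(design)
        chain = sample_posterior(series, tn_prior, fast_mcmc)
        assert summarize_posterior(chain).mean == pytest.approx(1.8, abs=0.1)

    def test_prior_only_draws_are_uniform(self, synthetic_series, tn_prior):
        chain = sample_posterior(
            synthetic_series, tn_prior, MCMCConfig(n_iterations=6000, burn_in=1000, seed=5),
            prior_only=True,
        )
        u = (chain.s_draws - tn_prior.s_low) / (tn_prior.s_high - tn_prior.s_low)
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_same_seed_bit_identical(self, synthetic_series, tn_prior, fast_mcmc):
        a = sample_posterior(synthetic_series, tn_prior, fast_mcmc)
        b = sample_posterior(synthetic_series, tn_prior, fast_mcmc)
        assert np.array_equal(a.s_draws, b.s_draws)
        assert np.array_equal(a.sigma_draws, b.sigma_draws)
        c = sample_posterior(
            synthetic_series, tn_prior,
            MCMCConfig(n_iterations=fast_mcmc.n_iterations, burn_in=fast_mcmc.burn_in, seed=99),
        )
        assert not np.array_equal(a.s_draws, c.s_draws)

    def test_draws_respect_support_and_acceptance(self, synthetic_series, tn_prior, fast_mcmc):
        chain = sample_posterior(synthetic_series, tn_prior, fast_mcmc)
        assert chain.s_draws.min() >= tn_prior.s_low
        assert chain.s_draws.max() <= tn_prior.s_high
        assert np.all(chain.sigma_draws > 0)
        assert 0.1 < chain.acceptance_rate < 0.7

    def test_thinning(self, synthetic_series, tn_prior):
        cfg = MCMCConfig(n_iterations=6000, burn_in=1000, thin=5, seed=3)
        chain = sample_posterior(synthetic_series, tn_prior, cfg)
        assert len(chain) == 1000


class TestSummaries:
    def test_permuted_integers(self):
        rng = np.random.default_rng(0)
        draws = rng.permutation(np.arange(1.0, 10001.0))
        summ = summarize_posterior(draws)
        assert summ.mean == pytest.approx(5000.5)
        # linear-interpolation order statistics of 1..10000
        assert summ.q05 == pytest.approx(500.95)
        assert summ.q25 == pytest.approx(2500.75)
        assert summ.q75 == pytest.approx(7500.25)
        assert summ.q95 == pytest.approx(9500.05)
        assert summ.sd == pytest.approx(np.std(draws, ddof=1))

    def test_degenerate_chain_rejected(self):
        with pytest.raises(DegenerateChainError):
            summarize_posterior(np.full(1000, 1.5))

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            summarize_posterior(np.arange(50.0))

    def test_chain_length_validation(self):
        with pytest.raises(ValueError):
            Chain(np.ones(10), np.ones(9), 0.5)
        with pytest.raises(ValueError):
            Chain(np.ones(10), np.zeros(10), 0.5)


class TestMCError:
    def test_iid_standard_normal(self):
        rng = np.random.default_rng(42)
        draws = rng.standard_normal(50_000)
        expected = 1.0 / np.sqrt(50_000)
        assert mc_error(draws) == pytest.approx(expected, rel=0.3)

    def test_constant_chain_is_zero(self):
        assert mc_error(np.full(5000, 2.0)) == 0.0

    def test_sqrt_scaling_with_length(self):
        rng = np.random.default_rng(1)
        short = rng.standard_normal(20_000)
        long = rng.standard_normal(40_000)
        assert mc_error(short) / mc_error(long) == pytest.approx(np.sqrt(2), rel=0.25)

    def test_truncates_non_divisible_length(self):
        draws = np.arange(5003, dtype=float)
        assert np.isfinite(mc_error(draws))


class TestConvergence:
    def test_published_tn_diagnostics_pass(self):
        summ = PosteriorSummary(
            q05=1.728, q25=1.805, mean=1.861, q75=1.914, q95=2.0,
            sd=0.08329, mc_error=0.0003863,
        )
        result = convergence_check(summ)
        assert result.passed
        assert result.ratio == pytest.approx(0.0046, abs=0.0005)

    @pytest.mark.parametrize("ratio", [1.0, 0.08])
    def test_at_or_above_threshold_fails(self, ratio):
        summ = PosteriorSummary(
            q05=0.9, q25=0.95, mean=1.0, q75=1.05, q95=1.1, sd=0.1, mc_error=0.1 * ratio
        )
        assert not convergence_check(summ).passed


class TestFitMetrics:
    def test_perfect_fit(self, geometry):
        decay = 1.8
        records = []
        for i, (load, q) in enumerate([(4e4, 120.0), (5e4, 140.0), (4.5e4, 100.0)]):
            r = q / geometry.volume
            records.append(
                AnnualRecord(2000 + i, load, q, load / (geometry.volume * (r + decay)))
            )
        series = NutrientSeries("TN", records, geometry)
        m = fit_metrics(decay, series)
        assert m["r_squared"] == pytest.approx(1.0, abs=1e-12)
        assert m["nse"] == pytest.approx(1.0, abs=1e-12)

    def test_oracle_formulas_and_nse_bound(self, synthetic_series):
        """Independent re-implementation of both formulas; NSE never
        exceeds the squared Pearson correlation."""
        for decay in (1.4, 1.861, 2.2):
            m = fit_metrics(decay, synthetic_series)
            obs = synthetic_series.observed_conc
            sim = synthetic_series.predicted_conc(decay)
            sxy = np.sum((obs - obs.mean()) * (sim - sim.mean()))
            r2 = sxy**2 / (np.sum((obs - obs.mean()) ** 2) * np.sum((sim - sim.mean()) ** 2))
            nse = 1 - np.sum((obs - sim) ** 2) / np.sum((obs - obs.mean()) ** 2)
            assert m["r_squared"] == pytest.approx(r2, abs=1e-10)
            assert m["nse"] == pytest.approx(nse, abs=1e-10)
            assert m["nse"] <= m["r_squared"] + 1e-12

    def test_constant_prediction_nse_zero(self, geometry):
        # equal loads/rates -> constant simulated series; engineered so the
        # constant equals mean(obs), the NSE zero point
        decay = 1.0
        load, q = 4.43e4, 44.3
        conc = load / (geometry.volume * (q / geometry.volume + decay))
        records = [
            AnnualRecord(2000, load, q, conc - 30.0),
            AnnualRecord(2001, load, q, conc + 30.0),
        ]
        series = NutrientSeries("TN", records, geometry)
        assert fit_metrics(decay, series)["nse"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_observations_error(self, geometry):
        records = [AnnualRecord(2000 + i, 4e4, 120.0, 200.0) for i in range(3)]
        series = NutrientSeries("TN", records, geometry)
        with pytest.raises(ValueError, match="zero variance"):
            fit_metrics(1.8, series)

    def test_chain_input_gives_level_wise_metrics(self, synthetic_series, tn_prior, fast_mcmc):
        chain = sample_posterior(synthetic_series, tn_prior, fast_mcmc)
        m = fit_metrics(chain, synthetic_series)
        assert set(m) == {"mean", "q05", "q95"}
        assert all(set(v) == {"r_squared", "nse"} for v in m.values())
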