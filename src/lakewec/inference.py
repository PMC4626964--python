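"""Bayesian inverse estimation of the in-lake nutrient decay rate.

Given a multi-year record of loads, outflows and observed concentrations,
the decay rate ``S`` (1/a) and the observation noise ``sigma`` (t per
10^8 m^3) are estimated by MCMC.  The observation model treats each year's
measured concentration as the steady-state prediction plus independent
Gaussian error:

    C*_i = I_i / (V * (r_i + S)) + eps_i,     eps_i ~ N(0, sigma^2)

with a year-specific flushing rate r_i = Q_i / V and one common (S, sigma)
per nutrient.  The prior on S is uniform on a literature-derived interval;
the noise precision tau = 1/sigma^2 carries a vague Gamma prior, so tau is
conditionally conjugate and can be Gibbs-updated exactly.  S is updated by
random-walk Metropolis with a proposal scale adapted only during burn-in,
keeping the post-burn-in kernel fixed and the chain reproducible under a
fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import gammaln

from .model import NutrientSeries

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "Chain",
    "PosteriorSummary",
    "ConvergenceResult",
    "DegenerateChainError",
    "log_likelihood",
    "log_posterior",
    "sample_posterior",
    "summarize_posterior",
    "mc_error",
    "convergence_check",
    "fit_metrics",
]

LOG_2PI = float(np.log(2.0 * np.pi))


class DegenerateChainError(ValueError):
    """Raised when a chain carries no information (e.g. zero variance)."""


@dataclass(frozen=True)
class PriorSpec:
    """Priors for one nutrient: S ~ Uniform(s_low, s_high) in 1/a and
    precision tau = 1/sigma^2 ~ Gamma(shape, rate)."""

    s_low: float
    s_high: float
    sigma_prior_shape: float = 0.001
    sigma_prior_rate: float = 0.001

    def __post_init__(self) -> None:
        if not 0 <= self.s_low < self.s_high:
            raise ValueError(
                f"need 0 <= s_low < s_high, got [{self.s_low}, {self.s_high}]"
            )
        if not (self.sigma_prior_shape > 0 and self.sigma_prior_rate > 0):
            raise ValueError("Gamma hyperparameters must be positive")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.s_low + self.s_high)


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler controls.  Defaults: a single 50,000-iteration chain with
    the first 10,000 draws discarded, no thinning."""

    n_iterations: int = 50_000
    burn_in: int = 10_000
    thin: int = 1
    seed: int = 0
    target_acceptance: float = 0.4
    n_chains: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0 < self.target_acceptance < 1:
            raise ValueError("target_acceptance must lie in (0, 1)")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")


@dataclass(frozen=True)
class Chain:
    """Post-burn-in, thinned posterior draws of (S, sigma)."""

    s_draws: np.ndarray
    sigma_draws: np.ndarray
    acceptance_rate: float
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "s_draws", np.asarray(self.s_draws, dtype=float))
        object.__setattr__(self, "sigma_draws", np.asarray(self.sigma_draws, dtype=float))
        if self.s_draws.shape != self.sigma_draws.shape:
            raise ValueError("s_draws and sigma_draws must have equal length")
        if np.any(self.sigma_draws <= 0):
            raise ValueError("sigma draws must be positive")

    def __len__(self) -> int:
        return self.s_draws.size


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior mean, credible levels (5/25/75/95%), SD and Monte Carlo
    standard error of the mean for the decay rate."""

    q05: float
    q25: float
    mean: float
    q75: float
    q95: float
    sd: float
    mc_error: float

    def __post_init__(self) -> None:
        if not (self.q05 <= self.q25 <= self.q75 <= self.q95):
            raise ValueError("posterior quantiles must be ordered")
        if not (self.q25 <= self.mean <= self.q75):
            warnings.warn(
                "posterior mean falls outside the interquartile range; "
                "the posterior is strongly skewed or the chain is short",
                stacklevel=2,
            )

    def quantile_levels(self) -> dict[str, float]:
        """S at the table levels, in level order."""
        return {
            "q05": self.q05,
            "q25": self.q25,
            "mean": self.mean,
            "q75": self.q75,
            "q95": self.q95,
        }


@dataclass(frozen=True)
class ConvergenceResult:
    passed: bool
    ratio: float
    message: str = ""


def _residual_ss(decay: float, series: NutrientSeries) -> float:
    predicted = series.predicted_conc(decay)
    resid = series.observed_conc - predicted
    return float(resid @ resid)


def log_likelihood(decay: float, sigma: float, series: NutrientSeries) -> float:
    """Gaussian log-likelihood of the observed concentrations.

    Sum over years of the normal log-density of C*_i around the
    steady-state prediction at the common decay rate, common sigma.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if decay < 0:
        raise ValueError(f"decay rate must be non-negative, got {decay}")
    n = len(series)
    ss = _residual_ss(decay, series)
    return -0.5 * n * LOG_2PI - n * np.log(sigma) - ss / (2.0 * sigma**2)


def _log_prior_sigma(sigma: float, prior: PriorSpec) -> float:
    """Log-density of sigma induced by tau = sigma^-2 ~ Gamma(a, b).

    Includes the Jacobian |d tau / d sigma| = 2 sigma^-3.
    """
    a, b = prior.sigma_prior_shape, prior.sigma_prior_rate
    tau = sigma**-2
    log_gamma = a * np.log(b) - gammaln(a) + (a - 1.0) * np.log(tau) - b * tau
    return float(log_gamma + np.log(2.0) - 3.0 * np.log(sigma))


def log_posterior(
    decay: float, sigma: float, series: NutrientSeries, prior: PriorSpec
) -> float:
    """Unnormalised log-posterior of (S, sigma); -inf outside prior support."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if not (prior.s_low <= decay <= prior.s_high):
        return -np.inf
    loglik = log_likelihood(decay, sigma, series)
    log_prior_s = -np.log(prior.s_high - prior.s_low)
    return loglik + log_prior_s + _log_prior_sigma(sigma, prior)


def sample_posterior(
    series: NutrientSeries,
    prior: PriorSpec,
    config: MCMCConfig,
    prior_only: bool = False,
) -> Chain:
    """Metropolis-within-Gibbs sampler for (S, sigma).

    S moves by random-walk Metropolis restricted to the prior interval;
    tau = 1/sigma^2 is drawn exactly from its conjugate conditional
    Gamma(a + n/2, b + SS(S)/2) given the current residual sum of squares.
    The S proposal scale is tuned toward ``target_acceptance`` during
    burn-in only, so the stationary kernel is untouched.  With
    ``prior_only=True`` the likelihood is dropped and draws come directly
    from the prior (a sampler self-check).

    Identical (series, prior, config) gives a bit-identical chain.
    """
    rng = np.random.default_rng(config.seed)
    n_iter = config.n_iterations
    n = len(series)
    a_post = prior.sigma_prior_shape + 0.5 * n

    if prior_only:
        size = n_iter - config.burn_in
        s_draws = rng.uniform(prior.s_low, prior.s_high, size=size)
        tau = rng.gamma(prior.sigma_prior_shape, 1.0 / prior.sigma_prior_rate, size=size)
        sigma_draws = 1.0 / np.sqrt(tau)
        return Chain(
            s_draws[:: config.thin],
            sigma_draws[:: config.thin],
            acceptance_rate=1.0,
            meta={"prior_only": True, "config": config, "nutrient": series.nutrient},
        )

    # all randomness drawn up front: the loop is pure arithmetic
    steps = rng.standard_normal(n_iter)
    log_u = np.log(rng.random(n_iter))
    gamma_std = rng.gamma(a_post, 1.0, size=n_iter)

    loads = series.loads
    rates = series.hydraulic_rates
    obs = series.observed_conc
    volume = series.geometry.volume

    def residual_ss(decay: float) -> float:
        resid = obs - loads / (volume * (rates + decay))
        return float(resid @ resid)

    s_cur = prior.midpoint
    ss_cur = residual_ss(s_cur)
    if not np.isfinite(ss_cur):
        raise ValueError("non-finite likelihood at the prior midpoint; check the data")
    tau_cur = gamma_std[0] / (prior.sigma_prior_rate + 0.5 * ss_cur)

    scale = 0.1 * (prior.s_high - prior.s_low)
    adapt_window = 50
    accepted_window = 0
    accepted_post = 0

    s_out = np.empty(n_iter)
    sig_out = np.empty(n_iter)

    for i in range(n_iter):
        prop = s_cur + scale * steps[i]
        if prior.s_low <= prop <= prior.s_high:
            ss_prop = residual_ss(prop)
            # uniform prior on S cancels; tau = 1/sigma^2
            if log_u[i] < 0.5 * tau_cur * (ss_cur - ss_prop):
                s_cur = prop
                ss_cur = ss_prop
                accepted_window += 1
                if i >= config.burn_in:
                    accepted_post += 1
        tau_cur = gamma_std[i] / (prior.sigma_prior_rate + 0.5 * ss_cur)
        s_out[i] = s_cur
        sig_out[i] = tau_cur**-0.5

        if i < config.burn_in and (i + 1) % adapt_window == 0:
            rate = accepted_window / adapt_window
            scale *= float(np.exp(rate - config.target_acceptance))
            accepted_window = 0

    keep = slice(config.burn_in, None, config.thin)
    n_post = n_iter - config.burn_in
    return Chain(
        s_out[keep],
        sig_out[keep],
        acceptance_rate=accepted_post / n_post,
        meta={
            "config": config,
            "nutrient": series.nutrient,
            "proposal_scale": scale,
            "n_records": n,
        },
    )


def mc_error(draws: np.ndarray, n_batches: int = 50) -> float:
    """Batch-means Monte Carlo standard error of the chain mean.

    The chain is split into ``n_batches`` equal consecutive batches
    (truncating the oldest draws when the length is not divisible) and the
    error is sd(batch means) / sqrt(n_batches), which accounts for serial
    correlation at the batch scale.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size < n_batches:
        raise ValueError(f"need at least {n_batches} draws, got {draws.size}")
    batch_size = draws.size // n_batches
    trimmed = draws[draws.size - n_batches * batch_size :]
    means = trimmed.reshape(n_batches, batch_size).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


def summarize_posterior(chain: Chain | np.ndarray) -> PosteriorSummary:
    """Empirical mean, SD, 5/25/75/95% levels and MC error of the S draws.

    Quantiles use linear interpolation between order statistics.  A chain
    shorter than 100 draws or with zero variance is rejected.
    """
    draws = chain.s_draws if isinstance(chain, Chain) else np.asarray(chain, dtype=float)
    if draws.size < 100:
        raise ValueError(f"chain too short to summarise ({draws.size} < 100 draws)")
    sd = float(draws.std(ddof=1))
    if sd == 0:
        raise DegenerateChainError("degenerate chain: all draws identical")
    q05, q25, q75, q95 = np.percentile(draws, [5, 25, 75, 95])
    return PosteriorSummary(
        q05=float(q05),
        q25=float(q25),
        mean=float(draws.mean()),
        q75=float(q75),
        q95=float(q95),
        sd=sd,
        mc_error=mc_error(draws),
    )


def convergence_check(summary: PosteriorSummary, threshold: float = 0.08) -> ConvergenceResult:
    """Convergence rule: the MC error must stay below 8% of the posterior SD.

    Strict inequality; a zero-SD summary fails with a degenerate-chain
    message.
    """
    if summary.sd <= 0:
        return ConvergenceResult(False, np.inf, "degenerate chain: sd = 0")
    ratio = summary.mc_error / summary.sd
    passed = ratio < threshold
    msg = "" if passed else f"MC error is {100 * ratio:.1f}% of the SD (limit {100 * threshold:.0f}%)"
    return ConvergenceResult(passed, float(ratio), msg)


def _point_fit_metrics(decay: float, series: NutrientSeries) -> dict[str, float]:
    obs = series.observed_conc
    sim = series.predicted_conc(decay)
    if obs.std() == 0:
        raise ValueError("observed concentrations have zero variance; fit metrics undefined")
    r = np.corrcoef(obs, sim)[0, 1]
    nse = 1.0 - np.sum((obs - sim) ** 2) / np.sum((obs - obs.mean()) ** 2)
    return {"r_squared": float(r**2), "nse": float(nse)}


def fit_metrics(decay, series: NutrientSeries):
    """Goodness of fit of steady-state predictions against observations.

    R^2 is the squared Pearson correlation of observed vs simulated
    concentrations; the Nash-Sutcliffe efficiency is
    1 - SS(obs - sim)/SS(obs - mean(obs)).  A scalar ``decay`` yields one
    ``{"r_squared", "nse"}`` pair; a :class:`Chain` (or array of draws)
    yields metrics at the posterior mean and at the 5%/95% levels.
    """
    if isinstance(decay, Chain):
        decay = decay.s_draws
    if np.ndim(decay) == 0:
        return _point_fit_metrics(float(decay), series)
    draws = np.asarray(decay, dtype=float)
    q05, q95 = np.percentile(draws, [5, 95])
    return {
        "mean": _point_fit_metrics(float(draws.mean()), series),
        "q05": _point_fit_metrics(float(q05), series),
        "q95": _point_fit_metrics(float(q95), series),
    }
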