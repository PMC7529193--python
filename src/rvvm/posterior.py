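"""Conjugate Bayesian inference for a Bernoulli proportion from measure-valued data.

With a Beta(alpha, beta) prior and a sample of Bernoulli measures with
success probabilities theta_1..theta_n, the generalized posterior is a
mixture of Beta densities: conditional on the success count W = k the
posterior is Beta(alpha + k, beta + n - k), and the mixture weights are the
Poisson-binomial pmf of W.  The posterior mean is

    (alpha + E[W]) / (alpha + beta + n),

and the posterior variance follows from the law of total variance over W:

    E[Var(theta | W)] + Var(W) / (alpha + beta + n)^2.

For an all-point-mass sample the mixture collapses to the single classical
conjugate component, so ordinary Beta-Bernoulli updating is recovered exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats

from .counts import SuccessCountMeasure, sample_thetas, success_count_distribution
from .measures import ProtocolSample

__all__ = [
    "BetaPrior",
    "BetaMixturePosterior",
    "posterior_mixture",
    "bayes_estimate",
    "posterior_sd",
    "posterior_density",
    "credible_interval",
]


@dataclass(frozen=True)
class BetaPrior:
    """Beta(alpha, beta) prior on the population proportion."""

    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self):
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("Beta prior parameters must be positive")

    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class BetaMixturePosterior:
    """A count-weighted mixture of Beta(alpha+k, beta+n-k) components, k = 0..n."""

    prior: BetaPrior
    nu: SuccessCountMeasure

    @property
    def n(self) -> int:
        return self.nu.n

    @property
    def weights(self) -> np.ndarray:
        return self.nu.pmf

    def component_params(self) -> Tuple[np.ndarray, np.ndarray]:
        k = np.arange(self.n + 1, dtype=float)
        return self.prior.alpha + k, self.prior.beta + self.n - k

    def mean(self) -> float:
        """Posterior mean, computed from the count measure in closed form."""
        s = self.prior.alpha + self.prior.beta + self.n
        return (self.prior.alpha + self.nu.mean()) / s

    def mixture_mean(self) -> float:
        """Posterior mean via the component means — an independent route."""
        a, b = self.component_params()
        return float(np.dot(self.weights, a / (a + b)))

    def var(self) -> float:
        """Posterior variance via total variance over the success count."""
        a, b = self.component_params()
        s = a + b  # constant alpha+beta+n
        within = float(np.dot(self.weights, a * b / (s * s * (s + 1.0))))
        between = self.nu.var() / float(s[0]) ** 2
        return within + between

    def mixture_var(self) -> float:
        """Posterior variance directly from component second moments."""
        a, b = self.component_params()
        s = a + b
        second = a * (a + 1.0) / (s * (s + 1.0))
        return float(np.dot(self.weights, second)) - self.mixture_mean() ** 2

    def sd(self) -> float:
        return math.sqrt(self.var())

    def pdf(self, theta) -> np.ndarray:
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        if np.any((theta <= 0.0) | (theta >= 1.0)):
            raise ValueError("density grid values must lie strictly inside (0, 1)")
        a, b = self.component_params()
        dens = stats.beta.pdf(theta[:, None], a[None, :], b[None, :])
        return dens @ self.weights

    def cdf(self, theta: float) -> float:
        if theta <= 0.0:
            return 0.0
        if theta >= 1.0:
            return 1.0
        a, b = self.component_params()
        return float(np.dot(self.weights, stats.beta.cdf(theta, a, b)))

    def quantile(self, q: float) -> float:
        """Invert the mixture CDF by bisection (well below 1e-10 on either scale)."""
        if not (0.0 < q < 1.0):
            raise ValueError("quantile level must be in (0, 1)")
        lo, hi = 0.0, 1.0
        while hi - lo > 1e-14:
            mid = 0.5 * (lo + hi)
            if self.cdf(mid) < q:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw theta by first drawing the success count, then the Beta component."""
        k = self.nu.sample(rng, size=size)
        return rng.beta(self.prior.alpha + k, self.prior.beta + self.n - k)


def posterior_mixture(sample: ProtocolSample, prior: BetaPrior = BetaPrior()) -> BetaMixturePosterior:
    """Generalized posterior for a Bernoulli proportion from a measure-valued sample.

    Every record's measure must be supported on {0, 1}; an empty sample
    returns the prior as a single-component mixture.
    """
    thetas = sample_thetas(sample)
    return BetaMixturePosterior(prior=prior, nu=success_count_distribution(thetas))


def bayes_estimate(sample: ProtocolSample, prior: BetaPrior = BetaPrior()) -> float:
    """Posterior-mean estimate (alpha + E[W]) / (alpha + beta + n)."""
    return posterior_mixture(sample, prior).mean()


def posterior_sd(sample: ProtocolSample, prior: BetaPrior = BetaPrior()) -> float:
    """Posterior standard deviation via the total-variance decomposition."""
    return posterior_mixture(sample, prior).sd()


def posterior_density(post: BetaMixturePosterior, theta_grid: Sequence[float]) -> np.ndarray:
    """Pointwise mixture density on a grid strictly inside (0, 1)."""
    return post.pdf(np.asarray(theta_grid, dtype=float))


def credible_interval(post: BetaMixturePosterior, level: float = 0.95) -> Tuple[float, float]:
    """Equal-tailed credible interval by numerical CDF inversion."""
    if not (0.0 < level < 1.0):
        raise ValueError("credible level must be in (0, 1)")
    tail = 0.5 * (1.0 - level)
    return post.quantile(tail), post.quantile(1.0 - tail)
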