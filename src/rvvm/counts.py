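"""Success-count aggregation for Bernoulli-valued measurements.

For a binary trait measured with per-unit confidences ``theta_1..theta_n``,
the total number of successes W across the sample follows the Poisson-binomial
distribution — the convolution of the n heterogeneous Bernoulli measures.
That count measure ``nu`` is what drives the conjugate posterior for the
population proportion.  The module also provides the generalized sample mean
(average of per-record measure expectations) and its sum analogue used as a
rating-scale total score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .measures import DiscreteMeasure, ProtocolSample

__all__ = [
    "SuccessCountMeasure",
    "success_count_distribution",
    "count_mean_var",
    "bernoulli_theta",
    "sample_thetas",
    "generalized_mean",
    "generalized_sum",
]


@dataclass(frozen=True)
class SuccessCountMeasure:
    """Distribution of the success count W over 0..n (Poisson-binomial)."""

    n: int
    pmf: np.ndarray

    def __post_init__(self):
        pmf = np.asarray(self.pmf, dtype=float)
        if pmf.shape != (self.n + 1,):
            raise ValueError(f"pmf must have length n+1={self.n + 1}")
        if np.any(pmf < -1e-15):
            raise ValueError("pmf entries must be nonnegative")
        if abs(pmf.sum() - 1.0) > 1e-10:
            raise ValueError(f"pmf sums to {pmf.sum()}, not 1")
        object.__setattr__(self, "pmf", np.clip(pmf, 0.0, None))

    def mean(self) -> float:
        return float(np.dot(np.arange(self.n + 1), self.pmf))

    def var(self) -> float:
        k = np.arange(self.n + 1)
        m = self.mean()
        return max(0.0, float(np.dot(k * k, self.pmf)) - m * m)

    def sample(self, rng: np.random.Generator, size=None):
        return rng.choice(self.n + 1, size=size, p=self.pmf)


def success_count_distribution(thetas: Sequence[float]) -> SuccessCountMeasure:
    """Exact Poisson-binomial pmf by iterative convolution.

    O(n^2) dynamic programming, exact to floating precision; entirely adequate
    at desk scale (n up to ~10^4).  n = 0 yields the point mass at 0.
    """
    thetas = [float(t) for t in thetas]
    for t in thetas:
        if not (0.0 <= t <= 1.0):
            raise ValueError(f"success probability {t!r} outside [0, 1]")
    n = len(thetas)
    pmf = np.zeros(n + 1)
    pmf[0] = 1.0
    for i, t in enumerate(thetas):
        # after i+1 coins, only entries 0..i+1 can be charged
        pmf[1 : i + 2] = pmf[1 : i + 2] * (1.0 - t) + pmf[: i + 1] * t
        pmf[0] *= 1.0 - t
    return SuccessCountMeasure(n=n, pmf=pmf)


def count_mean_var(nu: SuccessCountMeasure) -> Tuple[float, float]:
    """Mean and variance of the success count, from its exact pmf."""
    return nu.mean(), nu.var()


def bernoulli_theta(m: DiscreteMeasure) -> float:
    """Success probability of a measure supported on {0, 1} (or a subset)."""
    if not set(m.support) <= {0.0, 1.0}:
        raise ValueError(
            f"measure with support {m.support} is not Bernoulli-valued; "
            "a binary trait admits mass only on {0, 1}"
        )
    return m.prob_of(1.0)


def sample_thetas(sample: ProtocolSample) -> list:
    """Per-record success probabilities of a Bernoulli-valued sample."""
    return [bernoulli_theta(r.measure) for r in sample.records]


def generalized_mean(sample: ProtocolSample) -> float:
    """Mean of per-record measure expectations.

    The measure-valued analogue of the sample mean; for an all-point-mass
    sample it reduces to the ordinary arithmetic mean, and for a calibrated
    protocol it is unbiased and consistent for E(Y).
    """
    if sample.n == 0:
        raise ValueError("generalized mean of an empty sample is undefined")
    return float(np.mean([r.measure.mean() for r in sample.records]))


def generalized_sum(sample: ProtocolSample) -> float:
    """n times the generalized mean: the measure-valued total score."""
    if sample.n == 0:
        raise ValueError("generalized sum of an empty sample is undefined")
    return sample.n * generalized_mean(sample)
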