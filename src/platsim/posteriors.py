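"""Conjugate posterior models and the decision probabilities built on them.

Binary outcomes use a beta-binomial model (beta prior, binomial likelihood).
Continuous outcomes use a conjugate Gaussian model for the arm *mean* with a
plug-in outcome standard deviation: the pooled sample SD of all observations
seen so far, falling back to a user-supplied planning SD while fewer than two
observations are available.  Keeping the outcome SD as a plug-in keeps the
posterior of the mean Gaussian, so every decision probability reduces to
fast sampling (or a closed form for two Gaussian arms).

All Monte Carlo routines take an injected :class:`numpy.random.Generator`;
nothing in this module owns a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence, Union

import numpy as np
from scipy import integrate, stats

#: Benefit-direction flags used across the package.
HIGHER_BETTER = "higher-better"
LOWER_BETTER = "lower-better"
_DIRECTIONS = (HIGHER_BETTER, LOWER_BETTER)

#: Effect scales accepted by :func:`prob_effect_below_margin`.
RELATIVE_RISK_REDUCTION = "relative-risk-reduction"
MEAN_DIFFERENCE = "mean-difference"


def _check_direction(direction: str) -> None:
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}, got {direction!r}")


@dataclass(frozen=True)
class BinaryPosterior:
    """Beta posterior for a response probability.

    Parameters
    ----------
    alpha
        Pseudo-count of responses (must be > 0).
    beta
        Pseudo-count of non-responses (must be > 0).
    """

    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(
                f"beta posterior requires alpha > 0 and beta > 0, "
                f"got ({self.alpha}, {self.beta})"
            )

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def sd(self) -> float:
        a, b = self.alpha, self.beta
        return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))

    def sample(self, draws: int, rng: np.random.Generator) -> np.ndarray:
        return rng.beta(self.alpha, self.beta, size=draws)


@dataclass(frozen=True)
class ContinuousPosterior:
    """Gaussian posterior for an arm mean with plug-in outcome SD.

    The state carries the prior plus sufficient statistics of every
    observation seen, so updating with a concatenation of batches is
    identical to sequential updates (the plug-in SD is always recomputed
    from the full pooled sample).

    Attributes
    ----------
    prior_mean, prior_scale
        Gaussian prior on the arm mean (outcome units).
    planning_sd
        Outcome SD used until >= 2 observations allow estimating it.
    n, sum_x, sum_sq
        Count, sum and sum of squares of all observations.
    """

    prior_mean: float = 0.0
    prior_scale: float = 1000.0
    planning_sd: float = 1.0
    n: int = 0
    sum_x: float = 0.0
    sum_sq: float = 0.0

    def __post_init__(self) -> None:
        if self.prior_scale <= 0:
            raise ValueError("prior_scale must be positive")
        if self.planning_sd <= 0:
            raise ValueError("planning_sd must be positive")
        if self.n < 0:
            raise ValueError("n must be non-negative")

    @property
    def sigma_hat(self) -> float:
        """Plug-in outcome SD: pooled sample SD once n >= 2, else planning SD."""
        if self.n >= 2:
            var = (self.sum_sq - self.sum_x**2 / self.n) / (self.n - 1)
            if var > 1e-24:
                return math.sqrt(var)
        return self.planning_sd

    @property
    def mean(self) -> float:
        if self.n == 0:
            return self.prior_mean
        tau0 = self.prior_scale**-2
        tau_d = self.n / self.sigma_hat**2
        return (tau0 * self.prior_mean + tau_d * (self.sum_x / self.n)) / (tau0 + tau_d)

    @property
    def scale(self) -> float:
        """Posterior SD of the arm mean."""
        return (self.prior_scale**-2 + self.n / self.sigma_hat**2) ** -0.5

    def sample(self, draws: int, rng: np.random.Generator) -> np.ndarray:
        return rng.normal(self.mean, self.scale, size=draws)


Posterior = Union[BinaryPosterior, ContinuousPosterior]


@dataclass(frozen=True)
class SuperiorityVector:
    """Per-arm posterior probabilities of being the best active arm."""

    probs: tuple

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or p.size < 1:
            raise ValueError("probs must be a non-empty 1-D sequence")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("superiority probabilities must lie in [0, 1]")
        object.__setattr__(self, "probs", tuple(float(x) for x in p))

    def __len__(self) -> int:
        return len(self.probs)


def update_binary(prior: BinaryPosterior, responses: int, failures: int) -> BinaryPosterior:
    """Conjugate beta-binomial update: add observed counts to the pseudo-counts."""
    if responses < 0 or failures < 0:
        raise ValueError(
            f"counts must be non-negative, got responses={responses}, failures={failures}"
        )
    return BinaryPosterior(prior.alpha + responses, prior.beta + failures)


def update_continuous(
    prior: ContinuousPosterior, observations: Sequence[float]
) -> ContinuousPosterior:
    """Fold a batch of observations into the sufficient statistics.

    Batched and sequential updates commute because the posterior is always
    recomputed from the accumulated (n, sum, sum of squares).
    """
    obs = np.asarray(observations, dtype=float)
    if obs.size == 0:
        return prior
    if not np.all(np.isfinite(obs)):
        raise ValueError("observations must be finite")
    return replace(
        prior,
        n=prior.n + int(obs.size),
        sum_x=prior.sum_x + float(obs.sum()),
        sum_sq=prior.sum_sq + float((obs**2).sum()),
    )


def prob_superior_each(
    posteriors: Sequence[Posterior],
    direction: str = HIGHER_BETTER,
    draws: int = 10_000,
    rng: np.random.Generator = None,
) -> SuperiorityVector:
    """Monte Carlo probability that each arm's parameter is the best of all.

    Draws each arm's parameter ``draws`` times and counts, per arm, the
    fraction of joint draws where it is strictly best in the stated
    direction.  Ties (measure zero for the continuous posteriors used here)
    break to the lowest arm index.
    """
    if len(posteriors) < 2:
        raise ValueError("at least two posteriors are required")
    if draws < 1:
        raise ValueError("draws must be >= 1")
    _check_direction(direction)
    if rng is None:
        raise ValueError("an explicit numpy Generator must be supplied")
    samples = np.stack([p.sample(draws, rng) for p in posteriors])
    if direction == HIGHER_BETTER:
        best = np.argmax(samples, axis=0)
    else:
        best = np.argmin(samples, axis=0)
    counts = np.bincount(best, minlength=len(posteriors))
    return SuperiorityVector(tuple(counts / draws))


def prob_superior_pair_closed_form(
    a: Posterior, b: Posterior, direction: str = HIGHER_BETTER
) -> float:
    """Closed-form / numerically integrated P(a better than b).

    For two Gaussian posteriors this is Phi((mean_a - mean_b) /
    sqrt(scale_a^2 + scale_b^2)); for two beta posteriors P(p_a > p_b) is
    computed by numerical integration of pdf_a * cdf_b.  Serves as an
    independent oracle for the Monte Carlo path on two arms.
    """
    _check_direction(direction)
    if isinstance(a, BinaryPosterior) and isinstance(b, BinaryPosterior):
        da = stats.beta(a.alpha, a.beta)
        db = stats.beta(b.alpha, b.beta)
        p, _ = integrate.quad(lambda x: da.pdf(x) * db.cdf(x), 0.0, 1.0, limit=200)
        p = min(max(p, 0.0), 1.0)
    elif isinstance(a, ContinuousPosterior) and isinstance(b, ContinuousPosterior):
        p = float(stats.norm.cdf((a.mean - b.mean) / math.hypot(a.scale, b.scale)))
    else:
        raise ValueError("both posteriors must share the same outcome type")
    return p if direction == HIGHER_BETTER else 1.0 - p


def prob_effect_below_margin(
    treat: Posterior,
    control: Posterior,
    margin: float,
    effect_scale: str = RELATIVE_RISK_REDUCTION,
    draws: int = 10_000,
    rng: np.random.Generator = None,
    direction: str = HIGHER_BETTER,
) -> float:
    """Monte Carlo P(treatment-vs-control effect < margin).

    The effect is the relative risk reduction ``1 - p_treat / p_control``
    (harmful-event convention; binary outcomes only) or the mean difference
    taken in the benefit direction.  A high value is evidence the effect is
    smaller than the minimally important margin, i.e. grounds for futility.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    if draws < 1:
        raise ValueError("draws must be >= 1")
    if rng is None:
        raise ValueError("an explicit numpy Generator must be supplied")
    if effect_scale == RELATIVE_RISK_REDUCTION:
        if not (isinstance(treat, BinaryPosterior) and isinstance(control, BinaryPosterior)):
            raise ValueError("relative-risk-reduction requires binary posteriors")
        p_t = treat.sample(draws, rng)
        p_c = control.sample(draws, rng)
        effect = 1.0 - p_t / p_c
    elif effect_scale == MEAN_DIFFERENCE:
        _check_direction(direction)
        x_t = treat.sample(draws, rng)
        x_c = control.sample(draws, rng)
        effect = x_t - x_c if direction == HIGHER_BETTER else x_c - x_t
    else:
        raise ValueError(f"unknown effect scale {effect_scale!r}")
    return float(np.mean(effect < margin))
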