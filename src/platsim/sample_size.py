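"""Conventional fixed-design sample-size calculator.

Normal-approximation two-sample formulas (two-sided alpha, unpooled
variance for proportions), with a multi-arm path that sizes the trial to
detect the difference between the largest and second-largest planning
effect, optionally Bonferroni-adjusted over the treatment-vs-reference
comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, NamedTuple, Optional, Sequence

from scipy import stats

BONFERRONI = "bonferroni"
NONE = "none"


class GroupSizes(NamedTuple):
    n1: int
    n2: int

    @property
    def total(self) -> int:
        return self.n1 + self.n2


def _check_alpha_power(alpha: float, power: float) -> None:
    if not (0.0 < alpha <= 0.5):
        raise ValueError(f"alpha must lie in (0, 0.5], got {alpha}")
    if not (0.0 < power < 1.0):
        raise ValueError(f"power must lie in (0, 1), got {power}")
    if power <= alpha / 2:
        raise ValueError("requested power must exceed alpha/2 (degenerate request)")


def power_continuous(
    n1: int, delta: float, sd: float, alpha: float = 0.05, ratio: float = 1.0
) -> float:
    """Normal-approximation power of a two-sample mean comparison at n1 per
    reference group (n2 = ratio * n1)."""
    n2 = ratio * n1
    se = sd * math.sqrt(1.0 / n1 + 1.0 / n2)
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.cdf(abs(delta) / se - z_a))


def power_binary(
    n1: int, p1: float, p2: float, alpha: float = 0.05, ratio: float = 1.0
) -> float:
    """Normal-approximation (unpooled) power of a two-sample proportion
    comparison at n1 per reference group."""
    n2 = ratio * n1
    se = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.cdf(abs(p1 - p2) / se - z_a))


def sample_size_continuous(
    delta: float,
    sd: float,
    alpha: float = 0.05,
    power: float = 0.80,
    ratio: float = 1.0,
) -> GroupSizes:
    """Per-group n for detecting a mean difference ``delta`` at planning SD.

    n1 = (z_{1-alpha/2} + z_power)^2 (1 + 1/ratio) (sd/delta)^2, ceiled.
    """
    if delta == 0:
        raise ValueError("delta must be non-zero")
    if sd <= 0:
        raise ValueError("sd must be positive")
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    _check_alpha_power(alpha, power)
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(power)
    n1 = (z_a + z_b) ** 2 * (1.0 + 1.0 / ratio) * (sd / delta) ** 2
    n1 = int(math.ceil(n1 - 1e-12))
    return GroupSizes(n1, int(math.ceil(ratio * n1 - 1e-12)))


def sample_size_binary(
    p1: float,
    p2: float,
    alpha: float = 0.05,
    power: float = 0.80,
    ratio: float = 1.0,
) -> GroupSizes:
    """Per-group n for detecting p1 vs p2 (unpooled normal approximation)."""
    for p in (p1, p2):
        if not (0.0 < p < 1.0):
            raise ValueError(f"proportions must lie in (0, 1), got {p}")
    if p1 == p2:
        raise ValueError("p1 must differ from p2")
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    _check_alpha_power(alpha, power)
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(power)
    var = p1 * (1 - p1) + p2 * (1 - p2) / ratio
    n1 = (z_a + z_b) ** 2 * var / (p1 - p2) ** 2
    n1 = int(math.ceil(n1 - 1e-12))
    return GroupSizes(n1, int(math.ceil(ratio * n1 - 1e-12)))


@dataclass
class SampleSizeRequest:
    """Planning inputs for a (possibly multi-arm) conventional trial."""

    outcome_type: str  # "binary" or "continuous"
    effects: List[float] = field(default_factory=list)  # per-arm proportions or means
    sd: Optional[float] = None  # planning SD (continuous only)
    alpha: float = 0.05
    power: float = 0.80
    ratio: float = 1.0
    multiplicity: str = NONE

    def __post_init__(self) -> None:
        if self.outcome_type not in ("binary", "continuous"):
            raise ValueError(f"unknown outcome_type {self.outcome_type!r}")
        if len(self.effects) < 2:
            raise ValueError("at least two per-arm planning effects are required")
        if self.outcome_type == "continuous" and (self.sd is None or self.sd <= 0):
            raise ValueError("continuous requests need a positive planning sd")
        if self.multiplicity not in (NONE, BONFERRONI):
            raise ValueError(f"unknown multiplicity method {self.multiplicity!r}")

    @property
    def n_arms(self) -> int:
        return len(self.effects)


@dataclass
class MultiArmResult:
    n_per_group: int
    total: int
    working_alpha: float
    multiplicity: str
    pair: tuple  # (largest, second-largest) planning effects used

    def to_dict(self) -> dict:
        return {
            "n_per_group": self.n_per_group,
            "total": self.total,
            "working_alpha": self.working_alpha,
            "multiplicity": self.multiplicity,
            "pair": list(self.pair),
        }


def sample_size_multiarm(request: SampleSizeRequest) -> MultiArmResult:
    """Multi-arm sample size from the top-two planning effects.

    The pairwise calculation uses the largest and second-largest effect at
    working alpha = alpha (no adjustment) or alpha / (n_arms - 1)
    (Bonferroni over treatment-vs-reference comparisons); total is n per
    group times the number of arms.
    """
    effects = sorted(request.effects, reverse=True)
    largest, second = effects[0], effects[1]
    if largest == second:
        raise ValueError(
            "largest and second-largest planning effects tie: zero detectable difference"
        )
    k = request.n_arms
    working_alpha = request.alpha if request.multiplicity == NONE else request.alpha / (k - 1)
    if request.outcome_type == "binary":
        sizes = sample_size_binary(
            largest, second, alpha=working_alpha, power=request.power, ratio=request.ratio
        )
    else:
        sizes = sample_size_continuous(
            largest - second,
            request.sd,
            alpha=working_alpha,
            power=request.power,
            ratio=request.ratio,
        )
    return MultiArmResult(
        n_per_group=sizes.n1,
        total=sizes.n1 * k,
        working_alpha=working_alpha,
        multiplicity=request.multiplicity,
        pair=(largest, second),
    )
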