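"""Monte-Carlo operating characteristics of a design vs the fixed comparator.

Replicate i of a run with master seed s uses the generator seeded by
``SeedSequence(s, spawn_key=(stream, i))`` (stream 0 for the adaptive
design, 1 for the conventional comparator), so increasing ``n_sims`` never
reshuffles earlier replicates and the two designs see paired seed streams.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .trial_engine import (
    ArmSpec,
    DesignRules,
    TrialResult,
    simulate_conventional,
    simulate_trial,
)

logger = logging.getLogger(__name__)

N_HIST_BINS = 20


def replicate_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    """Child generator for one replicate, stable under n_sims changes."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream, index)))


@dataclass
class MetricSummary:
    """Distribution summary of one per-trial metric."""

    mean: float
    median: float
    quantiles: Dict[str, float]
    hist_counts: List[int]
    hist_edges: List[float]

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "MetricSummary":
        x = np.asarray(values, dtype=float)
        qs = (0.05, 0.25, 0.75, 0.95)
        counts, edges = np.histogram(x, bins=N_HIST_BINS)
        return cls(
            mean=float(x.mean()),
            median=float(np.median(x)),
            quantiles={f"q{int(q * 100):02d}": float(np.quantile(x, q)) for q in qs},
            hist_counts=[int(c) for c in counts],
            hist_edges=[float(e) for e in edges],
        )

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "median": self.median,
            "quantiles": dict(self.quantiles),
            "hist_counts": list(self.hist_counts),
            "hist_edges": list(self.hist_edges),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetricSummary":
        return cls(
            mean=d["mean"],
            median=d["median"],
            quantiles=dict(d["quantiles"]),
            hist_counts=list(d["hist_counts"]),
            hist_edges=list(d["hist_edges"]),
        )


@dataclass
class DesignSummary:
    """Operating characteristics over n_sims simulated trials."""

    n_sims: int
    prob_winner_declared: float
    per_arm_win: Dict[str, float]
    sample_size: MetricSummary
    cost: MetricSummary
    duration: MetricSummary
    stop_reasons: Dict[str, float] = field(default_factory=dict)
    conventional: Optional["DesignSummary"] = None

    @property
    def winner_se(self) -> float:
        p = self.prob_winner_declared
        return float(np.sqrt(p * (1.0 - p) / self.n_sims))

    def to_dict(self) -> dict:
        d = {
            "n_sims": self.n_sims,
            "prob_winner_declared": self.prob_winner_declared,
            "per_arm_win": dict(self.per_arm_win),
            "sample_size": self.sample_size.to_dict(),
            "cost": self.cost.to_dict(),
            "duration": self.duration.to_dict(),
            "stop_reasons": dict(self.stop_reasons),
        }
        if self.conventional is not None:
            d["conventional"] = self.conventional.to_dict()
        return d

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSummary":
        conv = d.get("conventional")
        return cls(
            n_sims=d["n_sims"],
            prob_winner_declared=d["prob_winner_declared"],
            per_arm_win=dict(d["per_arm_win"]),
            sample_size=MetricSummary.from_dict(d["sample_size"]),
            cost=MetricSummary.from_dict(d["cost"]),
            duration=MetricSummary.from_dict(d["duration"]),
            stop_reasons=dict(d.get("stop_reasons", {})),
            conventional=cls.from_dict(conv) if conv else None,
        )


def _aggregate(results: Sequence[TrialResult], arm_names: Sequence[str]) -> DesignSummary:
    n = len(results)
    winners = [r.winner for r in results]
    per_arm = {name: sum(w == name for w in winners) / n for name in arm_names}
    reasons: Dict[str, float] = {}
    for r in results:
        reasons[r.stop_reason] = reasons.get(r.stop_reason, 0.0) + 1.0 / n
    return DesignSummary(
        n_sims=n,
        prob_winner_declared=sum(w is not None for w in winners) / n,
        per_arm_win=per_arm,
        sample_size=MetricSummary.from_values([r.total_n for r in results]),
        cost=MetricSummary.from_values([r.total_cost for r in results]),
        duration=MetricSummary.from_values([r.duration for r in results]),
        stop_reasons=reasons,
    )


def evaluate_design(
    arms: Sequence[ArmSpec],
    rules: DesignRules,
    n_sims: Optional[int] = None,
    time_budget: Optional[float] = None,
    seed: int = 0,
    include_conventional: bool = True,
    keep_results: bool = False,
    progress_every: int = 0,
):
    """Estimate a design's operating characteristics over seeded replicates.

    Exactly one of ``n_sims`` / ``time_budget`` (seconds) bounds the run; in
    time-budget mode the wall clock is checked between replicates only, so
    every counted replicate is complete, and the realized n_sims is
    recorded in the summary.  Returns the :class:`DesignSummary` (with raw
    results attached as a second return value when ``keep_results``).
    """
    if n_sims is None and time_budget is None:
        raise ValueError("one of n_sims or time_budget is required")
    if n_sims is not None and n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if time_budget is not None and time_budget <= 0:
        raise ValueError("time_budget must be positive")
    logger.info("evaluate_design: master seed %d", seed)
    results: List[TrialResult] = []
    conv_results: List[TrialResult] = []
    t0 = time.monotonic()
    i = 0
    while True:
        if n_sims is not None and i >= n_sims:
            break
        if n_sims is None and time_budget is not None and time.monotonic() - t0 >= time_budget:
            break
        results.append(simulate_trial(arms, rules, replicate_rng(seed, 0, i)))
        if include_conventional:
            conv_results.append(simulate_conventional(arms, rules, replicate_rng(seed, 1, i)))
        i += 1
        if progress_every and i % progress_every == 0:
            logger.info("evaluate_design: %d replicates done", i)
    if not results:
        raise RuntimeError("time budget elapsed before any replicate completed")
    names = [a.name for a in arms]
    summary = _aggregate(results, names)
    if include_conventional:
        summary.conventional = _aggregate(conv_results, names)
    logger.info("evaluate_design: realized n_sims=%d", summary.n_sims)
    if keep_results:
        return summary, results
    return summary


@dataclass
class ErrorRates:
    """Type I error / power pair with Monte Carlo standard errors."""

    type_i: float
    type_i_se: float
    power: float
    power_se: float
    null_summary: DesignSummary
    alt_summary: DesignSummary


def _best_arm_names(arms: Sequence[ArmSpec], higher_better: bool) -> List[str]:
    params = [a.true_param for a in arms]
    best = max(params) if higher_better else min(params)
    return [a.name for a in arms if a.true_param == best]


def error_rate_pair(
    null_arms: Sequence[ArmSpec],
    alt_arms: Sequence[ArmSpec],
    rules: DesignRules,
    n_sims: int,
    seed: int = 0,
) -> ErrorRates:
    """Estimate (type I error, power) for one design.

    Type I error is the fraction of null-configuration trials that ever
    declare a winner; power is the fraction of alternative-configuration
    trials declaring one of the truly best arms the winner (when all true
    params tie, every arm is "best" and power degenerates to the
    winner-declared fraction, i.e. the type I error).
    """
    null_params = {a.true_param for a in null_arms}
    if len(null_params) != 1:
        raise ValueError("null configuration must have identical true params on every arm")
    null_summary = evaluate_design(null_arms, rules, n_sims=n_sims, seed=seed)
    alt_summary = evaluate_design(alt_arms, rules, n_sims=n_sims, seed=seed)
    type_i = null_summary.prob_winner_declared
    best = _best_arm_names(alt_arms, rules.higher_better)
    power = sum(alt_summary.per_arm_win[name] for name in best)
    return ErrorRates(
        type_i=type_i,
        type_i_se=float(np.sqrt(type_i * (1 - type_i) / n_sims)),
        power=power,
        power_se=float(np.sqrt(power * (1 - power) / n_sims)),
        null_summary=null_summary,
        alt_summary=alt_summary,
    )


def summarize_to_table(
    summaries: Sequence[DesignSummary], labels: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Flatten design summaries into a one-row-per-design comparison table."""
    if len(summaries) < 1:
        raise ValueError("at least one summary is required")
    if labels is None:
        labels = [f"design_{i}" for i in range(len(summaries))]
    rows = []
    for label, s in zip(labels, summaries):
        row = {
            "design": label,
            "n_sims": s.n_sims,
            "prob_winner_declared": s.prob_winner_declared,
            "mean_n": s.sample_size.mean,
            "median_n": s.sample_size.median,
            "mean_cost": s.cost.mean,
            "median_cost": s.cost.median,
            "mean_duration": s.duration.mean,
        }
        for name, p in s.per_arm_win.items():
            row[f"win[{name}]"] = p
        if s.conventional is not None:
            c = s.conventional
            row.update(
                {
                    "conv_prob_winner_declared": c.prob_winner_declared,
                    "conv_mean_n": c.sample_size.mean,
                    "conv_mean_cost": c.cost.mean,
                    "conv_mean_duration": c.duration.mean,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def plot_comparison(summary: DesignSummary, path: str) -> None:
    """Bar chart comparing winner rate / mean cost vs the conventional design."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
    conv = summary.conventional
    labels = ["adaptive"] + (["conventional"] if conv else [])
    axes[0].bar(labels, [summary.prob_winner_declared] + ([conv.prob_winner_declared] if conv else []))
    axes[0].set_ylabel("P(winner declared)")
    axes[1].bar(labels, [summary.cost.mean] + ([conv.cost.mean] if conv else []))
    axes[1].set_ylabel("mean cost")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_sample_size_hist(summary: DesignSummary, path: str) -> None:
    """Histogram of the adaptive design's final sample size."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ms = summary.sample_size
    fig, ax = plt.subplots(figsize=(5, 3.5))
    edges = np.asarray(ms.hist_edges)
    ax.bar(edges[:-1], ms.hist_counts, width=np.diff(edges), align="edge")
    ax.set_xlabel("sample size at termination")
    ax.set_ylabel("trials")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
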