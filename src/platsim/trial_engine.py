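"""Single-trial simulation: accrual, adherence dilution, interim decisions,
arm dropping/addition, stopping, and cost/time accounting.

One trial is driven by four independent child RNG streams spawned from the
caller's generator — outcomes, allocation, decision Monte Carlo, and
secondary-outcome draws — so that decision-side randomness never perturbs
the accrual trajectory.  This makes e.g. raising the superiority threshold
(all else fixed) replay the identical outcome stream, only stopping later.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import allocation, posteriors
from .posteriors import (
    HIGHER_BETTER,
    LOWER_BETTER,
    MEAN_DIFFERENCE,
    RELATIVE_RISK_REDUCTION,
    BinaryPosterior,
    ContinuousPosterior,
    Posterior,
    prob_effect_below_margin,
    prob_superior_each,
    update_binary,
    update_continuous,
)

BINARY = "binary"
CONTINUOUS = "continuous"

ALL_ARMS = "all-arms"
VS_CONTROL = "vs-control"

STOP_SUPERIORITY = "superiority"
STOP_FUTILITY_ALL = "futility-all"
STOP_MAX_N = "max-n"
STOP_PERPETUAL = "perpetual-censored"


@dataclass
class ArmSpec:
    """Ground truth for one arm.

    ``available_from`` > 0 places the arm in the platform queue: it only
    enters when an adaptation rule admits it and at least that many patients
    have accrued.
    """

    name: str
    true_param: float
    role: str = "treatment"
    true_sd: Optional[float] = None
    adherence: float = 1.0
    available_from: int = 0
    secondary_param: Optional[float] = None
    secondary_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.role not in ("control", "treatment"):
            raise ValueError(f"role must be 'control' or 'treatment', got {self.role!r}")
        if not (0.0 <= self.adherence <= 1.0):
            raise ValueError(f"adherence must lie in [0, 1], got {self.adherence}")
        if self.available_from < 0:
            raise ValueError("available_from must be non-negative")


@dataclass
class DesignRules:
    """All thresholds, schedules and switches defining the adaptive design."""

    max_n: int
    n_looks: int = 10
    superiority_threshold: float = 0.99
    futility_threshold: float = 0.01
    mcid_margin: Optional[float] = None
    mcid_certainty: float = 0.95
    burn_in: int = 0
    rar_enabled: bool = False
    protect_control: bool = False
    platform_enabled: bool = False
    perpetual: bool = False
    comparison_mode: str = ALL_ARMS
    cost_per_patient: float = 1.0
    accrual_rate: float = 1.0
    outcome_type: str = BINARY
    higher_better: bool = True
    planning_sd: float = 1.0
    secondary_type: Optional[str] = None
    secondary_planning_sd: float = 1.0
    decision_draws: int = 10_000
    rar_draws: int = 1_000
    max_active_arms: Optional[int] = None
    new_arm_burn_in: int = 0
    perpetual_cap_factor: float = 5.0

    def __post_init__(self) -> None:
        if self.max_n < 2:
            raise ValueError("max_n must be >= 2")
        if self.n_looks < 1:
            raise ValueError("n_looks must be >= 1")
        if not (0.5 < self.superiority_threshold <= 1.0):
            raise ValueError("superiority_threshold must lie in (0.5, 1]")
        if not (0.0 <= self.futility_threshold < 0.5):
            raise ValueError("futility_threshold must lie in [0, 0.5)")
        if self.mcid_margin is not None and self.mcid_margin < 0:
            raise ValueError("mcid_margin must be non-negative")
        if not (0.5 < self.mcid_certainty <= 1.0):
            raise ValueError("mcid_certainty must lie in (0.5, 1]")
        if not (0 <= self.burn_in <= self.max_n):
            raise ValueError("burn_in must lie in [0, max_n]")
        if self.comparison_mode not in (ALL_ARMS, VS_CONTROL):
            raise ValueError(f"unknown comparison_mode {self.comparison_mode!r}")
        if self.outcome_type not in (BINARY, CONTINUOUS):
            raise ValueError(f"unknown outcome_type {self.outcome_type!r}")
        if self.accrual_rate <= 0:
            raise ValueError("accrual_rate must be positive")
        if self.cost_per_patient < 0:
            raise ValueError("cost_per_patient must be non-negative")

    @property
    def direction(self) -> str:
        return HIGHER_BETTER if self.higher_better else LOWER_BETTER

    @property
    def effect_scale(self) -> str:
        return RELATIVE_RISK_REDUCTION if self.outcome_type == BINARY else MEAN_DIFFERENCE


def look_schedule(max_n: int, n_looks: int) -> List[int]:
    """Interim looks at equal increments of accumulated sample size."""
    looks = sorted({min(math.ceil(j * max_n / n_looks), max_n) for j in range(1, n_looks + 1)})
    return looks


@dataclass
class LookRecord:
    look: int
    n_total: int
    probs: Dict[str, Optional[float]]
    actions: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "look": self.look,
            "n_total": self.n_total,
            "probs": dict(self.probs),
            "actions": list(self.actions),
        }


@dataclass
class ArmResult:
    name: str
    role: str
    enrolled: int
    outcome_sum: float
    outcome_mean: Optional[float]
    posterior_mean: float
    posterior_sd: float
    entered_at: int
    dropped_at: Optional[int] = None
    drop_reason: Optional[str] = None
    secondary_n: Optional[int] = None
    secondary_posterior_mean: Optional[float] = None
    secondary_posterior_sd: Optional[float] = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class TrialResult:
    """Full record of one simulated trial."""

    stop_reason: str
    winner: Optional[str]
    total_n: int
    total_cost: float
    duration: float
    arms: List[ArmResult]
    decision_log: List[LookRecord]

    @property
    def enrolled(self) -> Dict[str, int]:
        return {a.name: a.enrolled for a in self.arms}

    @property
    def final_estimates(self) -> Dict[str, Dict[str, float]]:
        return {
            a.name: {"posterior_mean": a.posterior_mean, "posterior_sd": a.posterior_sd}
            for a in self.arms
        }

    @property
    def secondary_estimates(self) -> Optional[Dict[str, Dict[str, float]]]:
        if all(a.secondary_n is None for a in self.arms):
            return None
        return {
            a.name: {
                "n": a.secondary_n,
                "posterior_mean": a.secondary_posterior_mean,
                "posterior_sd": a.secondary_posterior_sd,
            }
            for a in self.arms
        }

    def to_dict(self) -> dict:
        return {
            "stop_reason": self.stop_reason,
            "winner": self.winner,
            "total_n": self.total_n,
            "total_cost": self.total_cost,
            "duration": self.duration,
            "arms": [a.to_dict() for a in self.arms],
            "decision_log": [r.to_dict() for r in self.decision_log],
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    def decision_frame(self) -> pd.DataFrame:
        """Decision log as a flat table, one row per look."""
        rows = []
        for rec in self.decision_log:
            row = {"look": rec.look, "n_total": rec.n_total, "actions": ";".join(rec.actions)}
            for name, p in rec.probs.items():
                row[f"prob_best[{name}]"] = p
            rows.append(row)
        return pd.DataFrame(rows)

    def superiority_frame(self) -> pd.DataFrame:
        """Superiority probability of each arm by interim look."""
        rows = []
        for rec in self.decision_log:
            row = {"look": rec.look, "n_total": rec.n_total}
            row.update(rec.probs)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class InterimDecision:
    """Outcome of evaluating the adaptation rules at one look."""

    probs: Dict[str, Optional[float]]
    stop: Optional[str] = None
    winner: Optional[str] = None
    drops: List[Tuple[str, str]] = field(default_factory=list)
    admits: int = 0


def validate_trial_inputs(arms: Sequence[ArmSpec], rules: DesignRules) -> None:
    """Raise ValueError on any configuration problem before simulating."""
    names = [a.name for a in arms]
    if len(set(names)) != len(names):
        raise ValueError("arm names must be unique")
    controls = [a for a in arms if a.role == "control"]
    if len(controls) != 1:
        raise ValueError(f"exactly one control arm is required, found {len(controls)}")
    if controls[0].available_from != 0:
        raise ValueError("the control arm must be available from the start")
    initial = [a for a in arms if a.available_from == 0]
    if len(initial) < 2:
        raise ValueError("at least two arms must be active at the start")
    for a in arms:
        if rules.outcome_type == BINARY:
            if not (0.0 < a.true_param < 1.0):
                raise ValueError(
                    f"arm {a.name!r}: binary true_param must lie in (0, 1), got {a.true_param}"
                )
        else:
            if a.true_sd is None or a.true_sd <= 0:
                raise ValueError(f"arm {a.name!r}: continuous outcomes need true_sd > 0")
        if rules.secondary_type == BINARY and a.secondary_param is not None:
            if not (0.0 < a.secondary_param < 1.0):
                raise ValueError(f"arm {a.name!r}: binary secondary_param must lie in (0, 1)")
        if rules.secondary_type == CONTINUOUS and a.secondary_param is not None:
            if a.secondary_sd is None or a.secondary_sd <= 0:
                raise ValueError(f"arm {a.name!r}: continuous secondary needs secondary_sd > 0")
    if rules.mcid_margin is not None and rules.outcome_type == BINARY and rules.higher_better:
        raise ValueError(
            "relative-risk-reduction margins use the harmful-event convention; "
            "set higher_better=False for a binary outcome with an MCID margin"
        )
    if rules.max_active_arms is not None and rules.max_active_arms < 2:
        raise ValueError("max_active_arms must be >= 2")


def _prior(rules: DesignRules, secondary: bool = False) -> Posterior:
    kind = rules.secondary_type if secondary else rules.outcome_type
    if kind == BINARY:
        return BinaryPosterior(1.0, 1.0)
    sd = rules.secondary_planning_sd if secondary else rules.planning_sd
    return ContinuousPosterior(prior_mean=0.0, prior_scale=1000.0, planning_sd=sd)


def draw_outcome(
    arm: ArmSpec,
    control: ArmSpec,
    rng: np.random.Generator,
    outcome_type: str = BINARY,
) -> float:
    """One patient's outcome under intent-to-treat adherence dilution.

    With probability ``arm.adherence`` the outcome comes from the arm's own
    distribution; otherwise from the control's (crossover).  The control arm
    always draws from its own distribution.
    """
    src = arm
    if arm.name != control.name and arm.role != "control" and arm.adherence < 1.0:
        if rng.random() >= arm.adherence:
            src = control
    if outcome_type == BINARY:
        return float(rng.random() < src.true_param)
    return float(rng.normal(src.true_param, src.true_sd))


def _draw_outcomes(
    arm: ArmSpec,
    ref: ArmSpec,
    k: int,
    rng: np.random.Generator,
    outcome_type: str,
    secondary: bool = False,
) -> np.ndarray:
    """Vector of k outcomes for one arm (adherence crossover to ``ref``)."""
    if secondary:
        param = arm.true_param if arm.secondary_param is None else arm.secondary_param
        sd = arm.secondary_sd
        ref_param = ref.true_param if ref.secondary_param is None else ref.secondary_param
        ref_sd = ref.secondary_sd
    else:
        param, sd = arm.true_param, arm.true_sd
        ref_param, ref_sd = ref.true_param, ref.true_sd
    crossover = arm.name != ref.name and arm.role != "control" and arm.adherence < 1.0
    if outcome_type == BINARY:
        if crossover:
            adhere = rng.random(k) < arm.adherence
            p = np.where(adhere, param, ref_param)
        else:
            p = param
        return (rng.random(k) < p).astype(float)
    if crossover:
        adhere = rng.random(k) < arm.adherence
        mu = np.where(adhere, param, ref_param)
        sig = np.where(adhere, sd, ref_sd)
    else:
        mu, sig = param, sd
    return rng.normal(mu, sig, size=k)


def track_secondary(
    draws_per_arm: Dict[str, Sequence[float]],
    outcome_type: str = BINARY,
    planning_sd: float = 1.0,
) -> Dict[str, Dict[str, float]]:
    """Posterior summaries for a monitored-only secondary outcome.

    The secondary outcome accumulates and is summarized exactly like the
    primary but never feeds any adaptation decision.
    """
    out: Dict[str, Dict[str, float]] = {}
    for name, draws in draws_per_arm.items():
        x = np.asarray(draws, dtype=float)
        if outcome_type == BINARY:
            post = update_binary(BinaryPosterior(1.0, 1.0), int(x.sum()), int(x.size - x.sum()))
            out[name] = {"n": int(x.size), "posterior_mean": post.mean, "posterior_sd": post.sd}
        else:
            post = update_continuous(
                ContinuousPosterior(planning_sd=planning_sd), x.tolist()
            )
            out[name] = {"n": int(x.size), "posterior_mean": post.mean, "posterior_sd": post.scale}
    return out


def apply_rules(
    probs: Dict[str, Optional[float]],
    margin_probs: Dict[str, float],
    roles: Dict[str, str],
    rules: DesignRules,
    reference: str,
    n_queued: int = 0,
) -> InterimDecision:
    """Pure rule application given precomputed probabilities.

    Precedence at one look: superiority stop, futility drops, MCID drops,
    platform admissions; a look that leaves no comparator arm stops the
    trial for futility.
    """
    names = list(probs)
    candidates = [n for n in names if probs[n] is not None and (
        rules.comparison_mode == ALL_ARMS or n != reference)]
    decision = InterimDecision(probs=dict(probs))
    best = max(candidates, key=lambda n: probs[n])
    if probs[best] > rules.superiority_threshold:
        decision.stop = STOP_SUPERIORITY
        decision.winner = best
        return decision
    droppable = [n for n in names if roles[n] != "control" and n != reference]
    dropped = set()
    for n in droppable:
        p = probs[n]
        if p is not None and p < rules.futility_threshold:
            decision.drops.append((n, "futility"))
            dropped.add(n)
    if rules.mcid_margin is not None:
        for n in droppable:
            if n in dropped:
                continue
            if margin_probs.get(n, 0.0) >= rules.mcid_certainty:
                decision.drops.append((n, "mcid"))
                dropped.add(n)
    if decision.drops and rules.platform_enabled and n_queued > 0:
        cap = rules.max_active_arms or len(names)
        capacity = cap - (len(names) - len(dropped))
        decision.admits = max(0, min(n_queued, capacity))
    if dropped and len(dropped) == len(droppable) and decision.admits == 0:
        decision.stop = STOP_FUTILITY_ALL
    return decision


def interim_decision(
    posterior_states: Sequence[Posterior],
    rules: DesignRules,
    arms: Sequence[ArmSpec],
    rng: np.random.Generator,
    n_queued: int = 0,
    reference: Optional[str] = None,
) -> InterimDecision:
    """Evaluate all adaptation rules at one interim look.

    ``arms`` and ``posterior_states`` are aligned and cover the currently
    active arms.  ``reference`` names the comparator arm (the control, or
    the previous-stage winner in a perpetual platform trial); it is never
    dropped.
    """
    if len(arms) < 2:
        raise ValueError("interim decisions need at least two active arms")
    names = [a.name for a in arms]
    roles = {a.name: a.role for a in arms}
    if reference is None:
        reference = next((a.name for a in arms if a.role == "control"), names[0])
    direction = rules.direction
    probs: Dict[str, Optional[float]] = {}
    if rules.comparison_mode == ALL_ARMS:
        vec = prob_superior_each(posterior_states, direction, rules.decision_draws, rng)
        probs = dict(zip(names, vec.probs))
    else:
        ref_post = posterior_states[names.index(reference)]
        for name, post in zip(names, posterior_states):
            if name == reference:
                probs[name] = None
                continue
            x = post.sample(rules.decision_draws, rng)
            r = ref_post.sample(rules.decision_draws, rng)
            better = x > r if direction == HIGHER_BETTER else x < r
            probs[name] = float(np.mean(better))
    margin_probs: Dict[str, float] = {}
    if rules.mcid_margin is not None and reference in names:
        ref_post = posterior_states[names.index(reference)]
        for name, post in zip(names, posterior_states):
            if name == reference or roles[name] == "control":
                continue
            margin_probs[name] = prob_effect_below_margin(
                post,
                ref_post,
                rules.mcid_margin,
                rules.effect_scale,
                rules.decision_draws,
                rng,
                direction,
            )
    return apply_rules(probs, margin_probs, roles, rules, reference, n_queued)


class _ArmState:
    __slots__ = (
        "spec",
        "active",
        "entered_at",
        "dropped_at",
        "drop_reason",
        "enrolled",
        "posterior",
        "secondary",
        "secondary_n",
    )

    def __init__(self, spec: ArmSpec, rules: DesignRules):
        self.spec = spec
        self.active = spec.available_from == 0
        self.entered_at = 0 if self.active else None
        self.dropped_at = None
        self.drop_reason = None
        self.enrolled = 0
        self.posterior = _prior(rules)
        self.secondary = _prior(rules, secondary=True) if rules.secondary_type else None
        self.secondary_n = 0 if rules.secondary_type else None


class _TrialRun:
    """Mutable state of one in-flight simulated trial."""

    def __init__(self, arms: Sequence[ArmSpec], rules: DesignRules, rng: np.random.Generator):
        validate_trial_inputs(arms, rules)
        self.rules = rules
        self.out_rng, self.alloc_rng, self.dec_rng, self.sec_rng = rng.spawn(4)
        self.states = [_ArmState(a, rules) for a in arms]
        self.reference = next(s.spec.name for s in self.states if s.spec.role == "control")
        self.total = 0
        self.equal_until = rules.burn_in
        self.log: List[LookRecord] = []

    # -- helpers ---------------------------------------------------------
    def _active(self) -> List[_ArmState]:
        return [s for s in self.states if s.active]

    def _queued(self) -> List[_ArmState]:
        pending = [
            s
            for s in self.states
            if not s.active and s.entered_at is None and s.spec.available_from <= self.total
        ]
        return sorted(pending, key=lambda s: s.spec.available_from)

    def _ref_spec(self) -> ArmSpec:
        for s in self.states:
            if s.spec.name == self.reference:
                return s.spec
        return self.states[0].spec

    def _record_chunk(self, state: _ArmState, outcomes: np.ndarray) -> None:
        state.enrolled += outcomes.size
        if self.rules.outcome_type == BINARY:
            resp = int(outcomes.sum())
            state.posterior = update_binary(state.posterior, resp, outcomes.size - resp)
        else:
            state.posterior = update_continuous(state.posterior, outcomes)

    def _record_secondary(self, state: _ArmState, k: int) -> None:
        if state.secondary is None or k == 0:
            return
        draws = _draw_outcomes(
            state.spec,
            self._ref_spec(),
            k,
            self.sec_rng,
            self.rules.secondary_type,
            secondary=True,
        )
        state.secondary_n += k
        if self.rules.secondary_type == BINARY:
            resp = int(draws.sum())
            state.secondary = update_binary(state.secondary, resp, draws.size - resp)
        else:
            state.secondary = update_continuous(state.secondary, draws)

    def _rar_weights(self, active: List[_ArmState]) -> allocation.AllocationWeights:
        vec = prob_superior_each(
            [s.posterior for s in active],
            self.rules.direction,
            self.rules.rar_draws,
            self.dec_rng,
        )
        w = allocation.rar_weights(vec)
        if self.rules.protect_control:
            k = len(active)
            ref_idx = next(
                (i for i, s in enumerate(active) if s.spec.name == self.reference), None
            )
            if ref_idx is not None:
                arr = np.asarray(w.weights)
                others = arr.sum() - arr[ref_idx]
                arr = arr * ((1.0 - 1.0 / k) / others if others > 0 else 0.0)
                arr[ref_idx] = 1.0 / k
                w = allocation.AllocationWeights(tuple(arr))
        return w

    def _accrue(self, m: int) -> None:
        rules = self.rules
        while m > 0:
            active = self._active()
            k = len(active)
            rar_now = rules.rar_enabled and self.total >= self.equal_until and k >= 2
            if not rar_now:
                chunk = m
                if rules.rar_enabled and self.total < self.equal_until:
                    chunk = min(m, self.equal_until - self.total)
                weights = allocation.equal_weights(k) if k >= 2 else allocation.AllocationWeights((1.0,))
                idx = self.alloc_rng.choice(k, size=chunk, p=np.asarray(weights.weights))
                ref = self._ref_spec()
                for i, state in enumerate(active):
                    n_i = int(np.sum(idx == i))
                    if n_i == 0:
                        continue
                    outcomes = _draw_outcomes(
                        state.spec, ref, n_i, self.out_rng, rules.outcome_type
                    )
                    self._record_chunk(state, outcomes)
                    self._record_secondary(state, n_i)
                self.total += chunk
                m -= chunk
            else:
                # RAR recomputes the weights for every accumulated patient.
                weights = self._rar_weights(active)
                i = allocation.assign_patient(weights, self.alloc_rng)
                state = active[i]
                outcomes = _draw_outcomes(
                    state.spec, self._ref_spec(), 1, self.out_rng, rules.outcome_type
                )
                self._record_chunk(state, outcomes)
                self._record_secondary(state, 1)
                self.total += 1
                m -= 1

    # -- decision application -------------------------------------------
    def _admit(self, state: _ArmState, rec: LookRecord) -> None:
        state.active = True
        state.entered_at = self.total
        if self.rules.rar_enabled and self.rules.new_arm_burn_in > 0:
            self.equal_until = max(self.equal_until, self.total + self.rules.new_arm_burn_in)
        rec.actions.append(f"add:{state.spec.name}")

    def _drop(self, name: str, reason: str, rec: LookRecord) -> None:
        for s in self.states:
            if s.spec.name == name:
                s.active = False
                s.dropped_at = self.total
                s.drop_reason = reason
                rec.actions.append(f"drop:{name}:{reason}")
                return

    def run(self) -> TrialResult:
        rules = self.rules
        looks = look_schedule(rules.max_n, rules.n_looks)
        step = looks[0] if len(looks) == 1 else looks[1] - looks[0]
        hard_cap = (
            rules.max_n
            if not rules.perpetual
            else int(math.ceil(rules.perpetual_cap_factor * rules.max_n))
        )
        stop_reason: Optional[str] = None
        winner: Optional[str] = None
        look_idx = 0
        while stop_reason is None:
            target = looks[look_idx] if look_idx < len(looks) else self.total + max(step, 1)
            target = min(target, hard_cap)
            self._accrue(target - self.total)
            queued = self._queued()
            active = self._active()
            decision = interim_decision(
                [s.posterior for s in active],
                rules,
                [s.spec for s in active],
                self.dec_rng,
                n_queued=len(queued) if rules.platform_enabled else 0,
                reference=self.reference,
            )
            rec = LookRecord(look=look_idx + 1, n_total=self.total, probs=decision.probs)
            if decision.stop == STOP_SUPERIORITY:
                rec.actions.append(f"superiority:{decision.winner}")
                winner = decision.winner
                if rules.perpetual and queued and self.total < hard_cap:
                    # Continue as a platform: the winner becomes the new
                    # comparator and the next queued arm enters.
                    for s in active:
                        if s.spec.name != decision.winner:
                            self._drop(s.spec.name, "stage-loss", rec)
                    self.reference = decision.winner
                    self._admit(queued[0], rec)
                    rec.actions.append(f"stage-continue:{decision.winner}")
                else:
                    stop_reason = STOP_SUPERIORITY
            elif decision.stop == STOP_FUTILITY_ALL:
                for name, reason in decision.drops:
                    self._drop(name, reason, rec)
                rec.actions.append("futility-all")
                stop_reason = STOP_FUTILITY_ALL
            else:
                for name, reason in decision.drops:
                    self._drop(name, reason, rec)
                for s in self._queued()[: decision.admits]:
                    self._admit(s, rec)
                if len(self._active()) < 2:
                    rec.actions.append("futility-all")
                    stop_reason = STOP_FUTILITY_ALL
            self.log.append(rec)
            if stop_reason is None and self.total >= hard_cap:
                stop_reason = STOP_PERPETUAL if rules.perpetual else STOP_MAX_N
            look_idx += 1
        return self._result(stop_reason, winner)

    def _result(self, stop_reason: str, winner: Optional[str]) -> TrialResult:
        rules = self.rules
        arm_results = []
        for s in self.states:
            if rules.outcome_type == BINARY:
                post_mean, post_sd = s.posterior.mean, s.posterior.sd
                outcome_sum = s.posterior.alpha - 1.0
            else:
                post_mean, post_sd = s.posterior.mean, s.posterior.scale
                outcome_sum = s.posterior.sum_x
            sec_mean = sec_sd = None
            if s.secondary is not None:
                if rules.secondary_type == BINARY:
                    sec_mean, sec_sd = s.secondary.mean, s.secondary.sd
                else:
                    sec_mean, sec_sd = s.secondary.mean, s.secondary.scale
            arm_results.append(
                ArmResult(
                    name=s.spec.name,
                    role=s.spec.role,
                    enrolled=s.enrolled,
                    outcome_sum=float(outcome_sum),
                    outcome_mean=float(outcome_sum / s.enrolled) if s.enrolled else None,
                    posterior_mean=float(post_mean),
                    posterior_sd=float(post_sd),
                    entered_at=s.entered_at if s.entered_at is not None else -1,
                    dropped_at=s.dropped_at,
                    drop_reason=s.drop_reason,
                    secondary_n=s.secondary_n,
                    secondary_posterior_mean=sec_mean,
                    secondary_posterior_sd=sec_sd,
                )
            )
        return TrialResult(
            stop_reason=stop_reason,
            winner=winner,
            total_n=self.total,
            total_cost=self.total * rules.cost_per_patient,
            duration=self.total / rules.accrual_rate,
            arms=arm_results,
            decision_log=self.log,
        )


def simulate_trial(
    arms: Sequence[ArmSpec], rules: DesignRules, rng: np.random.Generator
) -> TrialResult:
    """Simulate one adaptive/platform trial end-to-end.

    Patients accrue one at a time (vectorized in chunks when allocation is
    not response-adaptive), posteriors update at each completed outcome,
    and the adaptation rules run at each scheduled look.  Fully
    reproducible given (config, generator state).
    """
    return _TrialRun(arms, rules, rng).run()


def simulate_conventional(
    arms: Sequence[ArmSpec], rules: DesignRules, rng: np.random.Generator
) -> TrialResult:
    """Fixed-sample comparator: equal allocation, one final analysis at max_n.

    The arm with the highest superiority probability is declared the winner
    iff it exceeds the superiority threshold; total_n is always max_n.
    """
    validate_trial_inputs(arms, rules)
    conv_rules = DesignRules(
        max_n=rules.max_n,
        n_looks=1,
        superiority_threshold=rules.superiority_threshold,
        futility_threshold=0.0,
        mcid_margin=None,
        burn_in=0,
        rar_enabled=False,
        platform_enabled=False,
        perpetual=False,
        comparison_mode=rules.comparison_mode,
        cost_per_patient=rules.cost_per_patient,
        accrual_rate=rules.accrual_rate,
        outcome_type=rules.outcome_type,
        higher_better=rules.higher_better,
        planning_sd=rules.planning_sd,
        secondary_type=rules.secondary_type,
        secondary_planning_sd=rules.secondary_planning_sd,
        decision_draws=rules.decision_draws,
    )
    initial = [a for a in arms if a.available_from == 0]
    run = _TrialRun(initial, conv_rules, rng)
    run._accrue(conv_rules.max_n)
    active = run._active()
    decision = interim_decision(
        [s.posterior for s in active],
        conv_rules,
        [s.spec for s in active],
        run.dec_rng,
        reference=run.reference,
    )
    rec = LookRecord(look=1, n_total=run.total, probs=decision.probs)
    winner = None
    if decision.stop == STOP_SUPERIORITY:
        winner = decision.winner
        rec.actions.append(f"superiority:{winner}")
    else:
        rec.actions.append("no-winner")
    run.log.append(rec)
    return run._result(STOP_MAX_N, winner)
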