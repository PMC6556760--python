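import math
from dataclasses import replace

import numpy as np
import pytest

from platsim.posteriors import BinaryPosterior
from platsim.trial_engine import (
    ArmSpec,
    DesignRules,
    apply_rules,
    draw_outcome,
    interim_decision,
    look_schedule,
    simulate_conventional,
    simulate_trial,
    track_secondary,
    validate_trial_inputs,
)


def two_arms(p_control=0.40, p_treat=0.40, **kw):
    return [
        ArmSpec("control", p_control, role="control", **kw),
        ArmSpec("T1", p_treat, **kw),
    ]


def binary_rules(**overrides):
    base = dict(
        max_n=200,
        n_looks=5,
        superiority_threshold=0.99,
        futility_threshold=0.0,
        higher_better=False,
    )
    base.update(overrides)
    return DesignRules(**base)


class TestLookSchedule:
    def test_even_splits(self):
        assert look_schedule(100, 4) == [25, 50, 75, 100]

    def test_rounding_up_and_final_at_max(self):
        looks = look_schedule(100, 3)
        assert looks[-1] == 100
        assert looks == [34, 67, 100]

    def test_single_look(self):
        assert look_schedule(50, 1) == [50]


class TestDrawOutcome:
    def test_full_adherence_mean(self, rng):
        arm, control = ArmSpec("T", 0.2), ArmSpec("C", 0.4, role="control")
        n = 20_000
        draws = [draw_outcome(arm, control, rng) for _ in range(n)]
        se = math.sqrt(0.2 * 0.8 / n)
        assert abs(np.mean(draws) - 0.2) <= 3 * se

    def test_zero_adherence_matches_control(self, rng):
        arm = ArmSpec("T", 0.2, adherence=0.0)
        control = ArmSpec("C", 0.4, role="control")
        n = 20_000
        draws = [draw_outcome(arm, control, rng) for _ in range(n)]
        se = math.sqrt(0.4 * 0.6 / n)
        assert abs(np.mean(draws) - 0.4) <= 3 * se

    def test_half_adherence_mixture_mean(self, rng):
        arm = ArmSpec("T", 0.2, adherence=0.5)
        control = ArmSpec("C", 0.4, role="control")
        n = 30_000
        draws = [draw_outcome(arm, control, rng) for _ in range(n)]
        se = math.sqrt(0.3 * 0.7 / n)
        assert abs(np.mean(draws) - 0.30) <= 3 * se

    def test_control_never_crosses_over(self, rng):
        control = ArmSpec("C", 0.9, role="control", adherence=0.0)
        draws = [draw_outcome(control, control, rng) for _ in range(5_000)]
        assert np.mean(draws) > 0.8

    def test_continuous_outcome(self, rng):
        arm = ArmSpec("T", 1.0, true_sd=0.5)
        control = ArmSpec("C", 0.0, role="control", true_sd=0.5)
        draws = [draw_outcome(arm, control, rng, outcome_type="continuous") for _ in range(5_000)]
        assert np.mean(draws) == pytest.approx(1.0, abs=3 * 0.5 / math.sqrt(5_000))


class TestApplyRules:
    ROLES2 = {"control": "control", "T1": "treatment"}
    ROLES3 = {"control": "control", "T1": "treatment", "T2": "treatment"}

    def test_superiority_stop(self):
        rules = binary_rules(superiority_threshold=0.99)
        d = apply_rules({"control": 0.005, "T1": 0.995}, {}, self.ROLES2, rules, "control")
        assert d.stop == "superiority"
        assert d.winner == "T1"

    def test_no_rule_triggered(self):
        rules = binary_rules(futility_threshold=0.01)
        probs = {"control": 0.52, "T1": 0.40, "T2": 0.08}
        d = apply_rules(probs, {}, self.ROLES3, rules, "control")
        assert d.stop is None and not d.drops and d.admits == 0

    def test_futility_drop_and_platform_admit(self):
        rules = binary_rules(futility_threshold=0.01, platform_enabled=True)
        probs = {"control": 0.65, "T1": 0.005, "T2": 0.345}
        d = apply_rules(probs, {}, self.ROLES3, rules, "control", n_queued=1)
        assert d.drops == [("T1", "futility")]
        assert d.admits == 1
        assert d.stop is None

    def test_mcid_drop(self):
        rules = binary_rules(futility_threshold=0.0, mcid_margin=0.2, mcid_certainty=0.95)
        d = apply_rules(
            {"control": 0.6, "T1": 0.4}, {"T1": 0.97}, self.ROLES2, rules, "control"
        )
        assert d.drops == [("T1", "mcid")]
        assert d.stop == "futility-all"

    def test_superiority_precedes_futility(self):
        rules = binary_rules(superiority_threshold=0.99, futility_threshold=0.01)
        probs = {"control": 0.995, "T1": 0.005}
        d = apply_rules(probs, {}, self.ROLES2, rules, "control")
        assert d.stop == "superiority" and not d.drops

    def test_two_arm_futility_terminates(self):
        rules = binary_rules(futility_threshold=0.01)
        d = apply_rules({"control": 0.995, "T1": 0.005}, {}, self.ROLES2,
                        replace(rules, superiority_threshold=1.0), "control")
        assert d.drops == [("T1", "futility")]
        assert d.stop == "futility-all"


class TestInterimDecision:
    def test_extreme_posteriors_stop(self, rng):
        rules = binary_rules(higher_better=True)
        arms = [ArmSpec("control", 0.3, role="control"), ArmSpec("T1", 0.3)]
        posts = [BinaryPosterior(11, 991), BinaryPosterior(991, 11)]
        d = interim_decision(posts, rules, arms, rng)
        assert d.stop == "superiority" and d.winner == "T1"

    def test_requires_two_arms(self, rng):
        with pytest.raises(ValueError):
            interim_decision([BinaryPosterior(1, 1)], binary_rules(), [ArmSpec("a", 0.5)], rng)

    def test_vs_control_mode_reference_has_no_prob(self, rng):
        rules = binary_rules(comparison_mode="vs-control")
        arms = two_arms()
        posts = [BinaryPosterior(50, 50), BinaryPosterior(50, 50)]
        d = interim_decision(posts, rules, arms, rng)
        assert d.probs["control"] is None
        assert 0.0 <= d.probs["T1"] <= 1.0


class TestValidation:
    def test_two_controls_rejected(self):
        arms = [ArmSpec("a", 0.3, role="control"), ArmSpec("b", 0.3, role="control")]
        with pytest.raises(ValueError, match="control"):
            validate_trial_inputs(arms, binary_rules())

    def test_duplicate_names_rejected(self):
        arms = [ArmSpec("a", 0.3, role="control"), ArmSpec("a", 0.3)]
        with pytest.raises(ValueError, match="unique"):
            validate_trial_inputs(arms, binary_rules())

    def test_binary_param_range(self):
        arms = [ArmSpec("a", 0.3, role="control"), ArmSpec("b", 1.3)]
        with pytest.raises(ValueError, match="true_param"):
            validate_trial_inputs(arms, binary_rules())

    def test_rrr_margin_needs_harm_direction(self):
        arms = two_arms()
        with pytest.raises(ValueError, match="higher_better"):
            validate_trial_inputs(
                arms, binary_rules(higher_better=True, mcid_margin=0.2)
            )

    def test_continuous_needs_sd(self):
        arms = [ArmSpec("a", 0.0, role="control"), ArmSpec("b", 1.0)]
        with pytest.raises(ValueError, match="true_sd"):
            validate_trial_inputs(arms, binary_rules(outcome_type="continuous"))


class TestSimulateTrial:
    def test_unreachable_rules_run_to_max_n(self, rng):
        rules = binary_rules(superiority_threshold=1.0, futility_threshold=0.0)
        result = simulate_trial(two_arms(), rules, rng)
        assert result.stop_reason == "max-n"
        assert result.total_n == rules.max_n
        assert result.winner is None

    def test_determinism_bit_identical(self):
        rules = binary_rules(mcid_margin=0.2, futility_threshold=0.01)
        r1 = simulate_trial(two_arms(0.4, 0.3), rules, np.random.default_rng(33))
        r2 = simulate_trial(two_arms(0.4, 0.3), rules, np.random.default_rng(33))
        assert r1.to_json() == r2.to_json()

    def test_enrollment_conservation(self):
        rules = binary_rules(mcid_margin=0.2, futility_threshold=0.01)
        for seed in range(10):
            r = simulate_trial(two_arms(0.4, 0.3), rules, np.random.default_rng(seed))
            assert sum(a.enrolled for a in r.arms) == r.total_n

    def test_strong_effect_stops_early_for_right_winner(self):
        from platsim.design_eval import replicate_rng

        arms = two_arms(0.40, 0.10)
        rules = DesignRules(
            max_n=2000, n_looks=10, superiority_threshold=0.99, futility_threshold=0.0,
            higher_better=False,
        )
        totals, winners = [], []
        for i in range(200):
            r = simulate_trial(arms, rules, replicate_rng(5, 0, i))
            totals.append(r.total_n)
            if r.winner is not None:
                winners.append(r.winner)
        assert np.median(totals) < rules.max_n
        assert winners  # essentially every trial stops under this effect size
        assert np.mean([w == "T1" for w in winners]) > 0.95

    def test_stopping_dominance_under_shared_outcome_stream(self):
        arms = two_arms(0.40, 0.25)
        totals = []
        for thr in (0.8, 0.9, 0.975, 1.0):
            rules = binary_rules(max_n=300, n_looks=6, superiority_threshold=thr)
            r = simulate_trial(arms, rules, np.random.default_rng(17))
            totals.append(r.total_n)
        assert all(a <= b for a, b in zip(totals, totals[1:]))

    def test_cost_and_duration_accounting(self, rng):
        rules = binary_rules(cost_per_patient=250.0, accrual_rate=4.0)
        r = simulate_trial(two_arms(), rules, rng)
        assert r.total_cost == pytest.approx(r.total_n * 250.0)
        assert r.duration == pytest.approx(r.total_n / 4.0)

    def test_dropped_arm_enrollment_frozen(self):
        arms = two_arms(0.10, 0.40)  # treatment clearly worse (harm outcome)
        rules = binary_rules(
            max_n=600, n_looks=6, futility_threshold=0.05, superiority_threshold=1.0
        )
        r = simulate_trial(arms, rules, np.random.default_rng(3))
        t1 = next(a for a in r.arms if a.name == "T1")
        if t1.dropped_at is not None:
            assert t1.enrolled <= t1.dropped_at

    def test_rar_path_smoke_and_determinism(self):
        arms = two_arms(0.40, 0.20)
        rules = binary_rules(
            max_n=120, n_looks=3, rar_enabled=True, burn_in=40, rar_draws=200
        )
        r1 = simulate_trial(arms, rules, np.random.default_rng(8))
        r2 = simulate_trial(arms, rules, np.random.default_rng(8))
        assert r1.to_json() == r2.to_json()
        assert sum(a.enrolled for a in r1.arms) == r1.total_n

    def test_rar_favors_better_arm_on_average(self):
        from platsim.design_eval import replicate_rng

        arms = two_arms(0.40, 0.10)
        rules = binary_rules(
            max_n=200, n_looks=2, rar_enabled=True, burn_in=50, rar_draws=200,
            superiority_threshold=1.0,
        )
        diff = 0
        for i in range(30):
            r = simulate_trial(arms, rules, replicate_rng(21, 0, i))
            e = r.enrolled
            diff += e["T1"] - e["control"]
        assert diff > 0  # RAR skews allocation toward the superior arm

    def test_perpetual_caps_and_labels(self):
        arms = [
            ArmSpec("control", 0.40, role="control"),
            ArmSpec("T1", 0.40),
            ArmSpec("T2", 0.40, available_from=1),
        ]
        rules = binary_rules(
            max_n=100, n_looks=2, superiority_threshold=1.0, platform_enabled=True,
            perpetual=True, perpetual_cap_factor=2.0,
        )
        r = simulate_trial(arms, rules, np.random.default_rng(12))
        assert r.stop_reason in ("perpetual-censored", "superiority", "futility-all")
        assert r.total_n <= 200


class TestSimulateConventional:
    def test_total_n_always_max(self, rng):
        rules = binary_rules()
        for seed in range(5):
            r = simulate_conventional(two_arms(), rules, np.random.default_rng(seed))
            assert r.total_n == rules.max_n
            assert r.stop_reason == "max-n"

    def test_determinism(self):
        rules = binary_rules()
        r1 = simulate_conventional(two_arms(), rules, np.random.default_rng(4))
        r2 = simulate_conventional(two_arms(), rules, np.random.default_rng(4))
        assert r1.to_json() == r2.to_json()

    def test_near_equal_allocation(self, rng):
        rules = binary_rules(max_n=1000)
        r = simulate_conventional(two_arms(), rules, rng)
        e = r.enrolled
        assert abs(e["control"] - e["T1"]) < 150  # 3+ SD would be ~147

    def test_queued_arms_excluded(self, rng):
        arms = [
            ArmSpec("control", 0.40, role="control"),
            ArmSpec("T1", 0.40),
            ArmSpec("T2", 0.40, available_from=50),
        ]
        r = simulate_conventional(arms, binary_rules(), rng)
        assert {a.name for a in r.arms} == {"control", "T1"}


class TestSecondaryOutcome:
    def test_monitoring_only_contract(self):
        arms_plain = two_arms(0.40, 0.25)
        arms_sec = [
            ArmSpec("control", 0.40, role="control", secondary_param=0.3),
            ArmSpec("T1", 0.25, secondary_param=0.3),
        ]
        rules_plain = binary_rules(futility_threshold=0.01, mcid_margin=0.2)
        rules_sec = replace(rules_plain, secondary_type="binary")
        r1 = simulate_trial(arms_plain, rules_plain, np.random.default_rng(9))
        r2 = simulate_trial(arms_sec, rules_sec, np.random.default_rng(9))
        assert [rec.to_dict() for rec in r1.decision_log] == [
            rec.to_dict() for rec in r2.decision_log
        ]
        assert r1.stop_reason == r2.stop_reason and r1.winner == r2.winner

    def test_absent_when_not_configured(self, rng):
        r = simulate_trial(two_arms(), binary_rules(), rng)
        assert r.secondary_estimates is None

    def test_secondary_posterior_recovers_truth(self):
        arms = [
            ArmSpec("control", 0.40, role="control", secondary_param=0.3),
            ArmSpec("T1", 0.40, secondary_param=0.3),
        ]
        rules = binary_rules(
            max_n=1000, n_looks=1, superiority_threshold=1.0, secondary_type="binary"
        )
        r = simulate_trial(arms, rules, np.random.default_rng(0))
        for est in r.secondary_estimates.values():
            assert abs(est["posterior_mean"] - 0.3) <= 3 * est["posterior_sd"]

    def test_track_secondary_summaries(self):
        out = track_secondary({"a": [1, 0, 1, 1], "b": [0, 0]}, outcome_type="binary")
        assert out["a"]["n"] == 4
        assert out["a"]["posterior_mean"] == pytest.approx(4 / 6)  # Beta(1+3, 1+1)
        assert out["b"]["posterior_mean"] == pytest.approx(1 / 4)


class TestSerialization:
    def test_json_round_trip_fields(self, rng):
        import json

        r = simulate_trial(two_arms(), binary_rules(), rng)
        d = json.loads(r.to_json())
        assert d["total_n"] == r.total_n
        assert len(d["arms"]) == 2
        assert len(d["decision_log"]) == len(r.decision_log)

    def test_decision_frame_columns(self, rng):
        r = simulate_trial(two_arms(), binary_rules(), rng)
        df = r.decision_frame()
        assert {"look", "n_total", "actions"} <= set(df.columns)
        sup = r.superiority_frame()
        assert {"control", "T1"} <= set(sup.columns)
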