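"""Scenario configuration schema, (de)serialization and canonical fixtures.

Configs are YAML (JSON is a YAML subset and loads too).  Validation is
strict: unknown keys are rejected with a message naming the key, field
violations name the field and the allowed range, and any defaulted field is
logged so a run's effective configuration is always auditable.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import List, Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .trial_engine import ArmSpec, DesignRules, validate_trial_inputs

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Raised for any scenario-configuration problem, with a readable message."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class OutcomeConfig(_StrictModel):
    type: Literal["binary", "continuous"] = "binary"
    higher_better: bool = True
    planning_sd: float = Field(default=1.0, gt=0)
    secondary_type: Optional[Literal["binary", "continuous"]] = None
    secondary_planning_sd: float = Field(default=1.0, gt=0)


class ArmConfig(_StrictModel):
    name: str
    true_param: float
    role: Literal["control", "treatment"] = "treatment"
    true_sd: Optional[float] = Field(default=None, gt=0)
    adherence: float = Field(default=1.0, ge=0, le=1)
    available_from: int = Field(default=0, ge=0)
    secondary_param: Optional[float] = None
    secondary_sd: Optional[float] = Field(default=None, gt=0)


class RulesConfig(_StrictModel):
    max_n: int = Field(ge=2)
    n_looks: int = Field(default=10, ge=1)
    superiority_threshold: float = Field(default=0.99, gt=0.5, le=1.0)
    futility_threshold: float = Field(default=0.01, ge=0.0, lt=0.5)
    mcid_margin: Optional[float] = Field(default=None, ge=0.0)
    mcid_certainty: float = Field(default=0.95, gt=0.5, le=1.0)
    burn_in: int = Field(default=0, ge=0)
    rar_enabled: bool = False
    protect_control: bool = False
    platform_enabled: bool = False
    perpetual: bool = False
    comparison_mode: Literal["all-arms", "vs-control"] = "all-arms"
    cost_per_patient: float = Field(default=1.0, ge=0)
    accrual_rate: float = Field(default=1.0, gt=0)
    max_active_arms: Optional[int] = Field(default=None, ge=2)
    new_arm_burn_in: int = Field(default=0, ge=0)
    perpetual_cap_factor: float = Field(default=5.0, ge=1.0)

    @model_validator(mode="after")
    def _burn_in_within_max_n(self) -> "RulesConfig":
        if self.burn_in > self.max_n:
            raise ValueError("burn_in must not exceed max_n")
        return self


class SimulationConfig(_StrictModel):
    n_sims: int = Field(default=200, ge=1)
    time_budget: Optional[float] = Field(default=None, gt=0)
    seed: int = 0
    decision_draws: int = Field(default=10_000, ge=1)
    rar_draws: int = Field(default=1_000, ge=1)


class ScenarioConfig(_StrictModel):
    """One complete trial scenario: truth, design rules and run settings."""

    schema_version: int = SCHEMA_VERSION
    outcome: OutcomeConfig = Field(default_factory=OutcomeConfig)
    arms: List[ArmConfig]
    rules: RulesConfig
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)

    @model_validator(mode="after")
    def _validate_scenario(self) -> "ScenarioConfig":
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(
                f"schema_version {self.schema_version} unsupported (expected {SCHEMA_VERSION})"
            )
        # Reuse the engine's cross-field validation for truth/rules coherence.
        try:
            validate_trial_inputs(self.to_arm_specs(), self.to_design_rules())
        except ValueError as exc:
            raise ValueError(str(exc)) from exc
        return self

    def to_arm_specs(self) -> List[ArmSpec]:
        return [
            ArmSpec(
                name=a.name,
                true_param=a.true_param,
                role=a.role,
                true_sd=a.true_sd,
                adherence=a.adherence,
                available_from=a.available_from,
                secondary_param=a.secondary_param,
                secondary_sd=a.secondary_sd,
            )
            for a in self.arms
        ]

    def to_design_rules(self) -> DesignRules:
        r = self.rules
        return DesignRules(
            max_n=r.max_n,
            n_looks=r.n_looks,
            superiority_threshold=r.superiority_threshold,
            futility_threshold=r.futility_threshold,
            mcid_margin=r.mcid_margin,
            mcid_certainty=r.mcid_certainty,
            burn_in=r.burn_in,
            rar_enabled=r.rar_enabled,
            protect_control=r.protect_control,
            platform_enabled=r.platform_enabled,
            perpetual=r.perpetual,
            comparison_mode=r.comparison_mode,
            cost_per_patient=r.cost_per_patient,
            accrual_rate=r.accrual_rate,
            outcome_type=self.outcome.type,
            higher_better=self.outcome.higher_better,
            planning_sd=self.outcome.planning_sd,
            secondary_type=self.outcome.secondary_type,
            secondary_planning_sd=self.outcome.secondary_planning_sd,
            decision_draws=self.simulation.decision_draws,
            rar_draws=self.simulation.rar_draws,
            max_active_arms=r.max_active_arms,
            new_arm_burn_in=r.new_arm_burn_in,
            perpetual_cap_factor=r.perpetual_cap_factor,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_yaml())


def _format_validation_error(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        if err["type"] == "extra_forbidden":
            lines.append(f"{loc}: unknown key {err['loc'][-1]!r}")
        else:
            lines.append(f"{loc}: {err['msg']}")
    return "invalid scenario configuration:\n  " + "\n  ".join(lines)


def parse_config(data: dict) -> ScenarioConfig:
    if not isinstance(data, dict):
        raise ConfigError("scenario configuration must be a mapping")
    try:
        cfg = ScenarioConfig(**data)
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(exc)) from exc
    _log_defaults(cfg, data)
    return cfg


def _log_defaults(cfg: ScenarioConfig, data: dict) -> None:
    for section in ("outcome", "rules", "simulation"):
        model = getattr(cfg, section)
        provided = set((data.get(section) or {}).keys())
        defaulted = sorted(set(model.model_dump()) - provided)
        if defaulted:
            logger.info("config: %s fields defaulted: %s", section, ", ".join(defaulted))


def load_config(path: Union[str, Path]) -> ScenarioConfig:
    """Parse, validate and default a scenario configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    return parse_config(data)


FIXTURE_NAMES = ("null-2arm", "alt-2arm", "platform-3arm", "continuous-2arm")


def make_fixture(name: str) -> ScenarioConfig:
    """Canonical scenarios used throughout the test suite.

    All binary fixtures model a harmful event (lower rate is better) and use
    the worked example thresholds: 99% superiority, 1% futility, and a 20%
    relative-risk-reduction margin at 95% certainty.
    """
    common_rules = dict(
        superiority_threshold=0.99,
        futility_threshold=0.01,
        mcid_margin=0.20,
        mcid_certainty=0.95,
        cost_per_patient=100.0,
        accrual_rate=10.0,
    )
    if name == "null-2arm":
        return parse_config(
            {
                "outcome": {"type": "binary", "higher_better": False},
                "arms": [
                    {"name": "control", "role": "control", "true_param": 0.40},
                    {"name": "T1", "true_param": 0.40},
                ],
                "rules": {"max_n": 400, "n_looks": 10, **common_rules},
                "simulation": {"n_sims": 200, "seed": 42},
            }
        )
    if name == "alt-2arm":
        return parse_config(
            {
                "outcome": {"type": "binary", "higher_better": False},
                "arms": [
                    {"name": "control", "role": "control", "true_param": 0.40},
                    {"name": "T1", "true_param": 0.20},
                ],
                "rules": {"max_n": 400, "n_looks": 10, **common_rules},
                "simulation": {"n_sims": 200, "seed": 42},
            }
        )
    if name == "platform-3arm":
        return parse_config(
            {
                "outcome": {"type": "binary", "higher_better": False},
                "arms": [
                    {"name": "control", "role": "control", "true_param": 0.40},
                    {"name": "T1", "true_param": 0.55},
                    {"name": "T2", "true_param": 0.25, "available_from": 1},
                ],
                "rules": {
                    "max_n": 600,
                    "n_looks": 10,
                    "platform_enabled": True,
                    "max_active_arms": 2,
                    **common_rules,
                },
                "simulation": {"n_sims": 200, "seed": 42},
            }
        )
    if name == "continuous-2arm":
        return parse_config(
            {
                "outcome": {"type": "continuous", "higher_better": True, "planning_sd": 1.0},
                "arms": [
                    {"name": "control", "role": "control", "true_param": 0.0, "true_sd": 1.0},
                    {"name": "T1", "true_param": 0.5, "true_sd": 1.0},
                ],
                "rules": {
                    "max_n": 250,
                    "n_looks": 5,
                    "superiority_threshold": 0.99,
                    "futility_threshold": 0.01,
                    "mcid_margin": 0.20,
                    "mcid_certainty": 0.95,
                    "cost_per_patient": 100.0,
                    "accrual_rate": 10.0,
                },
                "simulation": {"n_sims": 200, "seed": 42},
            }
        )
    raise ConfigError(f"unknown fixture {name!r}; known fixtures: {', '.join(FIXTURE_NAMES)}")
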