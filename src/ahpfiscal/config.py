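"""Run configuration: loading, validation and defaults.

A run is fully described by a YAML (or JSON) document with blocks ``fiscal``
(fiscal constants), ``attack_cost`` (per-attack resource lines),
``management_costs`` (annual cost per attack-frequency category),
``scenarios``, ``paths`` (life-table and age-profile CSVs; when omitted the
calibrated synthetic fixture is generated instead), ``generator``
(synthetic-country parameters) and ``output``. Every omitted field takes the
shipped Belgian default, so an empty file is a valid, complete
configuration. Unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .demographics import load_age_profiles, load_life_table
from .fiscal import FiscalParameters
from .health import AttackCostLine, AttackCostTable, ManagementCostSet
from .health import default_attack_cost_table
from .projection import ModelInputs, ScenarioSpec
from .synthetic import CountryGeneratorParams, calibrate_fixture

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config"]


class ConfigError(ValueError):
    """Invalid run configuration (aggregated pydantic report attached)."""


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class FiscalBlock(_Base):
    tax_wedge: float = 0.527
    vat_rate: float = 0.21
    wage_growth: float = 0.013
    transfer_inflation: float = 0.0062
    health_inflation: float = 0.02
    discount_rate: float = 0.03
    pension_annual: float = 14_400.0
    disability_annual: float = 13_613.0
    retirement_age: int = 65
    entry_age: int = 18
    base_age: int = 30
    horizon_age: int = 100
    symptomatic_work_disability: float = 0.5
    indirect_tax_basis: Literal["average_consumption", "own_disposable"] = (
        "average_consumption"
    )

    def to_params(self) -> FiscalParameters:
        return FiscalParameters(**self.model_dump())

    @model_validator(mode="after")
    def _check(self):
        try:
            self.to_params()
        except ValueError as e:
            raise ValueError(str(e))
        return self


class AttackLineBlock(_Base):
    resource: str
    pct: float = Field(1.0, ge=0.0, le=1.0)
    units: float = Field(0.0, ge=0.0)
    unit_cost: float = Field(0.0, ge=0.0)
    canonical_total: Optional[float] = Field(None, ge=0.0)

    def to_line(self) -> AttackCostLine:
        return AttackCostLine(
            self.resource, self.pct, self.units, self.unit_cost,
            self.canonical_total,
        )


class ManagementBlock(_Base):
    asymptomatic: float = Field(6_192.0, ge=0.0)
    symptomatic: float = Field(20_930.0, ge=0.0)
    recurrent: float = Field(34_252.0, ge=0.0)
    severe: float = Field(34_252.0, ge=0.0)

    def to_set(self) -> ManagementCostSet:
        return ManagementCostSet(**self.model_dump())


class ScenarioBlock(_Base):
    name: str
    affected: bool = True
    onset_age: int = 30
    attacks_per_year: float = Field(12.0, ge=0.0)
    attack_duration_years: float | Literal["lifelong"] | None = "lifelong"
    able_to_return_to_work: bool = False
    work_disabled_during_attacks: bool = True
    post_attack_work_disabled: bool = True

    def to_spec(self) -> ScenarioSpec:
        dur = self.attack_duration_years
        if dur == "lifelong":
            dur = None
        return ScenarioSpec(
            name=self.name,
            affected=self.affected,
            onset_age=self.onset_age,
            attacks_per_year=self.attacks_per_year,
            attack_duration_years=dur,
            able_to_return_to_work=self.able_to_return_to_work,
            work_disabled_during_attacks=self.work_disabled_during_attacks,
            post_attack_work_disabled=self.post_attack_work_disabled,
        )

    @model_validator(mode="after")
    def _check(self):
        try:
            self.to_spec()
        except ValueError as e:
            raise ValueError(str(e))
        return self


class PathsBlock(_Base):
    life_table: Optional[str] = None
    profiles: Optional[str] = None

    @model_validator(mode="after")
    def _both_or_neither(self):
        if (self.life_table is None) != (self.profiles is None):
            raise ValueError("provide both life_table and profiles, or neither")
        return self


class GeneratorBlock(_Base):
    makeham_a: float = 0.0003
    gompertz_b: float = 2.2e-5
    gompertz_c: float = 1.099
    earnings_peak_age: int = 47
    earnings_peak: float = 52_000.0
    earnings_curvature: float = 0.0012
    activity_plateau: float = 0.85
    activity_decline_age: int = 55
    disability_base: float = 0.03
    disability_slope: float = 0.045
    gp_cost_base: float = 700.0
    gp_cost_growth_per_age: float = 0.025
    consumption_disposable_share: float = 0.473
    consumption_retirement_factor: float = 0.7
    noise_sd: float = Field(0.0, ge=0.0)
    seed: int = 20210804
    calibrate: bool = True  # scale to the Belgian reference comparator

    def to_params(self) -> CountryGeneratorParams:
        return CountryGeneratorParams(
            **self.model_dump(exclude={"calibrate"})
        )


class OutputBlock(_Base):
    directory: str = "results"
    formats: tuple[Literal["csv", "md"], ...] = ("csv", "md")
    rounding: Literal["eur", "cent", "none"] = "eur"


def _default_scenarios() -> tuple[ScenarioBlock, ...]:
    return (
        ScenarioBlock(name="gp", affected=False, attacks_per_year=0.0,
                      work_disabled_during_attacks=False,
                      post_attack_work_disabled=False),
        ScenarioBlock(name="al_w"),
        ScenarioBlock(name="a10_w", attack_duration_years=10.0),
        ScenarioBlock(name="a10_plus_w", attack_duration_years=10.0,
                      able_to_return_to_work=True,
                      post_attack_work_disabled=False),
    )


def _default_attack_lines() -> tuple[AttackLineBlock, ...]:
    return tuple(
        AttackLineBlock(
            resource=ln.resource, pct=ln.pct_receiving, units=ln.units,
            unit_cost=ln.unit_cost, canonical_total=ln.canonical_total,
        )
        for ln in default_attack_cost_table().lines
    )


class RunConfig(_Base):
    fiscal: FiscalBlock = FiscalBlock()
    attack_cost: tuple[AttackLineBlock, ...] = Field(
        default_factory=_default_attack_lines
    )
    management_costs: ManagementBlock = ManagementBlock()
    scenarios: tuple[ScenarioBlock, ...] = Field(
        default_factory=_default_scenarios
    )
    paths: PathsBlock = PathsBlock()
    generator: GeneratorBlock = GeneratorBlock()
    output: OutputBlock = OutputBlock()

    @model_validator(mode="after")
    def _cross_checks(self):
        names = [s.name for s in self.scenarios]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate scenario names in {names}")
        if not any(not s.affected for s in self.scenarios):
            raise ValueError(
                "configuration needs an unaffected (comparator) scenario"
            )
        return self

    # --- domain conversion --------------------------------------------------

    def fiscal_params(self) -> FiscalParameters:
        return self.fiscal.to_params()

    def attack_table(self) -> AttackCostTable:
        return AttackCostTable(tuple(b.to_line() for b in self.attack_cost))

    def scenario_specs(self) -> dict[str, ScenarioSpec]:
        return {s.name: s.to_spec() for s in self.scenarios}

    def comparator_name(self) -> str:
        return next(s.name for s in self.scenarios if not s.affected)

    def model_inputs(self) -> ModelInputs:
        """Resolve country inputs: CSV paths if given, else the calibrated fixture."""
        params = self.fiscal_params()
        if self.paths.life_table is not None:
            lt_path = Path(self.paths.life_table)
            prof_path = Path(self.paths.profiles)
            for p in (lt_path, prof_path):
                if not p.exists():
                    raise ConfigError(f"input file not found: {p}")
            lt = load_life_table(lt_path)
            prof = load_age_profiles(prof_path)
            inputs = ModelInputs(
                life_table=lt,
                earnings=prof["gross_earnings"],
                activity=prof["activity_rate"],
                disability=prof["disability_rate"],
                gp_health=prof["gp_health_cost"],
                consumption=prof.get("consumption"),
            )
        elif self.generator.calibrate:
            inputs, _ = calibrate_fixture(
                p0=self.generator.to_params(), params=params
            )
        else:
            from .synthetic import make_life_table, make_profiles

            gp = self.generator.to_params()
            prof = make_profiles(gp, params.entry_age, params.retirement_age,
                                 params.horizon_age)
            inputs = ModelInputs(
                life_table=make_life_table(gp, params.horizon_age),
                earnings=prof["gross_earnings"],
                activity=prof["activity_rate"],
                disability=prof["disability_rate"],
                gp_health=prof["gp_health_cost"],
                consumption=prof["consumption"],
            )
        from dataclasses import replace

        return replace(
            inputs,
            attack_costs=self.attack_table(),
            management_costs=self.management_costs.to_set(),
        )

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path=None) -> RunConfig:
    """Load and validate a YAML/JSON config; ``None`` gives pure defaults."""
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got {type(raw)}")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as e:
        raise ConfigError(str(e)) from e


def dump_config(config: RunConfig, path=None) -> str:
    """Serialize a config back to YAML (round-trips through load_config)."""
    text = yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
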