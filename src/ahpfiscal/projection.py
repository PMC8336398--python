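"""Scenario assembly: annual cashflow ledgers, lifetime summaries and deltas.

A scenario is projected as a year-by-year ledger of nominal streams
(earnings, direct and indirect tax, disability benefit, pension, health
cost) together with the survival weight (conditional on being alive at the
base age) and the start-of-year discount factor for each age. Lifetime
totals are the survival-weighted, discounted sums; scenario impact is the
fieldwise difference against a general-population comparator projected by
the same engine on the same inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .demographics import (
    AgeSchedule,
    LifeTable,
    conditional_survival,
    discount_factors,
    expected_work_years,
)
from .fiscal import (
    FiscalParameters,
    consumption_tax_stream,
    direct_tax_stream,
    earnings_stream,
    indirect_tax_stream,
    disability_stream,
    pension_stream,
)
from .health import (
    AttackCostTable,
    ManagementCostSet,
    attack_cost_total,
    gp_health_stream,
    patient_health_stream,
)

__all__ = [
    "ScenarioSpec",
    "ModelInputs",
    "CashflowLedger",
    "FiscalSummary",
    "FiscalDelta",
    "project_scenario",
    "summarize",
    "delta",
    "net_fiscal_impact",
    "annual_chart_data",
    "STANDARD_SCENARIOS",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """A clinical life course for the projection.

    The three shipped patient scenarios all start recurrent attacks (12/yr)
    at age 30 with full work disability while attacks are active:

    * ``al_w``   — attacks lifelong, never returns to work;
    * ``a10_w``  — attacks stop after 10 years, still unable to work
      (chronic comorbidities);
    * ``a10_plus_w`` — attacks stop after 10 years, returns to work.

    ``affected=False`` gives the general-population comparator: background
    activity, background disability prevalence, background health costs.
    """

    name: str
    affected: bool = True
    onset_age: int = 30
    attacks_per_year: float = 12.0
    attack_duration_years: Optional[float] = None  # None => lifelong
    able_to_return_to_work: bool = False
    work_disabled_during_attacks: bool = True
    post_attack_work_disabled: bool = True

    def __post_init__(self):
        if self.attacks_per_year < 0:
            raise ValueError("attacks_per_year must be >= 0")
        if self.attack_duration_years is not None and self.attack_duration_years <= 0:
            raise ValueError("attack_duration_years must be > 0 or lifelong (None)")
        if self.able_to_return_to_work and self.attack_duration_years is None:
            raise ValueError(
                f"{self.name}: cannot return to work with lifelong attacks"
            )
        if self.able_to_return_to_work and self.post_attack_work_disabled:
            raise ValueError(
                f"{self.name}: able_to_return_to_work contradicts "
                "post_attack_work_disabled"
            )

    @property
    def recovery_age(self) -> Optional[int]:
        """First age with attacks fully over (ceiling of onset + duration)."""
        if self.attack_duration_years is None:
            return None
        return int(np.ceil(self.onset_age + self.attack_duration_years))

    @classmethod
    def general_population(cls) -> "ScenarioSpec":
        return cls(name="gp", affected=False, attacks_per_year=0.0,
                   attack_duration_years=None,
                   work_disabled_during_attacks=False,
                   post_attack_work_disabled=False)


def _standard_scenarios() -> dict[str, ScenarioSpec]:
    return {
        "gp": ScenarioSpec.general_population(),
        "al_w": ScenarioSpec(name="al_w", attack_duration_years=None),
        "a10_w": ScenarioSpec(name="a10_w", attack_duration_years=10.0),
        "a10_plus_w": ScenarioSpec(
            name="a10_plus_w",
            attack_duration_years=10.0,
            able_to_return_to_work=True,
            post_attack_work_disabled=False,
        ),
    }


STANDARD_SCENARIOS = _standard_scenarios()


@dataclass(frozen=True)
class ModelInputs:
    """Country inputs the engine projects on."""

    life_table: LifeTable
    earnings: AgeSchedule          # gross annual earnings by age
    activity: AgeSchedule          # economic activity rate by age
    disability: AgeSchedule        # background disability prevalence by age
    gp_health: AgeSchedule         # background per-capita health cost by age
    consumption: Optional[AgeSchedule] = None  # VAT base (average_consumption)
    attack_costs: Optional[AttackCostTable] = None
    management_costs: ManagementCostSet = ManagementCostSet()

    def consumption_schedule(self, params: FiscalParameters) -> AgeSchedule:
        """VAT base; defaults to average disposable income (1-wedge) x gross."""
        if self.consumption is not None:
            return self.consumption
        return AgeSchedule(
            self.earnings.ages,
            (1.0 - params.tax_wedge) * self.earnings.values,
        )

    def attack_cost(self) -> float:
        from .health import default_attack_cost_table

        table = self.attack_costs or default_attack_cost_table()
        return attack_cost_total(table)


@dataclass(frozen=True)
class CashflowLedger:
    """Per-age nominal streams plus survival and discount weights."""

    frame: pd.DataFrame  # index: age; nominal streams + survival + discount
    spec: ScenarioSpec
    params: FiscalParameters
    work_activity: AgeSchedule  # activity actually applied (0 outside work ages)

    STREAMS = ("earnings", "direct_tax", "indirect_tax",
               "disability", "pension", "health_cost")

    def discounted(self) -> pd.DataFrame:
        """Streams after survival weighting and discounting."""
        w = self.frame["survival"] * self.frame["discount"]
        return self.frame[list(self.STREAMS)].mul(w, axis=0)


_SUMMARY_FIELDS = (
    "disability_transfers", "pension_costs", "health_costs",
    "sum_government_costs", "lifetime_earnings", "gross_tax", "work_years",
)


@dataclass(frozen=True)
class FiscalSummary:
    """Lifetime survival-weighted discounted totals (one results column)."""

    disability_transfers: float
    pension_costs: float
    health_costs: float
    sum_government_costs: float
    lifetime_earnings: float
    gross_tax: float
    work_years: float
    name: str = ""

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in _SUMMARY_FIELDS}


@dataclass(frozen=True)
class FiscalDelta:
    """Scenario-minus-comparator differences (one 'change' column)."""

    disability_transfers: float
    pension_costs: float
    health_costs: float
    sum_government_costs: float
    lifetime_earnings: float
    gross_tax: float
    work_years: float
    societal_cost: float  # foregone gross earnings, human-capital approach
    name: str = ""

    def as_dict(self) -> dict[str, float]:
        d = {f: getattr(self, f) for f in _SUMMARY_FIELDS}
        d["societal_cost"] = self.societal_cost
        return d


def _work_ages_and_disability(
    spec: ScenarioSpec, inputs: ModelInputs, params: FiscalParameters
) -> tuple[set[int], AgeSchedule]:
    """Ages worked (at background activity) and disabled fraction by age."""
    all_work = set(range(params.entry_age, params.retirement_age))
    background = inputs.disability
    ages = params.model_ages
    if not spec.affected:
        frac = np.array([background.at(int(a), default=0.0) for a in ages])
        return all_work, AgeSchedule(ages, frac)

    work: set[int] = set(range(params.entry_age, min(spec.onset_age,
                                                     params.retirement_age)))
    recovery = spec.recovery_age
    if spec.able_to_return_to_work and recovery is not None:
        work |= set(range(max(recovery, params.entry_age), params.retirement_age))
    if not spec.work_disabled_during_attacks:
        # symptomatic-style course: attacks do not remove the patient from work
        work = all_work

    frac = np.empty(len(ages))
    for i, a in enumerate(ages):
        bg = background.at(int(a), default=0.0)
        if a < spec.onset_age:
            frac[i] = bg
        elif recovery is None or a < recovery:
            frac[i] = 1.0 if spec.work_disabled_during_attacks else bg
        else:
            frac[i] = 1.0 if spec.post_attack_work_disabled else bg
    return work, AgeSchedule(ages, np.clip(frac, 0.0, 1.0))


def project_scenario(
    spec: ScenarioSpec, inputs: ModelInputs, params: FiscalParameters
) -> CashflowLedger:
    """Compose all streams for one scenario into an annual ledger."""
    ages = params.model_ages
    work, disabled_frac = _work_ages_and_disability(spec, inputs, params)

    earn = earnings_stream(inputs.earnings, params, work, inputs.activity)
    direct = direct_tax_stream(earn, params.tax_wedge)
    if params.indirect_tax_basis == "average_consumption":
        indirect = consumption_tax_stream(
            inputs.consumption_schedule(params), params
        )
    else:
        indirect = indirect_tax_stream(earn, direct, params.vat_rate)
    disab = disability_stream(disabled_frac, params)
    pens = pension_stream(params)
    if spec.affected:
        health = patient_health_stream(
            spec, inputs.attack_cost(), inputs.management_costs, params
        )
    else:
        health = gp_health_stream(inputs.gp_health, params)

    surv_sched = conditional_survival(
        inputs.life_table, params.base_age, params.horizon_age
    )
    survival = np.array([surv_sched.at(int(a), default=1.0) for a in ages])
    discount = discount_factors(ages, params.discount_rate, params.base_age)

    frame = pd.DataFrame(
        {
            "earnings": earn.amounts,
            "direct_tax": direct.amounts,
            "indirect_tax": indirect.amounts,
            "disability": disab.amounts,
            "pension": pens.amounts,
            "health_cost": health.amounts,
            "survival": survival,
            "discount": discount,
        },
        index=pd.Index(ages, name="age"),
    )
    applied_activity = np.array(
        [inputs.activity.at(int(a), default=0.0) if int(a) in work else 0.0
         for a in ages]
    )
    return CashflowLedger(
        frame=frame,
        spec=spec,
        params=params,
        work_activity=AgeSchedule(ages, applied_activity),
    )


def summarize(ledger: CashflowLedger) -> FiscalSummary:
    """Lifetime totals of a ledger (survival-weighted, discounted)."""
    params = ledger.params
    disc = ledger.discounted()
    totals = disc.sum()
    surv = AgeSchedule(
        ledger.frame.index.to_numpy(), ledger.frame["survival"].to_numpy()
    )
    work_years = expected_work_years(
        ledger.work_activity,
        surv,
        params.discount_rate,
        params.entry_age,
        params.retirement_age,
        params.base_age,
    )
    disability = float(totals["disability"])
    pension = float(totals["pension"])
    health = float(totals["health_cost"])
    return FiscalSummary(
        disability_transfers=disability,
        pension_costs=pension,
        health_costs=health,
        sum_government_costs=disability + pension + health,
        lifetime_earnings=float(totals["earnings"]),
        gross_tax=float(totals["direct_tax"] + totals["indirect_tax"]),
        work_years=work_years,
        name=ledger.spec.name,
    )


def delta(scenario: FiscalSummary, gp: FiscalSummary) -> FiscalDelta:
    """Fieldwise scenario minus comparator; societal cost = earnings foregone."""
    vals = {
        f: getattr(scenario, f) - getattr(gp, f) for f in _SUMMARY_FIELDS
    }
    return FiscalDelta(
        **vals,
        societal_cost=gp.lifetime_earnings - scenario.lifetime_earnings,
        name=f"{scenario.name}-{gp.name}" if scenario.name else "",
    )


def net_fiscal_impact(d: FiscalDelta) -> float:
    """Incremental government outlays plus foregone tax revenue (EUR)."""
    return d.sum_government_costs - d.gross_tax


def annual_chart_data(
    ledger: CashflowLedger, gp_ledger: CashflowLedger
) -> pd.DataFrame:
    """Per-age discounted differences versus the comparator.

    Columns: ``gross_tax`` (scenario minus comparator; negative when the
    scenario pays less tax) and the government cost categories
    ``disability_transfers``, ``pension_costs``, ``health_costs``. Each
    column sums to the matching lifetime-delta field, so the table stacks
    directly into an annual cashflow chart (taxes up, costs down).
    """
    if not ledger.frame.index.equals(gp_ledger.frame.index):
        raise ValueError("ledgers are not aligned on ages")
    d = ledger.discounted()
    g = gp_ledger.discounted()
    out = pd.DataFrame(index=ledger.frame.index)
    out["gross_tax"] = (d["direct_tax"] + d["indirect_tax"]) - (
        g["direct_tax"] + g["indirect_tax"]
    )
    out["disability_transfers"] = d["disability"] - g["disability"]
    out["pension_costs"] = d["pension"] - g["pension"]
    out["health_costs"] = d["health_cost"] - g["health_cost"]
    return out
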