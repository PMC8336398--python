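"""Health-cost inputs: attack micro-costing and annual management costs.

The cost of one hospital-treated attack is built bottom-up from resource
lines (share of patients receiving the resource x units used x Belgian unit
cost). Published line totals, where available, take precedence over the
product of their own rounded factors, so the shipped table reproduces the
reference per-attack total; the factors remain usable for new lines.

Annual disease-management costs are carried per attack-frequency category
(asymptomatic / symptomatic / recurrent / severe); the recurrent and severe
categories share the same cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .demographics import AgeSchedule
from .fiscal import CashStream, FiscalParameters

__all__ = [
    "AttackCostLine",
    "AttackCostTable",
    "ManagementCostSet",
    "line_cost",
    "attack_cost_total",
    "default_attack_cost_table",
    "patient_health_stream",
    "gp_health_stream",
]


@dataclass(frozen=True)
class AttackCostLine:
    """One resource consumed during a hospitalized attack."""

    resource: str
    pct_receiving: float = 1.0
    units: float = 0.0
    unit_cost: float = 0.0
    canonical_total: Optional[float] = None

    def __post_init__(self):
        if not (0.0 <= self.pct_receiving <= 1.0):
            raise ValueError(
                f"{self.resource}: pct_receiving must be in [0, 1]"
            )
        if self.units < 0 or self.unit_cost < 0:
            raise ValueError(f"{self.resource}: units/unit_cost must be >= 0")
        if self.canonical_total is not None and self.canonical_total < 0:
            raise ValueError(f"{self.resource}: canonical_total must be >= 0")


@dataclass(frozen=True)
class AttackCostTable:
    lines: tuple[AttackCostLine, ...]

    def __post_init__(self):
        lines = tuple(self.lines)
        names = [ln.resource for ln in lines]
        if len(set(names)) != len(names):
            raise ValueError("attack cost table has duplicate resource labels")
        object.__setattr__(self, "lines", lines)


def line_cost(line: AttackCostLine) -> float:
    """Euro cost of one resource line per attack."""
    if line.canonical_total is not None:
        return float(line.canonical_total)
    return float(line.pct_receiving * line.units * line.unit_cost)


def attack_cost_total(table: AttackCostTable) -> float:
    """Total cost per hospital-treated attack (sum over resource lines)."""
    if not table.lines:
        raise ValueError("attack cost table is empty")
    # fsum: the total is independent of the order of the lines
    return math.fsum(line_cost(ln) for ln in table.lines)


def default_attack_cost_table() -> AttackCostTable:
    """Shipped Belgian per-attack resource use and unit costs (2020 EUR).

    Opioid cover is morphine 5 mg hourly as required over 36 h; hemin is
    dosed 3 mg/kg once daily for 3 days plus a repeat course; hemin
    side-effects enter as a single aggregate line (extended stay).
    """
    return AttackCostTable((
        AttackCostLine("Opioids (morphine)", 1.00, 18, 0.68, 12.29),
        AttackCostLine("Hemin", 1.00, 4, 592.10, 2_368.39),
        AttackCostLine("Hemin side effects", 1.00, 1, 102.45, 102.45),
        AttackCostLine("Albumin", 1.00, 4, 29.63, 118.52),
        AttackCostLine("Hospital admission, ER", 1.00, 1, 43.69, 43.69),
        AttackCostLine("Hospital admission, ICU", 0.20, 2, 179.69, 69.08),
        AttackCostLine("Hospitalization days", 1.00, 7, 492.27, 3_440.42),
        AttackCostLine("Blood test", 1.00, 1, 26.00, 26.00),
    ))


@dataclass(frozen=True)
class ManagementCostSet:
    """Annual disease-management cost (EUR/yr) per attack-frequency category."""

    asymptomatic: float = 6_192.0
    symptomatic: float = 20_930.0
    recurrent: float = 34_252.0
    severe: float = 34_252.0

    def __post_init__(self):
        vals = (self.asymptomatic, self.symptomatic, self.recurrent, self.severe)
        if any(v < 0 for v in vals):
            raise ValueError("management costs must be non-negative")
        if not (self.recurrent >= self.symptomatic >= self.asymptomatic):
            raise ValueError(
                "expected recurrent >= symptomatic >= asymptomatic costs"
            )

    def scaled(self, factor: float) -> "ManagementCostSet":
        return ManagementCostSet(
            self.asymptomatic * factor,
            self.symptomatic * factor,
            self.recurrent * factor,
            self.severe * factor,
        )


def patient_health_stream(
    spec,
    attack_cost: float,
    mgmt: ManagementCostSet,
    params: FiscalParameters,
) -> CashStream:
    """Nominal annual health cost of an affected individual.

    During active-attack years the cost is ``attacks_per_year x attack_cost``
    plus the recurrent-category management cost; after attacks stop the
    patient continues to incur the symptomatic-category management cost for
    chronic comorbidities (never the population background cost on top).
    A fractional final attack year is prorated between the two regimes.
    Everything compounds at the healthcare-inflation rate over model time.
    """
    ages = params.model_ages
    amounts = np.zeros(len(ages))
    onset = spec.onset_age
    duration = spec.attack_duration_years  # None => lifelong
    infl = (1.0 + params.health_inflation) ** np.maximum(ages - params.base_age, 0)
    active_cost = spec.attacks_per_year * attack_cost + mgmt.recurrent
    post_cost = mgmt.symptomatic
    for i, a in enumerate(ages):
        if a < onset:
            continue
        years_in = a - onset  # whole years since onset at start of this age
        if duration is None:
            amounts[i] = active_cost * infl[i]
        elif years_in + 1 <= duration:
            amounts[i] = active_cost * infl[i]
        elif years_in < duration:
            frac = duration - years_in
            amounts[i] = (frac * active_cost + (1 - frac) * post_cost) * infl[i]
        else:
            amounts[i] = post_cost * infl[i]
    return CashStream(ages, amounts)


def gp_health_stream(
    gp_costs: AgeSchedule, params: FiscalParameters
) -> CashStream:
    """Background per-capita health expenditure of an unaffected individual.

    Counted from the base age (the comparison window) and compounded at the
    healthcare-inflation rate.
    """
    ages = params.model_ages
    amounts = np.zeros(len(ages))
    infl = (1.0 + params.health_inflation) ** np.maximum(ages - params.base_age, 0)
    for i, a in enumerate(ages):
        if a >= params.base_age:
            try:
                amounts[i] = gp_costs.at(int(a)) * infl[i]
            except KeyError:
                raise ValueError(f"background health profile missing age {a}")
    return CashStream(ages, amounts)
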