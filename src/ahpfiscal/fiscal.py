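"""Earnings, tax and transfer cash streams under a government perspective.

Streams are *nominal*: per-age euro amounts before survival weighting and
discounting, which the projection engine applies when it assembles a ledger.
Every stream covers the full model window (workforce entry age to the
horizon) with zeros outside the ages where it applies, so streams align by
construction.

Two indirect-tax bases are supported:

``average_consumption`` (default)
    VAT is levied on an age-specific average consumption (disposable-income)
    schedule that does not depend on the individual's own work status —
    consumption continues out of transfer income when out of work, so the
    indirect-tax stream is identical across clinical scenarios and the
    comparator, and any between-scenario gross-tax difference is the tax
    wedge applied to the earnings difference.

``own_disposable``
    VAT is levied on the individual's own disposable earnings
    (gross earnings minus direct tax), i.e. full consumption of own
    disposable income and no consumption tax while out of work.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .demographics import AgeSchedule

__all__ = [
    "FiscalParameters",
    "CashStream",
    "earnings_stream",
    "direct_tax_stream",
    "indirect_tax_stream",
    "consumption_tax_stream",
    "disability_stream",
    "pension_stream",
]

IndirectTaxBasis = Literal["average_consumption", "own_disposable"]


@dataclass(frozen=True)
class FiscalParameters:
    """Fiscal constants of the Belgian setting.

    Rates are decimal fractions per year, money in 2020 euros. Defaults are
    the published Belgian inputs: a 52.7% tax wedge, 21% VAT, 1.3% annual
    wage growth, 0.62% transfer (cost) inflation, 2% healthcare inflation,
    a 3% discount rate, a €14,400 average retirement pension and a €13,613
    average disability benefit. The model runs from workforce entry (18) to
    the horizon (100); comparisons start at the base age (30, diagnosis)
    and retirement is at 65.
    """

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
    # share of symptomatic (non-recurrent) patients unable to work; used only
    # by user-defined symptomatic scenarios, never by the three shipped ones
    symptomatic_work_disability: float = 0.5
    indirect_tax_basis: IndirectTaxBasis = "average_consumption"

    def __post_init__(self):
        for name in ("tax_wedge", "vat_rate", "wage_growth",
                     "transfer_inflation", "health_inflation", "discount_rate",
                     "symptomatic_work_disability"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1); got {v!r}")
        if self.tax_wedge + self.vat_rate * (1 - self.tax_wedge) >= 1.0:
            raise ValueError("combined direct + indirect tax rate must be < 1")
        if not (self.entry_age < self.base_age < self.retirement_age
                < self.horizon_age):
            raise ValueError(
                "need entry_age < base_age < retirement_age < horizon_age; got "
                f"{self.entry_age}/{self.base_age}/{self.retirement_age}/"
                f"{self.horizon_age}"
            )
        for name in ("pension_annual", "disability_annual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.indirect_tax_basis not in ("average_consumption", "own_disposable"):
            raise ValueError(
                f"unknown indirect_tax_basis {self.indirect_tax_basis!r}"
            )

    @property
    def model_ages(self) -> np.ndarray:
        return np.arange(self.entry_age, self.horizon_age + 1)

    def with_(self, **kwargs) -> "FiscalParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CashStream:
    """Nominal euro amounts per age (pre-discount, pre-survival)."""

    ages: np.ndarray
    amounts: np.ndarray

    def __post_init__(self):
        sched = AgeSchedule(self.ages, self.amounts)  # reuse validation
        object.__setattr__(self, "ages", sched.ages)
        object.__setattr__(self, "amounts", sched.values)

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    def at(self, age: int) -> float:
        if age < self.ages[0] or age > self.ages[-1]:
            raise KeyError(f"stream has no amount for age {age}")
        return float(self.amounts[age - self.ages[0]])

    def _check_aligned(self, other: "CashStream"):
        if len(self.ages) != len(other.ages) or self.ages[0] != other.ages[0]:
            raise ValueError("cash streams are not aligned on ages")


def _growth_factors(ages: np.ndarray, rate: float, base_age: int) -> np.ndarray:
    # exponent floored at 0: pre-base amounts are carried at base-year level
    t = np.maximum(ages - base_age, 0)
    return (1.0 + rate) ** t


def earnings_stream(
    profile: AgeSchedule,
    params: FiscalParameters,
    work_ages,
    activity: AgeSchedule,
) -> CashStream:
    """Gross annual earnings over the model window.

    For each age in ``work_ages`` below retirement, the age-specific gross
    earnings are scaled by the age-specific economic activity rate and by
    compounding wage growth over model time (floored at the base age).
    """
    ages = params.model_ages
    work = set(int(a) for a in work_ages)
    if work - set(int(a) for a in ages):
        raise ValueError("work_ages outside the model window")
    amounts = np.zeros(len(ages))
    growth = _growth_factors(ages, params.wage_growth, params.base_age)
    for i, a in enumerate(ages):
        if a in work and a < params.retirement_age:
            try:
                g = profile.at(int(a))
                act = activity.at(int(a))
            except KeyError:
                raise ValueError(f"earnings/activity profile missing age {a}")
            amounts[i] = g * act * growth[i]
    return CashStream(ages, amounts)


def direct_tax_stream(earnings: CashStream, tax_wedge: float) -> CashStream:
    """Direct tax: the tax wedge applied to gross earnings."""
    if not (0.0 <= tax_wedge < 1.0):
        raise ValueError("tax_wedge must be in [0, 1)")
    return CashStream(earnings.ages, earnings.amounts * tax_wedge)


def indirect_tax_stream(
    earnings: CashStream, direct_tax: CashStream, vat_rate: float
) -> CashStream:
    """VAT on disposable income (earnings minus direct tax), fully consumed."""
    earnings._check_aligned(direct_tax)
    return CashStream(
        earnings.ages, vat_rate * (earnings.amounts - direct_tax.amounts)
    )


def consumption_tax_stream(
    consumption: AgeSchedule, params: FiscalParameters
) -> CashStream:
    """VAT on an average-consumption schedule, independent of work status.

    Consumption is counted from the base age onward (the comparison window),
    grows with the wage-growth rate, and — like the earnings it mirrors —
    does not depend on the clinical scenario.
    """
    ages = params.model_ages
    growth = _growth_factors(ages, params.wage_growth, params.base_age)
    amounts = np.zeros(len(ages))
    for i, a in enumerate(ages):
        if a >= params.base_age:
            try:
                c = consumption.at(int(a))
            except KeyError:
                raise ValueError(f"consumption schedule missing age {a}")
            amounts[i] = params.vat_rate * c * growth[i]
    return CashStream(ages, amounts)


def disability_stream(
    disabled_fraction_by_age: AgeSchedule, params: FiscalParameters
) -> CashStream:
    """Disability benefit: fraction disabled x indexed annual benefit.

    Paid from the base age until retirement, when the pension replaces it.
    Benefits are indexed at the transfer-inflation rate over model time.
    """
    frac = disabled_fraction_by_age
    if np.any((frac.values < 0) | (frac.values > 1)):
        raise ValueError("disabled fractions must lie in [0, 1]")
    ages = params.model_ages
    growth = _growth_factors(ages, params.transfer_inflation, params.base_age)
    amounts = np.zeros(len(ages))
    for i, a in enumerate(ages):
        if params.base_age <= a < params.retirement_age:
            amounts[i] = (
                frac.at(int(a), default=0.0)
                * params.disability_annual
                * growth[i]
            )
    return CashStream(ages, amounts)


def pension_stream(params: FiscalParameters) -> CashStream:
    """Indexed retirement pension from retirement age; scenario-invariant."""
    ages = params.model_ages
    growth = _growth_factors(ages, params.transfer_inflation, params.base_age)
    amounts = np.where(
        ages >= params.retirement_age, params.pension_annual * growth, 0.0
    )
    return CashStream(ages, amounts)
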