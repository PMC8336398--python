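"""Synthetic Belgian-like country inputs and fixture calibration.

The projection needs a life table and age profiles (gross earnings, economic
activity, background disability prevalence, per-capita health expenditure)
that national statistics offices publish but that are not redistributable
here. This module generates a stylised stand-in country — Gompertz–Makeham
mortality, a hump-shaped age–earnings profile, an activity plateau that
falls near retirement, disability prevalence and health spending rising
with age — and then calibrates multiplicative scale factors (plus a bounded
mortality tilt) so the general-population comparator reproduces published
Belgian reference lifetime totals. Patient-scenario outputs are then
emergent, not fitted.

Everything is deterministic given the generator parameters (including the
seed, which only matters when optional noise is switched on).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .demographics import AgeSchedule, LifeTable
from .fiscal import FiscalParameters
from .projection import (
    FiscalSummary,
    ModelInputs,
    STANDARD_SCENARIOS,
    project_scenario,
    summarize,
)

__all__ = [
    "CountryGeneratorParams",
    "CalibrationTargets",
    "CalibrationResult",
    "make_life_table",
    "make_profiles",
    "calibrate_fixture",
    "default_fixture",
    "write_fixture",
    "BELGIAN_GP_REFERENCE",
]

#: Published Belgian reference lifetime totals for the general-population
#: comparator (survival-weighted, discounted at 3% from age 30): the
#: calibration surface for the shipped fixture.
BELGIAN_GP_REFERENCE = FiscalSummary(
    disability_transfers=40_277.0,
    pension_costs=83_110.0,
    health_costs=70_218.0,
    sum_government_costs=193_605.0,
    lifetime_earnings=632_367.0,
    gross_tax=434_722.0,
    work_years=25.24,
    name="gp_reference",
)

#: Reference pre-diagnosis (ages 18-29) totals implied by the published
#: never-working-after-onset scenario; used to split the lifetime targets
#: across the age-30 boundary.
PRE_ONSET_EARNINGS_REFERENCE = 284_565.0
PRE_ONSET_WORK_YEARS_REFERENCE = 11.36

#: Published Belgian reference lifetime totals for all four columns
#: (comparator plus the three clinical scenarios). Only the comparator
#: column is a calibration surface; the scenario columns serve as inputs to
#: reference delta arithmetic and as context for diagnostics.
BELGIAN_SCENARIO_REFERENCE: dict[str, FiscalSummary] = {
    "gp": BELGIAN_GP_REFERENCE,
    "al_w": FiscalSummary(287_519.0, 83_110.0, 3_100_534.0, 3_471_163.0,
                          284_565.0, 251_535.0, 11.36, name="al_w_reference"),
    "a10_w": FiscalSummary(287_519.0, 83_110.0, 1_589_502.0, 1_960_131.0,
                           284_565.0, 251_535.0, 11.36, name="a10_w_reference"),
    "a10_plus_w": FiscalSummary(108_335.0, 83_110.0, 1_589_502.0, 1_780_947.0,
                                509_141.0, 369_819.0, 20.88,
                                name="a10_plus_w_reference"),
}


@dataclass(frozen=True)
class CountryGeneratorParams:
    """Shape parameters of the stylised country.

    Mortality is Gompertz–Makeham, ``qx(a) = min(1, A + B * c**a)`` with a
    closed table at age 100. Earnings follow a log-quadratic hump peaking
    mid-career; activity ramps up through the early twenties, plateaus, and
    declines from 55 to retirement; disability prevalence grows
    exponentially with age; background health spending compounds per year
    of age. ``noise_sd`` adds seeded lognormal jitter to the earnings and
    health profiles (off by default: the shipped fixture is deterministic).
    """

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
    noise_sd: float = 0.0
    seed: int = 20210804

    def __post_init__(self):
        if min(self.makeham_a, self.gompertz_b) < 0 or self.gompertz_c <= 1:
            raise ValueError("mortality parameters must be positive, c > 1")
        if not (0 < self.activity_plateau <= 1):
            raise ValueError("activity_plateau must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_life_table(p: CountryGeneratorParams, max_age: int = 100) -> LifeTable:
    """Gompertz–Makeham life table over ages 0..max_age (closed at the top)."""
    ages = np.arange(0, max_age + 1)
    qx = np.minimum(1.0, p.makeham_a + p.gompertz_b * p.gompertz_c ** ages)
    if np.any(qx[ages < 60] >= 1.0):
        raise ValueError(
            "mortality parameters give certain death before age 60; "
            "check makeham_a / gompertz_b / gompertz_c"
        )
    qx[-1] = 1.0
    return LifeTable(ages, qx)


def make_profiles(
    p: CountryGeneratorParams,
    entry_age: int = 18,
    retirement_age: int = 65,
    horizon_age: int = 100,
) -> dict[str, AgeSchedule]:
    """Age profiles over the model window ``entry_age..horizon_age``.

    Returns schedules keyed ``gross_earnings``, ``activity_rate``,
    ``disability_rate``, ``gp_health_cost`` and ``consumption`` (the
    average-consumption VAT base: the disposable share of gross earnings,
    reduced after retirement).
    """
    rng = np.random.default_rng(p.seed)
    ages = np.arange(entry_age, horizon_age + 1)

    earnings = p.earnings_peak * np.exp(
        -p.earnings_curvature * (ages - p.earnings_peak_age) ** 2
    )
    if p.noise_sd > 0:
        earnings = earnings * rng.lognormal(0.0, p.noise_sd, len(ages))
        # keep the documented anchor exact even under jitter
        earnings[ages == p.earnings_peak_age] = p.earnings_peak

    ramp = np.clip((ages - entry_age + 1) / 8.0, 0.0, 1.0)
    tail = np.clip(
        1.0 - 0.85 * (ages - p.activity_decline_age)
        / max(retirement_age - 1 - p.activity_decline_age, 1),
        0.0, 1.0,
    )
    activity = p.activity_plateau * ramp * tail
    activity[ages >= retirement_age] = 0.0

    disability = np.minimum(
        1.0, p.disability_base * np.exp(p.disability_slope * (ages - entry_age))
    )

    gp_cost = p.gp_cost_base * (1.0 + p.gp_cost_growth_per_age) ** (ages - entry_age)
    if p.noise_sd > 0:
        gp_cost = gp_cost * rng.lognormal(0.0, p.noise_sd, len(ages))

    consumption = p.consumption_disposable_share * earnings
    retired = ages >= retirement_age
    consumption[retired] = (
        p.consumption_disposable_share
        * earnings[ages == retirement_age - 1][0]
        * p.consumption_retirement_factor
    )

    return {
        "gross_earnings": AgeSchedule(ages, earnings),
        "activity_rate": AgeSchedule(ages, np.clip(activity, 0.0, 1.0)),
        "disability_rate": AgeSchedule(ages, disability),
        "gp_health_cost": AgeSchedule(ages, gp_cost),
        "consumption": AgeSchedule(ages, consumption),
    }


@dataclass(frozen=True)
class CalibrationTargets:
    """Comparator lifetime totals to hit, plus the pre-diagnosis split."""

    gp: FiscalSummary = BELGIAN_GP_REFERENCE
    pre_onset_earnings: float = PRE_ONSET_EARNINGS_REFERENCE
    pre_onset_work_years: float = PRE_ONSET_WORK_YEARS_REFERENCE


@dataclass(frozen=True)
class CalibrationResult:
    scales: dict
    residuals: dict  # relative residual per comparator target
    converged: bool
    achieved: FiscalSummary
    diagnostics: dict  # soft checks (pre-onset split), not gated


class CalibrationError(RuntimeError):
    def __init__(self, residuals):
        self.residuals = residuals
        worst = max(residuals.items(), key=lambda kv: abs(kv[1]))
        super().__init__(
            f"calibration did not converge; worst residual {worst[0]}="
            f"{worst[1]:+.4%}; all residuals: "
            + ", ".join(f"{k}={v:+.4%}" for k, v in residuals.items())
        )


def _tilted_table(lt: LifeTable, tilt: float) -> LifeTable:
    qx = np.minimum(1.0, lt.qx * tilt)
    qx[-1] = 1.0
    return LifeTable(lt.ages, qx)


def _split_scale(values: np.ndarray, ages: np.ndarray, cut: int,
                 s_pre: float, s_post: float, cap: float | None = None):
    out = np.where(ages < cut, values * s_pre, values * s_post)
    if cap is not None:
        out = np.minimum(out, cap)
    return out


def _solve_increasing(fn, target, lo=1e-9, hi=1.0, max_hi=1e9):
    """Root of fn(s) = target for a non-decreasing fn, expanding hi as needed."""
    while fn(hi) < target and hi < max_hi:
        hi *= 2.0
    if fn(hi) < target:
        raise ValueError("calibration target unreachable (schedule saturates)")
    return brentq(lambda x: fn(x) - target, lo, hi, xtol=1e-12, maxiter=200)


def calibrate_fixture(
    targets: CalibrationTargets | None = None,
    p0: CountryGeneratorParams | None = None,
    params: FiscalParameters | None = None,
    tol: float = 1e-4,
) -> tuple[ModelInputs, CalibrationResult]:
    """Scale the generated country so the comparator hits the targets.

    Free knobs, solved in a triangular order (each knob's target is
    unaffected by the knobs solved after it): a mortality tilt (multiplies
    every qx, bounded so qx stays in [0, 1]) matching pension costs, which
    depend on survival alone; activity scales before/after the base age
    (capped at 1 per age) matching the pre-diagnosis and remaining work
    years; earnings scales before/after the base age matching the earnings
    split; a background-disability scale (capped at prevalence 1); a
    background-health scale; and a consumption scale matching gross tax once
    earnings are fixed. Every solve is run through the projection engine
    itself, so calibration cannot drift from the model it serves. A final
    engine pass verifies all comparator targets; a :class:`CalibrationError`
    carrying the residuals is raised if any remain outside ``tol``.
    """
    targets = targets or CalibrationTargets()
    p0 = p0 or CountryGeneratorParams()
    params = params or FiscalParameters()

    lt0 = make_life_table(p0, max_age=params.horizon_age)
    prof = make_profiles(
        p0, params.entry_age, params.retirement_age, params.horizon_age
    )
    ages = prof["activity_rate"].ages
    base = params.base_age

    post_wy_target = targets.gp.work_years - targets.pre_onset_work_years
    post_earn_target = targets.gp.lifetime_earnings - targets.pre_onset_earnings
    indirect_target = (
        targets.gp.gross_tax - params.tax_wedge * targets.gp.lifetime_earnings
    )
    if post_wy_target <= 0 or post_earn_target <= 0 or indirect_target <= 0:
        raise ValueError("calibration targets are mutually inconsistent")

    s = dict(act_pre=1.0, act_post=1.0, earn_pre=1.0, earn_post=1.0,
             disability=1.0, health=1.0, consumption=1.0, tilt=1.0)

    def run(**over):
        kw = {**s, **over}
        inputs = _build_inputs(lt0, prof, ages, base, **kw)
        gp = summarize(project_scenario(STANDARD_SCENARIOS["gp"], inputs, params))
        alw = summarize(project_scenario(STANDARD_SCENARIOS["al_w"], inputs, params))
        return gp, alw

    # 1. mortality tilt: pension costs depend only on survival and decrease
    #    in the tilt
    hi_t = 1.0
    while run(tilt=hi_t)[0].pension_costs > targets.gp.pension_costs and hi_t < 64:
        hi_t *= 2.0
    s["tilt"] = brentq(
        lambda m: run(tilt=m)[0].pension_costs - targets.gp.pension_costs,
        0.02, hi_t, xtol=1e-10,
    )

    # 2. pre-base activity -> pre-diagnosis work years (AL-W work window)
    s["act_pre"] = _solve_increasing(
        lambda x: run(act_pre=x)[1].work_years, targets.pre_onset_work_years
    )
    # 3. post-base activity -> remaining comparator work years
    s["act_post"] = _solve_increasing(
        lambda x: (lambda gp, alw: gp.work_years - alw.work_years)(
            *run(act_post=x)
        ),
        post_wy_target,
    )
    # 4-5. earnings scales are exactly linear given the activity profile
    gp_now, alw_now = run()
    s["earn_pre"] *= targets.pre_onset_earnings / alw_now.lifetime_earnings
    s["earn_post"] *= post_earn_target / (
        gp_now.lifetime_earnings - alw_now.lifetime_earnings
    )
    # 6. background disability (prevalence capped at 1, hence a solve)
    s["disability"] = _solve_increasing(
        lambda x: run(disability=x)[0].disability_transfers,
        targets.gp.disability_transfers,
    )
    # 7-8. background health and consumption are exactly linear
    gp_now, _ = run()
    s["health"] *= targets.gp.health_costs / gp_now.health_costs
    indirect_now = (
        gp_now.gross_tax - params.tax_wedge * gp_now.lifetime_earnings
    )
    s["consumption"] *= indirect_target / indirect_now

    gp_sum, alw_sum = run()
    residuals = {
        "disability_transfers": gp_sum.disability_transfers
        / targets.gp.disability_transfers - 1,
        "pension_costs": gp_sum.pension_costs / targets.gp.pension_costs - 1,
        "health_costs": gp_sum.health_costs / targets.gp.health_costs - 1,
        "sum_government_costs": gp_sum.sum_government_costs
        / targets.gp.sum_government_costs - 1,
        "lifetime_earnings": gp_sum.lifetime_earnings
        / targets.gp.lifetime_earnings - 1,
        "gross_tax": gp_sum.gross_tax / targets.gp.gross_tax - 1,
        "work_years": gp_sum.work_years / targets.gp.work_years - 1,
    }
    if max(abs(r) for r in residuals.values()) >= tol:
        raise CalibrationError(residuals)

    diagnostics = {
        "pre_onset_earnings": alw_sum.lifetime_earnings,
        "pre_onset_earnings_rel": alw_sum.lifetime_earnings
        / targets.pre_onset_earnings - 1,
        "pre_onset_work_years": alw_sum.work_years,
    }
    result = CalibrationResult(
        scales=dict(s),
        residuals=residuals,
        converged=True,
        achieved=gp_sum,
        diagnostics=diagnostics,
    )
    inputs = _build_inputs(lt0, prof, ages, base, **s)
    return inputs, result


def _build_inputs(
    lt0: LifeTable, prof: dict, ages: np.ndarray, base: int,
    act_pre: float = 1.0, act_post: float = 1.0,
    earn_pre: float = 1.0, earn_post: float = 1.0,
    disability: float = 1.0, health: float = 1.0,
    consumption: float = 1.0, tilt: float = 1.0,
) -> ModelInputs:
    act = _split_scale(prof["activity_rate"].values, ages, base,
                       act_pre, act_post, cap=1.0)
    earn = _split_scale(prof["gross_earnings"].values, ages, base,
                        earn_pre, earn_post)
    return ModelInputs(
        life_table=_tilted_table(lt0, tilt),
        earnings=AgeSchedule(ages, earn),
        activity=AgeSchedule(ages, act),
        disability=AgeSchedule(
            ages, np.minimum(prof["disability_rate"].values * disability, 1.0)
        ),
        gp_health=AgeSchedule(ages, prof["gp_health_cost"].values * health),
        consumption=AgeSchedule(
            ages, prof["consumption"].values * consumption
        ),
    )


_FIXTURE_CACHE: dict = {}


def default_fixture(
    seed: int = 20210804,
) -> tuple[ModelInputs, CalibrationResult]:
    """The shipped calibrated fixture (cached per seed)."""
    if seed not in _FIXTURE_CACHE:
        _FIXTURE_CACHE[seed] = calibrate_fixture(
            p0=CountryGeneratorParams(seed=seed)
        )
    return _FIXTURE_CACHE[seed]


def write_fixture(inputs: ModelInputs, out_dir) -> dict[str, Path]:
    """Write ``life_table.csv`` and ``profiles.csv`` for a fixture."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lt_path = out / "life_table.csv"
    inputs.life_table.to_frame().to_csv(lt_path, index=False, float_format="%.12g")
    prof_path = out / "profiles.csv"
    df = pd.DataFrame(
        {
            "age": inputs.earnings.ages,
            "gross_earnings": inputs.earnings.values,
            "activity_rate": inputs.activity.values,
            "disability_rate": inputs.disability.values,
            "gp_health_cost": inputs.gp_health.values,
        }
    )
    if inputs.consumption is not None:
        df["consumption"] = inputs.consumption.values
    df.to_csv(prof_path, index=False, float_format="%.12g")
    return {"life_table": lt_path, "profiles": prof_path}
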