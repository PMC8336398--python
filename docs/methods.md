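# Methods

## The accounting frame

The model takes the *government perspective*: it counts only cash flows to
and from the state attributable to one individual — direct tax on labour
earnings, indirect (consumption) tax, disability benefits, the retirement
pension, and publicly financed health costs. Societal cost is reported
separately as gross earnings foregone (human-capital approach). The unit of
analysis is a single individual (cohort n = 1); nothing is scaled to a
population.

The model runs in whole years of age from workforce entry (18) to the
horizon (100). The comparison window opens at the base age 30 — the age of
diagnosis — where survival is conditioned ($S(30)=1$) and to which all flows
are discounted at 3 %/yr. Three conventions matter and are fixed:

* **Timing.** Cashflows fall at the start of each model year, so the
  discount factor at age $a$ is $(1+r)^{-(a-30)}$ (an annuity-due). Nothing
  in the source setting pins the timing; start-of-year is the simplest
  choice and is applied uniformly.
* **Pre-base flows.** Earnings and work years accrued at ages 18–29 enter
  lifetime totals with discount factor clamped to 1 (no upward
  compounding) and survival 1 (being alive at 30 implies having been alive
  earlier). Government cost streams (disability, pension, health) are
  counted from age 30 only.
* **Indexation vs. discounting.** Earnings (and the consumption VAT base)
  grow at 1.3 %/yr of *model time*, transfers are indexed at 0.62 %/yr,
  health expenditure at 2 %/yr, all compounded from age 30 (exponent
  floored at 0 before it). These are distinct processes applied on top of
  the cross-sectional age profiles.

## Streams

* **Earnings** $E(a) = g(a)\,\alpha(a)\,(1.013)^{a-30}$ for ages the
  scenario has the person in work and below retirement (65), where $g$ is
  the age–earnings profile and $\alpha$ the economic activity rate.
* **Direct tax** $T_d(a) = \theta E(a)$ with tax wedge $\theta = 52.7\%$.
* **Indirect tax.** Two bases are implemented.
  *Default — average consumption*: VAT (21 %) on an age-specific average
  consumption (disposable-income) schedule that does not depend on the
  individual's own work status; consumption continues out of transfer
  income when out of work. Under this basis the indirect-tax stream is
  identical across scenarios, so every between-scenario gross-tax
  difference equals $\theta\,\Delta E$ — which is exactly the pattern the
  published scenario columns exhibit (their gross-tax column is affine in
  lifetime earnings with slope 0.527). *Alternative — own disposable*:
  VAT on the individual's own $E - T_d$, i.e. full consumption of own
  disposable income and no consumption tax while out of work. The basis is
  a `FiscalParameters` switch; only the default reproduces the reference
  gross-tax level and deltas simultaneously.
* **Disability benefit**: fraction disabled × €13,613, indexed, paid from
  age 30 until retirement, where the pension replaces it. The comparator
  uses the background age-specific disability prevalence; patient scenarios
  use fraction 1.0 during work-disabled years and the background rate when
  recovered. (A 50 % work-disability share for symptomatic, non-recurrent
  disease is carried as a configurable constant for user-defined scenarios.)
* **Pension**: €14,400, indexed, from 65 for everyone — scenario-invariant
  by construction, which is the only composition consistent with identical
  pension totals across all published columns.
* **Patient health costs**: during active-attack years,
  (attacks/yr × cost per attack) + the recurrent-category management cost
  (€34,252/yr); after attacks stop, the symptomatic-category management
  cost (€20,930/yr) for chronic comorbidities — never the population
  background cost on top. A fractional final attack year (from the ±25 %
  duration variation) is prorated within the year. All patient health costs
  compound at the 2 % healthcare-inflation rate. What annual cost applies
  after attacks stop is genuinely open; symptomatic-level cost is a
  modelling choice, bracketed by zero and the recurrent level.
* **Comparator health costs**: background age-specific per-capita
  expenditure, inflated at 2 %, from age 30.

## Attack micro-costing

One hospital-treated attack is costed bottom-up from eight resource lines
(share receiving × units × Belgian unit cost): opioids, hemin (4 doses at
€592.10), an aggregate hemin adverse-event line (€102.45, an extended
stay), albumin, ER and ICU admission, seven bed-days, and a blood test.
Three published line totals are inconsistent with their own rounded factors
(e.g. ICU: 0.20 × 2 × €179.69 = €71.88 vs the printed €69.08), so printed
line totals take precedence where present ("canonical totals") and the
factors remain available for user-defined lines. The table sums to
€6,180.84. All 12 annual attacks are treated as hospitalized.

## Scenarios

All three patient scenarios start recurrent attacks (12/yr) at age 30 with
full work disability while attacks are active: `al_w` (lifelong attacks,
never works again), `a10_w` (attacks stop at 40, still unable to work),
`a10_plus_w` (attacks stop at 40, returns to work at the background
activity rate). Work disability applies from onset inclusive; recovery
restores the background activity and disability pattern from age
onset + duration. Inconsistent specifications (return to work with lifelong
attacks) are rejected at construction.

## Synthetic country and calibration

The real inputs — Belgian life tables, age–earnings, activity, disability
prevalence and health-expenditure profiles — are not redistributable, so the
package generates a stylised stand-in and calibrates it:

* mortality $q_x = \min(1, A + B c^x)$ (Gompertz–Makeham;
  $A=3\times10^{-4}$, $B=2.2\times10^{-5}$, $c=1.099$ — adult-mortality
  levels of a high-income European country), closed at 100;
* log-quadratic earnings hump peaking at €52,000 at age 47;
* activity ramping up to a 0.85 plateau through the early twenties and
  declining after 55;
* disability prevalence $0.03\,e^{0.045(a-18)}$; health spending
  €700 × 1.025^(a−18); consumption = the disposable share (0.473) of gross
  earnings, reduced to 70 % after retirement.

Calibration then solves a triangular sequence of one-dimensional problems,
each evaluated through the projection engine itself (so the calibration can
never drift from the model): a bounded mortality tilt (every $q_x$
multiplied by one factor) matches the comparator pension total, which
depends on survival alone; activity scales before/after age 30 (capped at 1
per age) match the pre-diagnosis work years and the remaining work years;
earnings scales before/after 30 match the earnings split; and background
disability, background health and consumption scales match the remaining
comparator totals. Linear knobs are solved by one ratio update; capped ones
by bracketed root finding. The shipped fixture reproduces all seven
comparator reference totals with residuals below 10⁻⁴ (machine precision
for the linear ones); the calibration object records every scale and
residual.

Two reference quantities are *soft diagnostics* rather than targets: the
pre-diagnosis earnings floor (€284,565) and work years (11.36). Matching
11.36 work years over ages 18–29 forces near-full youth employment
(average activity ≈ 0.95), which is the main respect in which the fixture
is a calibration artefact rather than a realistic country: real youth
activity is far lower. Consequences are confined to the pre-base window.

What passing tests show — and what they do not: the comparator column,
attack costing, delta arithmetic and all structural properties (stream
composition, additivity, orderings, invariances) are verified; the patient
scenario *levels* depend on unpublished inputs and conventions that cannot
all be reconciled (see below), so they are checked ordinally and
structurally, not by value. Results on the synthetic fixture therefore
demonstrate the mechanics and the calibrated comparator, not a re-estimate
of Belgian patient-level totals.

## Known limitations and numerical notes

* The published scenario columns cannot all be reproduced from any single
  survival curve: the lifelong-attack health total implies a
  survival-discount factor ≈ 28.6 while the pension total implies a far
  heavier post-65 mortality-discount weight; with 2 % health inflation the
  pension-consistent table yields a factor ≈ 39.4. Emergent patient totals
  here are correspondingly higher than the published ones (e.g. lifelong
  health costs ≈ €4.28 M vs €3.10 M) while deltas driven by earnings and
  taxes agree to ≈ 0.1 %.
* Expected work years use the same discount convention as money streams; if
  the reference 25.24 GP work years were mortality-adjusted only, the
  difference is absorbed by the activity scale during calibration.
* No AHP-specific excess mortality (general-population life table applied),
  no liver transplantation, no part-time or reduced-wage return to work, no
  progressive taxation, no savings rate (full consumption of the VAT base),
  single-sex-aggregate period life table, no probabilistic sensitivity
  analysis.
* Money is carried as floats internally; reports round half-up to whole
  euros (cents for costing tables) at the output layer only. Attack-table
  totals use compensated summation so they are independent of line order.
* One-way sensitivity varies one parameter at a time by ±25 %; "chronic
  health cost" scales all four management-cost categories jointly;
  "attack duration" 10 → 7.5/12.5 years exercises the fractional-year
  proration. Ranking ties (per-attack cost and annual attack count scale
  the same product, so their ranges coincide exactly) are broken
  alphabetically.
* Problem sizes: 83 model ages, 4 scenarios, 5 sensitivity parameters; a
  full pipeline run including calibration takes well under a second, and
  the test suite a few seconds.
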