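"""Scenario composition, lifetime summaries, deltas and chart data."""

import numpy as np
import pytest

from ahpfiscal import (
    FiscalParameters,
    ModelInputs,
    STANDARD_SCENARIOS,
    ScenarioSpec,
    annual_chart_data,
    delta,
    net_fiscal_impact,
    project_scenario,
    summarize,
)

from conftest import flat_life_table, flat_schedule


def test_inconsistent_spec_rejected():
    with pytest.raises(ValueError, match="lifelong"):
        ScenarioSpec(name="bad", attack_duration_years=None,
                     able_to_return_to_work=True,
                     post_attack_work_disabled=False)


class TestTwoAgeToy:
    """Hand-composable miniature: 2 comparison ages, no mortality/discount."""

    @pytest.fixture
    def toy(self):
        params = FiscalParameters(
            tax_wedge=0.5, vat_rate=0.2, wage_growth=0.0,
            transfer_inflation=0.0, health_inflation=0.0, discount_rate=0.0,
            entry_age=29, base_age=30, retirement_age=32, horizon_age=33,
            indirect_tax_basis="own_disposable",
        )
        inputs = ModelInputs(
            life_table=flat_life_table(0.0),
            earnings=flat_schedule(10_000.0, 29, 33),
            activity=flat_schedule(1.0, 29, 33),
            disability=flat_schedule(0.0, 29, 33),
            gp_health=flat_schedule(0.0, 29, 33),
        )
        return inputs, params

    def test_gp_per_age_gross_tax(self, toy):
        inputs, params = toy
        ledger = project_scenario(ScenarioSpec.general_population(), inputs, params)
        f = ledger.frame
        for age in (30, 31):
            assert f.loc[age, "earnings"] == 10_000.0
            assert f.loc[age, "direct_tax"] == 5_000.0
            assert f.loc[age, "indirect_tax"] == pytest.approx(1_000.0)
        post_base_tax = (
            f.loc[30:, "direct_tax"] + f.loc[30:, "indirect_tax"]
        ).sum()
        assert post_base_tax == pytest.approx(12_000.0)

    def test_alw_no_earnings_or_tax_after_onset(self, toy):
        inputs, params = toy
        spec = ScenarioSpec(name="al_w", onset_age=30)
        ledger = project_scenario(spec, inputs, params)
        f = ledger.frame
        assert (f.loc[30:, "earnings"] == 0).all()
        assert (f.loc[30:, "direct_tax"] + f.loc[30:, "indirect_tax"] == 0).all()
        assert f.loc[29, "earnings"] == 10_000.0  # pre-onset work window


class TestComparatorComposition:
    def test_gp_ledger_structure(self, fixture_inputs, params):
        ledger = project_scenario(
            STANDARD_SCENARIOS["gp"], fixture_inputs, params
        )
        f = ledger.frame
        assert (f.loc[18:64, "earnings"] > 0).all()
        assert (f.loc[65:, "earnings"] == 0).all()
        # background disability, not full disability
        assert (f.loc[30:64, "disability"] < params.disability_annual).all()
        assert (f.loc[30:, "health_cost"] > 0).all()

    def test_alw_never_works_after_onset(self, fixture_inputs, params):
        ledger = project_scenario(
            STANDARD_SCENARIOS["al_w"], fixture_inputs, params
        )
        assert (ledger.frame.loc[30:, "earnings"] == 0).all()

    def test_return_to_work_restores_background(self, fixture_inputs, params):
        led = project_scenario(
            STANDARD_SCENARIOS["a10_plus_w"], fixture_inputs, params
        )
        gp = project_scenario(STANDARD_SCENARIOS["gp"], fixture_inputs, params)
        f, g = led.frame, gp.frame
        assert (f.loc[30:39, "earnings"] == 0).all()
        assert np.allclose(f.loc[40:64, "earnings"], g.loc[40:64, "earnings"])
        assert np.allclose(f.loc[40:64, "disability"], g.loc[40:64, "disability"])


class TestSummaries:
    def test_zero_ledger_zero_summary(self, params):
        inputs = ModelInputs(
            life_table=flat_life_table(0.0),
            earnings=flat_schedule(0.0),
            activity=flat_schedule(0.0),
            disability=flat_schedule(0.0),
            gp_health=flat_schedule(0.0),
            consumption=flat_schedule(0.0),
        )
        p = params.with_(pension_annual=0.0, disability_annual=0.0)
        s = summarize(project_scenario(ScenarioSpec.general_population(), inputs, p))
        assert all(v == 0.0 for v in s.as_dict().values())

    def test_additivity_identity(self, fixture_inputs, params):
        for spec in STANDARD_SCENARIOS.values():
            s = summarize(project_scenario(spec, fixture_inputs, params))
            assert s.sum_government_costs == pytest.approx(
                s.disability_transfers + s.pension_costs + s.health_costs,
                abs=1e-9,
            )

    def test_closed_form_annuity_equivalence(self, flat_inputs, zero_growth_params):
        """qx = 0, flat profiles, zero growth: every field is an annuity."""
        p = zero_growth_params
        s = summarize(
            project_scenario(ScenarioSpec.general_population(), flat_inputs, p)
        )
        v = 1.0 / (1.0 + p.discount_rate)

        def annuity(n):  # sum_{t=0}^{n-1} v^t
            return (1.0 - v**n) / (1.0 - v)

        work_pv = 12.0 + annuity(35)  # ages 18-29 undiscounted, 30-64
        ret_pv = annuity(71) - annuity(35)  # ages 65-100
        health_pv = annuity(71)  # ages 30-100
        assert s.lifetime_earnings == pytest.approx(
            30_000.0 * 0.8 * work_pv, rel=1e-9
        )
        assert s.work_years == pytest.approx(0.8 * work_pv, rel=1e-9)
        assert s.disability_transfers == pytest.approx(
            0.1 * 13_613.0 * annuity(35), rel=1e-9
        )
        assert s.pension_costs == pytest.approx(14_400.0 * ret_pv, rel=1e-9)
        assert s.health_costs == pytest.approx(1_000.0 * health_pv, rel=1e-9)
        assert s.gross_tax == pytest.approx(
            p.tax_wedge * s.lifetime_earnings
            + p.vat_rate * 5_000.0 * health_pv,
            rel=1e-9,
        )

    def test_discount_rate_monotonicity(self, fixture_inputs):
        prev = None
        for r in (0.0, 0.02, 0.03, 0.05):
            p = FiscalParameters(discount_rate=r)
            s = summarize(
                project_scenario(STANDARD_SCENARIOS["gp"], fixture_inputs, p)
            )
            if prev is not None:
                for k, v in s.as_dict().items():
                    assert v <= prev[k] + 1e-9, f"{k} increased with discount"
            prev = s.as_dict()


class TestDeltasAndImpact:
    def test_identical_summaries_zero_delta(self, fixture_inputs, params):
        s = summarize(
            project_scenario(STANDARD_SCENARIOS["gp"], fixture_inputs, params)
        )
        d = delta(s, s)
        assert all(v == 0.0 for v in d.as_dict().values())
        assert net_fiscal_impact(d) == 0.0

    def test_net_impact_sign_convention(self):
        from ahpfiscal.projection import FiscalDelta

        d = FiscalDelta(0, 0, 0, 100.0, 0, 40.0, 0, societal_cost=0.0)
        assert net_fiscal_impact(d) == pytest.approx(60.0)

    def test_societal_cost_is_earnings_foregone(self, fixture_inputs, params):
        sums = {
            n: summarize(project_scenario(s, fixture_inputs, params))
            for n, s in STANDARD_SCENARIOS.items()
        }
        d = delta(sums["al_w"], sums["gp"])
        assert d.societal_cost == pytest.approx(-d.lifetime_earnings)
        assert d.societal_cost > 0

    def test_pension_scenario_invariance(self, fixture_inputs, params):
        sums = {
            n: summarize(project_scenario(s, fixture_inputs, params))
            for n, s in STANDARD_SCENARIOS.items()
        }
        pensions = {round(s.pension_costs, 6) for s in sums.values()}
        assert len(pensions) == 1

    def test_health_equality_with_and_without_return_to_work(
        self, fixture_inputs, params
    ):
        a = summarize(
            project_scenario(STANDARD_SCENARIOS["a10_w"], fixture_inputs, params)
        )
        b = summarize(
            project_scenario(
                STANDARD_SCENARIOS["a10_plus_w"], fixture_inputs, params
            )
        )
        assert a.health_costs == pytest.approx(b.health_costs, rel=1e-12)

    def test_scenario_cost_and_tax_ordering(self, fixture_inputs, params):
        sums = {
            n: summarize(project_scenario(s, fixture_inputs, params))
            for n, s in STANDARD_SCENARIOS.items()
        }
        g = lambda n: sums[n].sum_government_costs
        assert g("al_w") >= g("a10_w") >= g("a10_plus_w") >= g("gp")
        t = lambda n: sums[n].gross_tax
        assert t("gp") >= t("a10_plus_w") >= t("al_w")


class TestChartData:
    def test_gp_vs_gp_all_zero(self, fixture_inputs, params):
        gp = project_scenario(STANDARD_SCENARIOS["gp"], fixture_inputs, params)
        chart = annual_chart_data(gp, gp)
        assert float(chart.abs().to_numpy().sum()) == 0.0

    def test_column_sums_equal_delta_fields(self, fixture_inputs, params):
        gp = project_scenario(STANDARD_SCENARIOS["gp"], fixture_inputs, params)
        led = project_scenario(STANDARD_SCENARIOS["al_w"], fixture_inputs, params)
        chart = annual_chart_data(led, gp)
        d = delta(summarize(led), summarize(gp))
        assert chart["gross_tax"].sum() == pytest.approx(d.gross_tax, rel=1e-9)
        assert chart["disability_transfers"].sum() == pytest.approx(
            d.disability_transfers, rel=1e-9
        )
        assert chart["pension_costs"].sum() == pytest.approx(0.0, abs=1e-9)
        assert chart["health_costs"].sum() == pytest.approx(
            d.health_costs, rel=1e-9
        )
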