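"""Synthetic country generation and calibration round trip."""

import numpy as np
import pytest

from ahpfiscal import FiscalParameters, STANDARD_SCENARIOS, project_scenario, summarize
from ahpfiscal.synthetic import (
    BELGIAN_GP_REFERENCE,
    CalibrationTargets,
    CountryGeneratorParams,
    calibrate_fixture,
    make_life_table,
    make_profiles,
    write_fixture,
)


class TestLifeTableGenerator:
    def test_makeham_only_limit(self):
        p = CountryGeneratorParams(gompertz_b=1e-300)  # vanishing senescence
        lt = make_life_table(p)
        assert np.allclose(lt.qx[:-1], p.makeham_a)
        assert lt.qx[-1] == 1.0

    def test_gompertz_makeham_evaluation(self):
        p = CountryGeneratorParams(
            makeham_a=0.0002, gompertz_b=3e-5, gompertz_c=1.1
        )
        lt = make_life_table(p)
        assert lt.q(70) == pytest.approx(0.0002 + 3e-5 * 1.1**70, rel=1e-12)
        assert lt.q(70) == pytest.approx(0.0238924087, rel=1e-8)

    def test_early_certain_death_rejected(self):
        with pytest.raises(ValueError, match="60"):
            make_life_table(CountryGeneratorParams(makeham_a=0.9999,
                                                   gompertz_b=1.0))

    def test_deterministic(self):
        p = CountryGeneratorParams()
        a, b = make_life_table(p), make_life_table(p)
        assert np.array_equal(a.qx, b.qx)


class TestProfilesGenerator:
    def test_peak_anchoring(self):
        p = CountryGeneratorParams()
        prof = make_profiles(p)
        assert prof["gross_earnings"].at(p.earnings_peak_age) == pytest.approx(
            p.earnings_peak
        )

    def test_peak_anchoring_under_noise(self):
        p = CountryGeneratorParams(noise_sd=0.05)
        prof = make_profiles(p)
        assert prof["gross_earnings"].at(p.earnings_peak_age) == pytest.approx(
            p.earnings_peak
        )

    def test_disability_nondecreasing(self):
        prof = make_profiles(CountryGeneratorParams())
        assert np.all(np.diff(prof["disability_rate"].values) >= 0)

    def test_gp_cost_compounds_from_entry(self):
        p = CountryGeneratorParams(gp_cost_base=500.0,
                                   gp_cost_growth_per_age=0.02)
        prof = make_profiles(p)
        assert prof["gp_health_cost"].at(38) == pytest.approx(
            742.9736979891775, rel=1e-12
        )

    def test_activity_within_bounds_and_retires(self):
        prof = make_profiles(CountryGeneratorParams())
        act = prof["activity_rate"]
        assert np.all((act.values >= 0) & (act.values <= 1))
        assert act.at(70) == 0.0

    def test_seeded_noise_deterministic(self):
        p = CountryGeneratorParams(noise_sd=0.05, seed=11)
        a = make_profiles(p)["gross_earnings"].values
        b = make_profiles(p)["gross_earnings"].values
        assert np.array_equal(a, b)
        c = make_profiles(CountryGeneratorParams(noise_sd=0.05, seed=12))
        assert not np.array_equal(a, c["gross_earnings"].values)


class TestCalibration:
    def test_round_trip_reproduces_all_seven_targets(self, fixture_country):
        """Re-running the engine on the fixture hits every comparator target."""
        inputs, result = fixture_country
        gp = summarize(
            project_scenario(STANDARD_SCENARIOS["gp"], inputs,
                             FiscalParameters())
        )
        ref = BELGIAN_GP_REFERENCE.as_dict()
        for field, target in ref.items():
            assert getattr(gp, field) == pytest.approx(target, rel=0.02), field

    def test_residuals_recorded_and_small(self, fixture_country):
        _, result = fixture_country
        assert result.converged
        assert max(abs(r) for r in result.residuals.values()) < 1e-4

    def test_pre_onset_soft_diagnostics(self, fixture_country):
        _, result = fixture_country
        assert result.diagnostics["pre_onset_earnings"] == pytest.approx(
            284_565.0, rel=0.10
        )

    def test_doubling_earnings_target_doubles_scale(self):
        base = CalibrationTargets()
        _, r1 = calibrate_fixture(base)
        doubled = CalibrationTargets(
            gp=type(base.gp)(
                **{**base.gp.as_dict(),
                   "lifetime_earnings": 2 * base.gp.lifetime_earnings,
                   # keep gross tax consistent: direct tax is linear in earnings
                   "gross_tax": base.gp.gross_tax
                   + 0.527 * base.gp.lifetime_earnings},
                name="x",
            ),
            pre_onset_earnings=2 * base.pre_onset_earnings,
        )
        _, r2 = calibrate_fixture(doubled)
        assert r2.scales["earn_pre"] == pytest.approx(
            2 * r1.scales["earn_pre"], rel=1e-6
        )
        assert r2.scales["earn_post"] == pytest.approx(
            2 * r1.scales["earn_post"], rel=1e-6
        )

    def test_calibration_deterministic(self, fixture_country):
        inputs1, _ = fixture_country
        inputs2, _ = calibrate_fixture()
        assert np.array_equal(inputs1.life_table.qx, inputs2.life_table.qx)
        assert np.array_equal(inputs1.earnings.values, inputs2.earnings.values)

    def test_parameter_recovery_smoke(self, fixture_country):
        """Perturb a linear fiscal parameter and re-estimate it from one
        summary statistic: identifiability at the 1% level."""
        inputs, _ = fixture_country
        base_params = FiscalParameters()
        true_value = base_params.disability_annual * 1.1
        perturbed = base_params.with_(disability_annual=true_value)
        observed = summarize(
            project_scenario(STANDARD_SCENARIOS["gp"], inputs, perturbed)
        ).disability_transfers
        baseline = summarize(
            project_scenario(STANDARD_SCENARIOS["gp"], inputs, base_params)
        ).disability_transfers
        estimate = base_params.disability_annual * observed / baseline
        assert estimate == pytest.approx(true_value, rel=0.01)


class TestFixtureFiles:
    def test_same_seed_byte_identical(self, tmp_path, fixture_country):
        inputs, _ = fixture_country
        p1 = write_fixture(inputs, tmp_path / "a")
        inputs2, _ = calibrate_fixture()  # fresh, same default seed
        p2 = write_fixture(inputs2, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_files_load_back(self, tmp_path, fixture_country):
        from ahpfiscal.demographics import load_age_profiles, load_life_table

        inputs, _ = fixture_country
        paths = write_fixture(inputs, tmp_path)
        lt = load_life_table(paths["life_table"])
        prof = load_age_profiles(paths["profiles"])
        assert lt.max_age == 100
        assert np.allclose(
            prof["gross_earnings"].values, inputs.earnings.values
        )
        assert "consumption" in prof
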