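"""Doubly-labeled-water energetics: definitions, table consistency, and
synthetic round trips."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from divefmr import dlw
from divefmr.simulate import SimConfig, simulate_isotope_study


def make_sample(t, o18, h2, phase):
    return dlw.IsotopeSample(time_days=t, o18_ppm=o18, h2_ppm=h2, phase=phase)


class TestDilutionSpaces:
    def test_plateau_is_excess_over_enrichment(self):
        # 10 mol of dose water at 10% label = 1.0 mol excess; equilibration
        # excess mole fraction 5e-4 (500 ppm over a zero background)
        dose = dlw.DoseRecord(dose_mass_g=10 * 18.02, o18_fraction=0.10, h2_fraction=0.99)
        bg = make_sample(0.0, 0.0, 0.0, "background")
        eq = make_sample(0.15, 500.0, 800.0, "equilibration")
        n = dlw.dilution_space_plateau(dose, "o18", eq, bg)
        assert n == pytest.approx(2000.0, rel=1e-12)

    def test_plateau_rejects_no_enrichment(self):
        dose = dlw.DoseRecord(dose_mass_g=100.0, o18_fraction=0.10, h2_fraction=0.99)
        bg = make_sample(0.0, 2000.0, 150.0, "background")
        eq = make_sample(0.15, 2000.0, 150.0, "equilibration")
        with pytest.raises(dlw.InvalidStudyError, match="o18"):
            dlw.dilution_space_plateau(dose, "o18", eq, bg, animal_id="C9")

    def test_scaling_follows_mass_ratio(self):
        assert dlw.dilution_space_scaling(2000.0, 85.4, 81.2) == pytest.approx(1901.6, abs=0.05)
        assert dlw.dilution_space_scaling(1500.0, 80.0, 80.0) == 1500.0
        with pytest.raises(ValueError):
            dlw.dilution_space_scaling(2000.0, 85.4, 0.0)

    def test_tbw_fraction(self):
        n_o = 55.5 * 1000.0 / 18.02  # 55.5 kg of body water
        assert dlw.tbw_fraction(n_o, 85.4) == pytest.approx(64.99, abs=0.01)
        n_all = 70.0 * 1000.0 / 18.02
        assert dlw.tbw_fraction(n_all, 70.0) == pytest.approx(100.0)


class TestTurnover:
    def test_log_ratio_over_time(self):
        bg = make_sample(0.0, 0.0, 0.0, "background")
        eq = make_sample(0.0, 1000.0, 1000.0, "equilibration")
        fin = make_sample(10.0, 1000.0 * np.exp(-1.0), 500.0, "final")
        k = dlw.turnover_rate(eq, fin, bg, "o18")
        assert k == pytest.approx(0.1, rel=1e-12)

    def test_no_decline_warns_and_returns_zero(self):
        bg = make_sample(0.0, 0.0, 0.0, "background")
        eq = make_sample(0.0, 800.0, 800.0, "equilibration")
        fin = make_sample(5.0, 800.0, 800.0, "final")
        with pytest.warns(UserWarning, match="not turning over"):
            assert dlw.turnover_rate(eq, fin, bg, "o18") == 0.0

    def test_nonpositive_final_excess_is_invalid(self):
        bg = make_sample(0.0, 100.0, 100.0, "background")
        eq = make_sample(0.0, 800.0, 800.0, "equilibration")
        fin = make_sample(5.0, 90.0, 90.0, "final")
        with pytest.raises(dlw.InvalidStudyError):
            dlw.turnover_rate(eq, fin, bg, "o18")


class TestCO2Production:
    def test_single_pool_value(self):
        k = dlw.TurnoverRates(k_o=0.12, k_d=0.09)
        assert dlw.rco2_single_pool(2000.0, k) == pytest.approx(27.758, abs=1e-3)

    def test_single_pool_linear_in_pool(self):
        k = dlw.TurnoverRates(k_o=0.12, k_d=0.09)
        assert dlw.rco2_single_pool(4000.0, k) == pytest.approx(
            2 * dlw.rco2_single_pool(2000.0, k)
        )

    def test_equal_rates_give_negative_fractionation_term(self):
        k = dlw.TurnoverRates(k_o=0.1, k_d=0.1)
        with pytest.warns(UserWarning, match="negative CO2"):
            assert dlw.rco2_single_pool(2000.0, k) < 0

    def test_two_pool_reduces_to_single_pool_at_unit_ratio(self):
        spaces = dlw.DilutionSpaces(n_o=2000.0, n_d=2000.0 * 1.0427, method="plateau")
        k = dlw.TurnoverRates(k_o=0.12, k_d=0.09)
        two = dlw.rco2_two_pool(spaces, k, constants={"dilution_space_ratio": 1.0})
        assert two == pytest.approx(dlw.rco2_single_pool(2000.0, k), rel=1e-14)

    def test_fixed_and_observed_ratio_agree_at_population_value(self):
        spaces = dlw.DilutionSpaces(n_o=2000.0, n_d=2000.0 * 1.0427, method="plateau")
        k = dlw.TurnoverRates(k_o=0.12, k_d=0.09)
        assert dlw.rco2_two_pool(spaces, k, "fixed") == pytest.approx(
            dlw.rco2_two_pool(spaces, k, "observed"), rel=1e-12
        )


class TestEnergyConversion:
    @pytest.mark.parametrize(
        "rco2, m0, m1, watts, wkg",
        [
            (0.233, 85.4, 81.2, 127.0, 1.52),  # low-expenditure animal
            (0.836, 78.4, 79.4, 432.6, 5.48),  # high-expenditure animal
            (0.614, 78.9, 77.9, 315.7, 4.03),
        ],
    )
    def test_reproduces_reference_rows(self, rco2, m0, m1, watts, wkg):
        w, per_kg = dlw.fmr_from_co2(rco2, m0, m1)
        assert w == pytest.approx(watts, rel=5e-3)
        assert per_kg == pytest.approx(wkg, rel=5e-3)

    def test_zero_co2_zero_power(self):
        assert dlw.fmr_from_co2(0.0, 80.0, 80.0) == (0.0, 0.0)


class TestWaterFlux:
    def test_steady_pool_limit(self):
        influx, efflux = dlw.water_flux(2000.0, 2000.0, 0.09, 10.0, 80.0)
        expected = 0.09 * 2000.0 * 18.02 / 80.0
        assert influx == pytest.approx(expected)
        assert efflux == pytest.approx(expected)

    @given(
        n1=hst.floats(500.0, 5000.0),
        shrink=hst.floats(0.7, 1.3),
        k_d=hst.floats(0.01, 0.4),
        interval=hst.floats(1.0, 20.0),
        mass=hst.floats(30.0, 120.0),
    )
    def test_mass_balance_identity(self, n1, shrink, k_d, interval, mass):
        n2 = n1 * shrink
        influx, efflux = dlw.water_flux(n1, n2, k_d, interval, mass)
        pool_change = (n2 - n1) / interval * 18.02 / mass
        assert influx - efflux == pytest.approx(pool_change, rel=1e-9, abs=1e-9)


class TestAtSeaCorrection:
    def test_identity_when_entire_interval_at_sea(self):
        value, flags = dlw.at_sea_fmr(4.0, 10.0, 10.0, dlw.OnshoreRateSpec(rate_wkg=2.0))
        assert value == 4.0 and not flags

    def test_time_budget_partition(self):
        value, flags = dlw.at_sea_fmr(4.0, 10.0, 6.0, dlw.OnshoreRateSpec(rate_wkg=2.0))
        assert value == pytest.approx((4.0 * 10 - 2.0 * 4) / 6.0)
        assert value == pytest.approx(5.3333, abs=1e-3)

    def test_onshore_rate_above_total_flags_invalid(self):
        value, flags = dlw.at_sea_fmr(1.0, 10.0, 0.5, dlw.OnshoreRateSpec(rate_wkg=5.0))
        assert "invalid-partition" in flags

    def test_onshore_spec_requires_exactly_one_mode(self):
        with pytest.raises(ValueError):
            dlw.OnshoreRateSpec().resolve(80.0)
        with pytest.raises(ValueError):
            dlw.OnshoreRateSpec(rate_wkg=2.0, basal_multiple=1.5).resolve(80.0)


class TestUncertainty:
    def _study(self, noise=False):
        cfg = SimConfig(seed=11)
        return simulate_isotope_study(cfg, 0, noise=noise)

    def test_zero_noise_degenerates_to_point(self):
        study, truth = self._study()
        lo, hi = dlw.rco2_uncertainty(study, {"o18": 0.0, "h2": 0.0}, n_draws=200)
        assert lo == pytest.approx(hi)
        assert lo == pytest.approx(truth.rco2_ml_g_hr, rel=1e-6)

    def test_interval_widens_with_noise(self):
        study, _ = self._study()
        widths = []
        for sd in (0.5, 1.5, 4.5):
            lo, hi = dlw.rco2_uncertainty(
                study, {"o18": sd, "h2": 2 * sd}, n_draws=4000, seed=5
            )
            widths.append(hi - lo)
        assert widths[0] < widths[1] < widths[2]

    def test_bit_reproducible_under_seed(self):
        study, _ = self._study()
        a = dlw.rco2_uncertainty(study, {"o18": 1.5, "h2": 3.0}, n_draws=500, seed=42)
        b = dlw.rco2_uncertainty(study, {"o18": 1.5, "h2": 3.0}, n_draws=500, seed=42)
        assert a == b

    def test_requires_minimum_draws(self):
        study, _ = self._study()
        with pytest.raises(ValueError):
            dlw.rco2_uncertainty(study, {"o18": 1.0, "h2": 1.0}, n_draws=10)


class TestRoundTrip:
    def test_noise_free_chain_recovers_truth(self):
        cfg = SimConfig(seed=5, n_animals=10)
        for i in range(10):
            study, truth = simulate_isotope_study(cfg, i, noise=False)
            res = dlw.process_study(study)
            assert res.n_o_mol == pytest.approx(truth.n_o_mol, rel=1e-3)
            assert res.k_o == pytest.approx(truth.k_o, rel=1e-3)
            assert res.k_d == pytest.approx(truth.k_d, rel=1e-3)
            assert res.rco2_speakman_ml_g_hr == pytest.approx(truth.rco2_ml_g_hr, rel=5e-3)
            assert res.influx_ml_kg_day == pytest.approx(truth.influx_ml_kg_day, rel=5e-3)
            assert res.tbw_percent == pytest.approx(100 * truth.tbw_fraction, rel=1e-3)

    def test_processed_result_internal_consistency(self):
        study, _ = simulate_isotope_study(SimConfig(seed=9), 0, noise=False)
        res = dlw.process_study(study)
        mean_mass = 0.5 * (study.mass_initial_kg + study.mass_final_kg)
        assert res.fmr_w_speakman == pytest.approx(res.fmr_wkg_speakman * mean_mass)
        # influx - efflux equals the pool-change rate
        n_d_fin = res.n_d_mol * study.mass_final_kg / study.mass_initial_kg
        pool_change = (n_d_fin - res.n_d_mol) / study.interval_days * 18.02 / mean_mass
        assert res.influx_ml_kg_day - res.efflux_ml_kg_day == pytest.approx(pool_change)
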