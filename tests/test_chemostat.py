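"""Chemostat steady-state bookkeeping: rates, error propagation, stability."""

import numpy as np
import pytest

import fluxmaint as fm
from fluxmaint.chemostat_rates import (
    ChemostatRecord,
    biomass_carbon_content,
    dilution_rate,
    steady_state_rates,
)
from fluxmaint.errors import InsufficientDataError, ValidationError


def record(times, feed_mass, nv=None, nt=None, conc=None, feed=None, volume=270.0):
    n = len(times)
    return ChemostatRecord(
        record_id="t",
        times=np.asarray(times, dtype=float),
        feed_mass=np.asarray(feed_mass, dtype=float),
        volume_ml=volume,
        viable_density=np.full(n, 5e6) if nv is None else np.asarray(nv),
        total_density=np.full(n, 5.3e6) if nt is None else np.asarray(nt),
        concentrations=conc or {},
        feed_concentrations=feed or {},
    )


class TestDilutionRate:
    def test_flow_over_volume(self):
        # 5.4 mL/h into 270 mL -> 0.020 h^-1
        times = [0.0, 10.0, 20.0, 30.0]
        rec = record(times, [5.4 * t for t in times])
        D, _ = dilution_rate(rec)
        assert D == pytest.approx(0.020)

    def test_zero_feed_gives_zero(self):
        rec = record([0.0, 10.0, 20.0], [0.0, 0.0, 0.0])
        assert dilution_rate(rec)[0] == pytest.approx(0.0)

    def test_noisy_slope_recovered_within_fit_ci(self):
        rng = np.random.default_rng(0)
        times = np.linspace(0, 48, 12)
        mass = 5.4 * times * (1 + 0.01 * rng.standard_normal(12))
        rec = record(times, mass)
        D, D_sd = dilution_rate(rec)
        assert abs(D - 0.020) <= 2.5 * D_sd

    def test_single_point_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            dilution_rate(record([0.0], [0.0]))


class TestGrowthRate:
    def test_full_viability_means_mu_equals_d(self):
        mu, _ = fm.growth_rate((0.02, 0.0), (5e6, 0.0), (5e6, 0.0))
        assert mu == pytest.approx(0.02)

    def test_dead_cells_require_faster_growth(self):
        mu, _ = fm.growth_rate((0.020, 0.0), (5.25e6, 0.0), (5e6, 0.0))
        assert mu == pytest.approx(0.021)
        mu2, _ = fm.growth_rate((0.030, 0.0), (5.5e6, 0.0), (5e6, 0.0))
        assert mu2 == pytest.approx(0.033)

    def test_zero_viable_density_rejected(self):
        with pytest.raises(ValidationError):
            fm.growth_rate((0.02, 0.0), (5e6, 0.0), (0.0, 0.0))


class TestExchangeRate:
    def test_consumption_is_negative(self):
        q, _ = fm.exchange_rate(30.0, (10.0, 0.0), (0.02, 0.0), (1.5, 0.0))
        assert q == pytest.approx(-0.2667, abs=1e-4)

    def test_secretion_is_positive(self):
        q, _ = fm.exchange_rate(0.0, (40.0, 0.0), (0.021, 0.0), (1.5, 0.0))
        assert q == pytest.approx(0.56)

    def test_no_gradient_no_flux(self):
        q, sd = fm.exchange_rate(5.0, (5.0, 0.1), (0.02, 0.0), (1.5, 0.0))
        assert q == 0.0

    def test_linear_in_gradient_and_dilution(self):
        q1, _ = fm.exchange_rate(10.0, (4.0, 0.0), (0.02, 0.0), (1.5, 0.0))
        q2, _ = fm.exchange_rate(10.0, (7.0, 0.0), (0.02, 0.0), (1.5, 0.0))
        q3, _ = fm.exchange_rate(10.0, (4.0, 0.0), (0.04, 0.0), (1.5, 0.0))
        assert q2 == pytest.approx(q1 / 2)
        assert q3 == pytest.approx(2 * q1)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError):
            fm.exchange_rate(-1.0, (5.0, 0.0), (0.02, 0.0), (1.5, 0.0))


class TestPropagateSd:
    def test_product_closed_form(self):
        sd = fm.propagate_sd("product_quotient", (10.0, 5.0), (1.0, 0.5))
        assert sd == pytest.approx(50.0 * np.hypot(0.1, 0.1))  # ~7.07

    def test_zero_sds_propagate_to_zero(self):
        assert fm.propagate_sd("product_quotient", (10.0, 5.0), (0.0, 0.0)) == 0.0
        assert fm.propagate_sd("sum_difference", (10.0, 5.0), (0.0, 0.0)) == 0.0

    def test_sum_closed_form(self):
        assert fm.propagate_sd("sum_difference", (1.0, 2.0), (3.0, 4.0)) == pytest.approx(5.0)

    def test_zero_value_in_relative_form_rejected(self):
        with pytest.raises(ValidationError):
            fm.propagate_sd("product_quotient", (0.0, 5.0), (1.0, 0.5))

    @pytest.mark.parametrize(
        "op,combine",
        [("product_quotient", lambda a, b: a * b), ("sum_difference", lambda a, b: a + b)],
    )
    def test_matches_monte_carlo(self, op, combine):
        rng = np.random.default_rng(12345)
        a, sa, b, sb = 10.0, 1.0, 5.0, 0.5
        n = 10**6
        draws = combine(rng.normal(a, sa, n), rng.normal(b, sb, n))
        expected = float(draws.std())
        assert fm.propagate_sd(op, (a, b), (sa, sb)) == pytest.approx(expected, rel=0.02)


class TestStabilityCheck:
    def test_constant_series_is_stable(self):
        rng = np.random.default_rng(1)
        times = np.linspace(0, 48, 8)
        res = fm.stability_check(times, 5.0 + 0.01 * rng.standard_normal(8))
        assert res.stable is True

    def test_strong_trend_is_unstable(self):
        rng = np.random.default_rng(2)
        times = np.linspace(0, 48, 8)
        res = fm.stability_check(times, 5.0 + 0.5 * times + 0.05 * rng.standard_normal(8))
        assert res.stable is False

    def test_two_points_flagged_insufficient(self):
        res = fm.stability_check(np.array([0.0, 24.0]), np.array([5.0, 5.1]))
        assert res.stable is None
        assert res.insufficient_data

    def test_instrument_error_override_flag(self):
        times = np.linspace(0, 48, 10)
        series = 5.0 + 1e-4 * times  # significant but tiny drift
        res = fm.stability_check(times, series, instrument_error=0.1)
        if not res.stable:
            assert res.within_instrument_error


class TestCarbonRecovery:
    def test_half_of_uptake_secreted_no_growth(self, toy_model):
        q = {"glc__D": (-1.0, 0.0), "lac__L": (1.0, 0.0)}  # 6 C in, 3 C out
        rec = fm.carbon_recovery(q, toy_model, mu=0.0, biomass_carbon=36.0)
        assert rec == pytest.approx(0.5)

    def test_under_measured_secretion_lowers_recovery(self, toy_model, noiseless_chemostat):
        _, records = noiseless_chemostat
        rates = steady_state_rates(records[0], model=toy_model)
        q = dict(rates.q)
        v, sd = q["lac__L"] if q["lac__L"][0] > 0 else q["co2"]
        key = "lac__L" if q["lac__L"][0] > 0 else "co2"
        q[key] = (0.9 * v, sd)
        lowered = fm.carbon_recovery(
            q, toy_model, rates.growth_rate[0], biomass_carbon_content(toy_model)
        )
        assert lowered < rates.carbon_recovery

    def test_zero_uptake_rejected(self, toy_model):
        with pytest.raises(ValidationError):
            fm.carbon_recovery({"lac__L": (1.0, 0.0)}, toy_model, 0.0, 36.0)


class TestSteadyStateAggregation:
    def test_mu_at_least_d_and_equality_at_full_viability(self, noiseless_chemostat):
        _, records = noiseless_chemostat
        for rec in records:
            rates = steady_state_rates(rec)
            assert rates.growth_rate[0] >= rates.dilution_rate[0] - 1e-12

    def test_record_requires_nt_at_least_nv(self):
        with pytest.raises(ValidationError):
            record([0.0, 1.0, 2.0], [0, 1, 2], nv=np.full(3, 6e6), nt=np.full(3, 5e6))

    def test_record_tsv_round_trip(self, noiseless_chemostat, tmp_path):
        _, records = noiseless_chemostat
        path = tmp_path / "rec.tsv"
        records[0].to_tsv(path)
        back = ChemostatRecord.from_tsv(path)
        assert np.allclose(back.times, records[0].times)
        assert np.allclose(back.feed_mass, records[0].feed_mass)
        assert set(back.concentrations) == set(records[0].concentrations)
        for sid in back.concentrations:
            assert np.allclose(back.concentrations[sid], records[0].concentrations[sid])
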