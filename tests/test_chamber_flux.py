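import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from benthicflux.chamber_flux import compute_flux, fit_slope, flux_by_interval, mean_kelvin
from benthicflux.models import (
    ChamberGeometry,
    Constants,
    FluxStatus,
    Gas,
    GasSample,
    GasSeries,
    ValidationError,
)


def ols_slope_oracle(times, concs):
    """Independent closed-form OLS slope: sum((t-t̄)(c-c̄)) / sum((t-t̄)²)."""
    t = np.asarray(times, float)
    c = np.asarray(concs, float)
    tc = t - t.mean()
    return float((tc * (c - c.mean())).sum() / (tc * tc).sum())


def ideal_gas_flux_oracle(slope, volume_l, t_kelvin, area_m2, p_atm=1.0, r=8.205746e-5):
    """n = PV/(RT) in moles of headspace air, flux = slope * n / A."""
    n = p_atm * (volume_l / 1000.0) / (r * t_kelvin)
    return slope * n / area_m2


class TestFitSlope:
    def test_two_point_difference_quotient(self):
        slope, r2, n = fit_slope([0.0, 12.0], [400.0, 412.0])
        assert slope == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)
        assert n == 2

    def test_constant_series(self):
        slope, r2, n = fit_slope([0.0, 12.0, 18.0], [400.0, 400.0, 400.0])
        assert slope == 0.0
        assert n == 3

    def test_collinear_three_points(self):
        # (0, 400), (12, 406), (18, 409): exact line with slope 0.5
        times, concs = [0.0, 12.0, 18.0], [400.0, 406.0, 409.0]
        slope, r2, _ = fit_slope(times, concs)
        assert slope == pytest.approx(0.5, abs=1e-12)
        assert slope == pytest.approx(ols_slope_oracle(times, concs), abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_slope([0.0], [400.0])

    def test_coincident_times_rejected(self):
        with pytest.raises(ValidationError):
            fit_slope([1.0, 1.0], [400.0, 410.0])

    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100, allow_nan=False),
            min_size=2,
            max_size=8,
        ),
        st.integers(min_value=0, max_value=1000),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_closed_form_oracle(self, concs, seed):
        times = np.sort(np.random.default_rng(seed).uniform(0, 24, size=len(concs)))
        if np.unique(times).size < len(times):
            return
        slope, _, _ = fit_slope(times, concs)
        assert slope == pytest.approx(ols_slope_oracle(times, concs), abs=1e-8)

    def test_two_point_slope_equals_ols(self):
        t, c = [2.0, 7.5], [410.0, 395.2]
        slope, _, _ = fit_slope(t, c)
        assert slope == pytest.approx((c[1] - c[0]) / (t[1] - t[0]))
        assert slope == pytest.approx(ols_slope_oracle(t, c))


class TestMeanKelvin:
    def test_field_range_mean(self):
        series = [(0.0, 24.2), (12.0, 33.6)]
        assert mean_kelvin(series, (0.0, 12.0)) == pytest.approx(302.05)

    def test_single_zero_celsius(self):
        assert mean_kelvin([(0.0, 0.0)], (0.0, 1.0)) == pytest.approx(273.15)

    def test_fallback_to_nearest(self):
        assert mean_kelvin([(0.0, 25.0)], (5.0, 6.0)) == pytest.approx(298.15)

    def test_nearest_picks_closest(self):
        series = [(0.0, 10.0), (4.9, 25.0)]
        assert mean_kelvin(series, (5.0, 6.0)) == pytest.approx(298.15)

    def test_empty_series_rejected(self):
        with pytest.raises(ValidationError):
            mean_kelvin([], (0.0, 1.0))


def series_from(times, concs, gas=Gas.CO2):
    return GasSeries(
        gas,
        [GasSample(f"t{i}", t, c) for i, (t, c) in enumerate(zip(times, concs))],
    )


class TestComputeFlux:
    def test_zero_slope_zero_flux(self, geometry, flat_temperature):
        res = compute_flux(series_from([0, 12, 18], [400, 400, 400]), geometry, flat_temperature)
        assert res.flux_umol_m2_h == 0.0
        assert res.status is FluxStatus.OK

    def test_hand_oracle_unit_case(self):
        # slope 1 ppmv/h, V=24.6 L, T=300 K, A=1 m2 -> ~0.9993 umol m-2 h-1
        geom = ChamberGeometry(1.0, 24.6)
        temps = [(0.0, 300.0 - 273.15)]
        res = compute_flux(series_from([0.0, 1.0], [400.0, 401.0]), geom, temps)
        expected = 0.0246 / (8.205746e-5 * 300.0)
        assert res.flux_umol_m2_h == pytest.approx(expected, rel=1e-12)
        assert res.flux_umol_m2_h == pytest.approx(0.9993, abs=5e-5)

    def test_double_area_halves_flux(self, flat_temperature):
        series = series_from([0.0, 12.0], [400.0, 412.0])
        f1 = compute_flux(series, ChamberGeometry(1.0, 24.6), flat_temperature)
        f2 = compute_flux(series, ChamberGeometry(2.0, 24.6), flat_temperature)
        assert f2.flux_umol_m2_h == pytest.approx(f1.flux_umol_m2_h / 2.0, rel=1e-12)

    def test_double_volume_doubles_flux(self, flat_temperature):
        series = series_from([0.0, 12.0], [400.0, 412.0])
        f1 = compute_flux(series, ChamberGeometry(1.0, 10.0), flat_temperature)
        f2 = compute_flux(series, ChamberGeometry(1.0, 20.0), flat_temperature)
        assert f2.flux_umol_m2_h == pytest.approx(2.0 * f1.flux_umol_m2_h, rel=1e-12)

    def test_warmer_headspace_decreases_flux_magnitude(self, geometry):
        series = series_from([0.0, 12.0], [400.0, 412.0])
        cool = compute_flux(series, geometry, [(0.0, 20.0)])
        warm = compute_flux(series, geometry, [(0.0, 30.0)])
        assert abs(warm.flux_umol_m2_h) < abs(cool.flux_umol_m2_h)

    def test_flux_sign_follows_slope(self, geometry, flat_temperature):
        res = compute_flux(series_from([0.0, 12.0], [412.0, 400.0]), geometry, flat_temperature)
        assert res.slope_ppmv_h < 0
        assert res.flux_umol_m2_h < 0  # uptake, not clipped

    def test_all_nondetect_yields_nondetect_status(self, geometry, flat_temperature):
        series = GasSeries(
            Gas.CH4,
            [GasSample("t0", 0.0, None, detected=False), GasSample("t1", 12.0, None, detected=False)],
        )
        res = compute_flux(series, geometry, flat_temperature)
        assert res.status is FluxStatus.NONDETECT
        assert res.flux_umol_m2_h is None and res.flux_ug_m2_h is None

    def test_single_detected_point_insufficient(self, geometry, flat_temperature):
        series = GasSeries(
            Gas.CH4,
            [GasSample("t0", 0.0, None, detected=False), GasSample("t1", 12.0, 3.0)],
        )
        res = compute_flux(series, geometry, flat_temperature)
        assert res.status is FluxStatus.INSUFFICIENT_POINTS

    def test_ch4_gets_mass_flux(self, geometry, flat_temperature, constants):
        series = series_from([0.0, 12.0], [2.0, 3.2], gas=Gas.CH4)
        res = compute_flux(series, geometry, flat_temperature, constants)
        assert res.flux_ug_m2_h == pytest.approx(res.flux_umol_m2_h * constants.ch4_molar_mass)
        # umol -> ug -> umol round trip is identity
        assert res.flux_ug_m2_h / constants.ch4_molar_mass == pytest.approx(res.flux_umol_m2_h)

    @given(
        slope=st.floats(min_value=-10, max_value=10, allow_nan=False),
        volume=st.floats(min_value=0.5, max_value=200, allow_nan=False),
        area=st.floats(min_value=0.01, max_value=5, allow_nan=False),
        temp_c=st.floats(min_value=0, max_value=40, allow_nan=False),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_ideal_gas_oracle(self, slope, volume, area, temp_c):
        c0 = 400.0
        if c0 + 12 * slope < 0:
            return
        series = series_from([0.0, 12.0], [c0, c0 + 12 * slope])
        res = compute_flux(series, ChamberGeometry(area, volume), [(0.0, temp_c)])
        expected = ideal_gas_flux_oracle(slope, volume, temp_c + 273.15, area)
        assert res.flux_umol_m2_h == pytest.approx(expected, rel=1e-9, abs=1e-12)


class TestFluxByInterval:
    def test_three_samples_two_intervals(self, geometry, flat_temperature):
        series = series_from([0.0, 12.0, 18.0], [400.0, 406.0, 409.0])
        results = flux_by_interval(series, geometry, flat_temperature)
        assert [r.interval for r in results] == ["t0-t1", "t1-t2"]
        assert all(r.status is FluxStatus.OK for r in results)

    def test_missing_endpoint_flagged(self, geometry, flat_temperature):
        # damaged chamber at t2: only the t0->t1 flux is computable
        series = series_from([0.0, 12.0], [400.0, 406.0])
        results = flux_by_interval(
            series, geometry, flat_temperature, expected_labels=("t0", "t1", "t2")
        )
        assert results[0].status is FluxStatus.OK
        assert results[1].interval == "t1-t2"
        assert results[1].status is FluxStatus.INSUFFICIENT_POINTS

    def test_equal_concentrations_zero_interval_flux(self, geometry, flat_temperature):
        series = series_from([0.0, 12.0], [400.0, 400.0])
        (res,) = flux_by_interval(series, geometry, flat_temperature)
        assert res.flux_umol_m2_h == 0.0

    def test_interval_slope_is_difference_quotient(self, geometry, flat_temperature):
        series = series_from([0.0, 12.0, 18.0], [400.0, 406.0, 409.0])
        r01, r12 = flux_by_interval(series, geometry, flat_temperature)
        assert r01.slope_ppmv_h == pytest.approx(0.5)
        assert r12.slope_ppmv_h == pytest.approx(0.5)
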