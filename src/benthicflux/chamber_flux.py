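"""Areal gas fluxes from closed-chamber headspace concentration series.

The flux is the product of the fitted concentration slope (ppmv h-1)
and the total moles of headspace air per unit sediment area:

    F [umol m-2 h-1] = slope * (P * V / (R * T)) / A

with P in atm, V in m3, R in atm m3 K-1 mol-1, T in Kelvin and A in m2.
Since ppmv is umol gas per mol of air, the bracket (total moles of air)
converts a mixing-ratio rate directly into a molar rate.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .models import (
    CELSIUS_TO_KELVIN,
    ChamberGeometry,
    Constants,
    FluxResult,
    FluxStatus,
    Gas,
    GasSeries,
    ValidationError,
)

__all__ = ["fit_slope", "mean_kelvin", "compute_flux", "flux_by_interval"]


def fit_slope(
    times: Sequence[float], concentrations: Sequence[float]
) -> tuple[float, float, int]:
    """Ordinary least-squares slope of concentration against time.

    Returns ``(slope_ppmv_h, r_squared, n_points)``. With exactly two
    points the slope is the difference quotient and r2 = 1. A constant
    series has slope 0 and, being fit exactly by a flat line, r2 = 1.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.size != c.size:
        raise ValidationError("times and concentrations differ in length")
    if t.size < 2 or np.unique(t).size < 2:
        raise ValidationError("need >= 2 points with distinct times")
    if np.ptp(c) == 0.0:
        return 0.0, 1.0, int(t.size)
    res = stats.linregress(t, c)
    return float(res.slope), float(res.rvalue**2), int(t.size)


def mean_kelvin(
    temperature_series: Sequence[tuple[float, float]],
    window: tuple[float, float],
) -> float:
    """Mean of the Celsius readings inside ``window`` (hours), in Kelvin.

    If no reading falls inside the window the nearest reading (by time
    distance to the interval) is used instead.
    """
    if not temperature_series:
        raise ValidationError("temperature series is empty")
    lo, hi = window
    if hi < lo:
        raise ValidationError("window end precedes window start")
    inside = [temp for t, temp in temperature_series if lo <= t <= hi]
    if inside:
        return float(np.mean(inside)) + CELSIUS_TO_KELVIN
    # fallback: nearest reading by distance to the interval
    def dist(t: float) -> float:
        return lo - t if t < lo else t - hi

    _, nearest = min(temperature_series, key=lambda pair: dist(pair[0]))
    return float(nearest) + CELSIUS_TO_KELVIN


def _headspace_moles(geometry: ChamberGeometry, t_kelvin: float, c: Constants) -> float:
    volume_m3 = geometry.headspace_volume_l / 1000.0
    return c.p_atm * volume_m3 / (c.r_gas * t_kelvin)


def compute_flux(
    series: GasSeries,
    geometry: ChamberGeometry,
    temperature_series: Sequence[tuple[float, float]],
    constants: Optional[Constants] = None,
    window: Optional[tuple[float, float]] = None,
    chamber_id: str = "",
    interval: str = "all",
) -> FluxResult:
    """Fit a slope to the detected samples and convert it to an areal flux.

    A series whose samples are all flagged non-detect yields a
    ``nondetect`` result; fewer than two detected points yield
    ``insufficient_points``. Neither carries flux values. Negative
    slopes are reported as negative fluxes (net uptake), never clipped.
    """
    constants = constants or Constants()
    detected = series.detected_samples
    if not detected and series.samples:
        return FluxResult(
            gas=series.gas,
            slope_ppmv_h=None,
            r_squared=None,
            n_points=0,
            mean_temperature_k=None,
            flux_umol_m2_h=None,
            flux_ug_m2_h=None,
            status=FluxStatus.NONDETECT,
            chamber_id=chamber_id,
            interval=interval,
        )
    if len(detected) < 2 or len({s.time_h for s in detected}) < 2:
        return FluxResult(
            gas=series.gas,
            slope_ppmv_h=None,
            r_squared=None,
            n_points=len(detected),
            mean_temperature_k=None,
            flux_umol_m2_h=None,
            flux_ug_m2_h=None,
            status=FluxStatus.INSUFFICIENT_POINTS,
            chamber_id=chamber_id,
            interval=interval,
        )

    times = [s.time_h for s in detected]
    concs = [s.concentration_ppmv for s in detected]
    slope, r2, n = fit_slope(times, concs)
    if window is None:
        window = (min(times), max(times))
    t_k = mean_kelvin(temperature_series, window)
    n_air = _headspace_moles(geometry, t_k, constants)
    flux_molar = slope * n_air / geometry.cross_sectional_area_m2
    flux_mass = (
        flux_molar * constants.ch4_molar_mass if series.gas == Gas.CH4 else None
    )
    return FluxResult(
        gas=series.gas,
        slope_ppmv_h=slope,
        r_squared=r2,
        n_points=n,
        mean_temperature_k=t_k,
        flux_umol_m2_h=flux_molar,
        flux_ug_m2_h=flux_mass,
        status=FluxStatus.OK,
        chamber_id=chamber_id,
        interval=interval,
    )


def flux_by_interval(
    series: GasSeries,
    geometry: ChamberGeometry,
    temperature_series: Sequence[tuple[float, float]],
    constants: Optional[Constants] = None,
    expected_labels: Optional[Sequence[str]] = None,
    chamber_id: str = "",
) -> list[FluxResult]:
    """One two-point flux per consecutive labeled sample pair.

    ``expected_labels`` defaults to the labels present in the series;
    pass the full deployment schedule (e.g. ``("t0", "t1", "t2")``) to
    surface intervals lost to a damaged chamber as
    ``insufficient_points`` records instead of silently dropping them.
    Each interval uses its own temperature window.
    """
    constants = constants or Constants()
    by_label = {s.label: s for s in series.samples}
    if expected_labels is None:
        expected_labels = [s.label for s in series.samples]
    results: list[FluxResult] = []
    for a, b in zip(expected_labels, expected_labels[1:]):
        interval = f"{a}-{b}"
        pair = [by_label.get(a), by_label.get(b)]
        present = [s for s in pair if s is not None]
        sub = GasSeries(gas=series.gas, samples=present)
        results.append(
            compute_flux(
                sub,
                geometry,
                temperature_series,
                constants,
                chamber_id=chamber_id,
                interval=interval,
            )
        )
    return results
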