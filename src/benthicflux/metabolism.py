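"""Community metabolism (CR, NCP, GPP) from diel dissolved-oxygen series.

The dark interval of a deployment gives hourly community respiration
(CR, negative for oxygen drawdown), the light interval gives hourly net
community production (NCP), and gross primary production is their sum,
GPP = CR + NCP. Daily rates scale hourly GPP by the photoperiod and
hourly CR by 24 h; the daily balance is NCP = GPP - CR with CR kept
signed, so respiration-driven drawdown is credited back to net
production. Oxygen rates double as carbon rates because the
photosynthetic and respiratory quotients both default to 1.
"""

from __future__ import annotations

from typing import Optional

from .models import (
    Constants,
    DOSeries,
    MetabolismResult,
    TrophicStatus,
    ValidationError,
)

__all__ = [
    "hourly_rate",
    "hourly_metabolism",
    "daily_ncp",
    "daily_metabolism",
    "classify_trophic",
]


def hourly_rate(
    do_start: float,
    do_end: float,
    dt_h: float,
    volume_l: float,
    area_m2: float,
    o2_molar_mass: float = 32.0,
) -> float:
    """Areal oxygen rate over one interval, mmol O2 m-2 h-1.

    ``(do_end - do_start) / dt * (volume / area) / molar_mass``; the
    sign is preserved, so an oxygen decline gives a negative rate.
    """
    if dt_h <= 0:
        raise ValidationError("interval duration must be > 0")
    if volume_l <= 0 or area_m2 <= 0:
        raise ValidationError("volume and area must be > 0")
    return (do_end - do_start) / dt_h * (volume_l / area_m2) / o2_molar_mass


def hourly_metabolism(
    do: DOSeries,
    volume_l: float,
    area_m2: float,
    constants: Optional[Constants] = None,
    dark_labels: tuple[str, str] = ("t0", "t1"),
    light_labels: tuple[str, str] = ("t1", "t2"),
) -> tuple[float, float, float]:
    """Hourly (CR, NCP, GPP) from labeled DO samples.

    CR comes from the dark interval, NCP from the light interval, and
    GPP = CR + NCP exactly. ``volume_l`` is the enclosed water volume,
    not the gas headspace. The interval-to-process mapping is
    configurable; the default matches an evening/dawn/noon schedule.
    """
    constants = constants or Constants()
    m = constants.o2_molar_mass

    def rate(labels: tuple[str, str]) -> float:
        start, end = (do.by_label(lbl) for lbl in labels)
        return hourly_rate(
            start.do_mg_per_l,
            end.do_mg_per_l,
            end.time_h - start.time_h,
            volume_l,
            area_m2,
            o2_molar_mass=m,
        )

    cr = rate(dark_labels)
    ncp = rate(light_labels)
    return cr, ncp, cr + ncp


def daily_ncp(gpp_daily: float, cr_daily: float) -> float:
    """Daily net community production: NCP = GPP - CR (CR signed)."""
    return gpp_daily - cr_daily


def daily_metabolism(
    hourly: tuple[float, float, float],
    photoperiod_h: float,
    constants: Optional[Constants] = None,
    trophic_threshold: float = 0.0,
    chamber_id: str = "",
    area_type=None,
) -> MetabolismResult:
    """Scale hourly rates to daily rates and classify trophic status.

    gpp_daily = gpp_hourly * photoperiod, cr_daily = cr_hourly * 24,
    ncp_daily = gpp_daily - cr_daily. The O2-to-carbon conversion is
    the identity in mmol because PQ = RQ = 1; units are relabeled
    mmol C.
    """
    constants = constants or Constants()
    if not (0 < photoperiod_h <= 24):
        raise ValidationError("photoperiod must be in (0, 24]")
    cr_hourly, ncp_hourly, _ = hourly
    # PQ/RQ scaling: mol C exchanged per mol O2 (both 1 by default).
    # GPP is rebuilt as CR + NCP after conversion so the oxygen-balance
    # identity holds bit-exactly for every result.
    cr_c = cr_hourly * constants.rq
    ncp_c = ncp_hourly / constants.pq
    gpp_c = cr_c + ncp_c
    gpp_daily = gpp_c * photoperiod_h
    cr_daily = cr_c * 24.0
    ncp_d = daily_ncp(gpp_daily, cr_daily)
    return MetabolismResult(
        cr_hourly=cr_c,
        ncp_hourly=ncp_c,
        gpp_hourly=gpp_c,
        gpp_daily=gpp_daily,
        cr_daily=cr_daily,
        ncp_daily=ncp_d,
        trophic_status=classify_trophic(ncp_d, trophic_threshold),
        chamber_id=chamber_id,
        area_type=area_type,
    )


def classify_trophic(ncp_daily: float, threshold: float = 0.0) -> TrophicStatus:
    """Autotrophic above ``threshold``, heterotrophic below ``-threshold``,
    balanced in between. ``threshold`` defaults to 0 (metabolic balance);
    a stricter positive cutoff may be configured."""
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    if ncp_daily > threshold:
        return TrophicStatus.AUTOTROPHIC
    if ncp_daily < -threshold:
        return TrophicStatus.HETEROTROPHIC
    return TrophicStatus.BALANCED
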