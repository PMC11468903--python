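"""Domain types shared by every pipeline stage.

All sample times are decimal hours since chamber closure (t = 0 at the
first post-setup sample); clock labels such as ``t0``/``t1``/``t2`` are
carried as metadata only. Concentrations are ppmv, dissolved oxygen is
mg O2 L-1, temperatures are degrees Celsius until explicitly converted
to Kelvin.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "AreaType",
    "Gas",
    "FluxStatus",
    "TrophicStatus",
    "Constants",
    "ChamberGeometry",
    "GasSample",
    "GasSeries",
    "DOSample",
    "DOSeries",
    "ChamberDeployment",
    "FluxResult",
    "MetabolismResult",
    "BenthicFluxError",
    "SchemaError",
    "ValidationError",
]

CELSIUS_TO_KELVIN = 273.15


class BenthicFluxError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(BenthicFluxError):
    """An input file does not conform to the documented column schema."""


class ValidationError(BenthicFluxError):
    """A value or series violates a domain invariant."""


class AreaType(str, enum.Enum):
    VEGETATED = "vegetated"
    BARE = "bare"


class Gas(str, enum.Enum):
    CO2 = "CO2"
    CH4 = "CH4"


class FluxStatus(str, enum.Enum):
    OK = "ok"
    NONDETECT = "nondetect"
    INSUFFICIENT_POINTS = "insufficient_points"


class TrophicStatus(str, enum.Enum):
    AUTOTROPHIC = "autotrophic"
    HETEROTROPHIC = "heterotrophic"
    BALANCED = "balanced"


@dataclass(frozen=True)
class Constants:
    """Physical constants and conversion factors.

    Attributes
    ----------
    r_gas:
        Ideal gas constant in atm m3 K-1 mol-1.
    p_atm:
        Barometric pressure in atm.
    o2_molar_mass, co2_molar_mass, ch4_molar_mass:
        Molar masses in g mol-1.
    pq, rq:
        Photosynthetic and respiratory quotients (mol CO2 per mol O2);
        both default to 1, making O2-based rates numerically equal to
        carbon rates.
    sgwp_ch4:
        Sustained-flux global warming potential multiplier for CH4,
        conventionally in [45, 96]; the conservative low end is the
        default.
    """

    r_gas: float = 8.205746e-5
    p_atm: float = 1.0
    o2_molar_mass: float = 32.0
    co2_molar_mass: float = 44.01
    ch4_molar_mass: float = 16.04
    pq: float = 1.0
    rq: float = 1.0
    sgwp_ch4: float = 45.0

    def __post_init__(self) -> None:
        for name in (
            "r_gas",
            "p_atm",
            "o2_molar_mass",
            "co2_molar_mass",
            "ch4_molar_mass",
            "pq",
            "rq",
            "sgwp_ch4",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"Constants.{name} must be strictly positive")

    def molar_mass(self, gas: Gas) -> float:
        if gas == Gas.CO2:
            return self.co2_molar_mass
        if gas == Gas.CH4:
            return self.ch4_molar_mass
        raise ValidationError(f"unknown gas: {gas!r}")


@dataclass(frozen=True)
class ChamberGeometry:
    """Chamber dimensions. Cross-sectional area in m2, headspace in L."""

    cross_sectional_area_m2: float
    headspace_volume_l: float
    chamber_length_cm: Optional[float] = None
    insertion_depth_cm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cross_sectional_area_m2 <= 0:
            raise ValidationError("cross_sectional_area_m2 must be > 0")
        if self.headspace_volume_l <= 0:
            raise ValidationError("headspace_volume_l must be > 0")
        if (
            self.chamber_length_cm is not None
            and self.insertion_depth_cm is not None
            and self.insertion_depth_cm >= self.chamber_length_cm
        ):
            raise ValidationError("insertion_depth_cm must be < chamber_length_cm")


@dataclass(frozen=True)
class GasSample:
    label: str
    time_h: float
    concentration_ppmv: Optional[float]
    detected: bool = True

    def __post_init__(self) -> None:
        if self.detected:
            if self.concentration_ppmv is None:
                raise ValidationError(
                    f"sample {self.label!r}: detected sample needs a concentration"
                )
            if self.concentration_ppmv < 0:
                raise ValidationError(
                    f"sample {self.label!r}: concentration must be >= 0"
                )


def _check_strictly_increasing(times: Sequence[float], what: str) -> None:
    for a, b in zip(times, times[1:]):
        if b <= a:
            raise ValidationError(f"{what}: times must be strictly increasing")


@dataclass
class GasSeries:
    """Headspace concentration time series for one gas in one chamber."""

    gas: Gas
    samples: list[GasSample]

    def __post_init__(self) -> None:
        self.gas = Gas(self.gas)
        _check_strictly_increasing([s.time_h for s in self.samples], "GasSeries")

    @property
    def detected_samples(self) -> list[GasSample]:
        return [s for s in self.samples if s.detected]


@dataclass(frozen=True)
class DOSample:
    label: str
    time_h: float
    do_mg_per_l: float

    def __post_init__(self) -> None:
        if self.do_mg_per_l < 0:
            raise ValidationError(f"sample {self.label!r}: DO must be >= 0")


@dataclass
class DOSeries:
    """Dissolved-oxygen time series for one chamber."""

    samples: list[DOSample]

    def __post_init__(self) -> None:
        _check_strictly_increasing([s.time_h for s in self.samples], "DOSeries")

    def by_label(self, label: str) -> DOSample:
        for s in self.samples:
            if s.label == label:
                return s
        raise ValidationError(f"DO series is missing required sample label {label!r}")


@dataclass
class ChamberDeployment:
    """One chamber: geometry, metadata, and its attached sample series.

    ``water_volume_l`` is the enclosed water-phase volume used by the
    oxygen-based metabolism rates; it is distinct from the gas headspace
    volume in :class:`ChamberGeometry`.
    """

    chamber_id: str
    area_type: AreaType
    geometry: ChamberGeometry
    photoperiod_h: float
    species_label: str = ""
    patch_area_ha: Optional[float] = None
    water_volume_l: Optional[float] = None
    temperature_series: list[tuple[float, float]] = field(default_factory=list)
    gas_series: dict[Gas, GasSeries] = field(default_factory=dict)
    do_series: Optional[DOSeries] = None

    def __post_init__(self) -> None:
        self.area_type = AreaType(self.area_type)
        if not (0 < self.photoperiod_h <= 24):
            raise ValidationError(
                f"chamber {self.chamber_id!r}: photoperiod must be in (0, 24]"
            )
        if self.patch_area_ha is not None and self.patch_area_ha <= 0:
            raise ValidationError(f"chamber {self.chamber_id!r}: patch_area_ha <= 0")
        if self.water_volume_l is not None and self.water_volume_l <= 0:
            raise ValidationError(f"chamber {self.chamber_id!r}: water_volume_l <= 0")


@dataclass(frozen=True)
class FluxResult:
    """A fitted areal gas flux plus its fit diagnostics.

    ``flux_umol_m2_h`` carries the molar flux; ``flux_ug_m2_h`` is the
    mass-based flux (reported for CH4 only). Both are ``None`` unless
    ``status`` is ``ok``.
    """

    gas: Gas
    slope_ppmv_h: Optional[float]
    r_squared: Optional[float]
    n_points: int
    mean_temperature_k: Optional[float]
    flux_umol_m2_h: Optional[float]
    flux_ug_m2_h: Optional[float]
    status: FluxStatus
    chamber_id: str = ""
    interval: str = "all"

    def __post_init__(self) -> None:
        if self.status != FluxStatus.OK and self.flux_umol_m2_h is not None:
            raise ValidationError("non-ok flux result must not carry flux values")


@dataclass(frozen=True)
class MetabolismResult:
    """Hourly and daily community metabolism in carbon units.

    Units: hourly rates mmol C m-2 h-1, daily rates mmol C m-2 d-1.
    Community respiration (CR) is carried with its sign (oxygen
    consumption is negative), so the daily balance
    ``ncp_daily = gpp_daily - cr_daily`` credits respiration-driven
    oxygen drawdown back to net production.
    """

    cr_hourly: float
    ncp_hourly: float
    gpp_hourly: float
    gpp_daily: float
    cr_daily: float
    ncp_daily: float
    trophic_status: TrophicStatus
    chamber_id: str = ""
    area_type: Optional[AreaType] = None
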