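"""Forward simulation of chamber deployments with known ground truth.

Gas accumulation is generated by inverting the ideal-gas flux equation:
a target areal flux is converted to a concentration slope using the
same headspace-moles bracket the flux estimator divides by, so a
noiseless simulation round-trips exactly. Dissolved oxygen declines at
the configured respiration rate in the dark interval and changes at the
net (production + respiration) rate in the light interval(s).

Ground truth is reported on the estimator's scale: ``cr = r_hourly``,
``ncp = p_hourly + r_hourly`` and ``gpp = cr + ncp`` (the oxygen-balance
identity the metabolism stage enforces).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .chamber_flux import mean_kelvin
from .models import (
    AreaType,
    ChamberDeployment,
    ChamberGeometry,
    Constants,
    DOSample,
    DOSeries,
    Gas,
    GasSample,
    GasSeries,
    ValidationError,
)

__all__ = [
    "AreaSpec",
    "SimulationConfig",
    "simulate_gas_series",
    "simulate_do_series",
    "simulate_study",
    "write_study",
    "ground_truth",
]


def _default_temperature_profile() -> list[tuple[float, float]]:
    """Hourly sinusoid spanning the 24.2-33.6 degC field range.

    Peak mid-afternoon (hour 21 of a deployment starting at 6 pm).
    """
    lo, hi = 24.2, 33.6
    mid, amp = (lo + hi) / 2.0, (hi - lo) / 2.0
    return [
        (float(h), mid + amp * math.sin(2.0 * math.pi * (h - 15.0) / 24.0))
        for h in range(0, 19)
    ]


@dataclass(frozen=True)
class AreaSpec:
    label: str
    area_type: AreaType
    patch_area_ha: Optional[float] = None


DEFAULT_AREAS = (
    AreaSpec("bare_sand", AreaType.BARE, 1.0),
    AreaSpec("E_acoroides", AreaType.VEGETATED, 0.15),
    AreaSpec("T_hemprichii", AreaType.VEGETATED, 0.10),
)

# Area-mean fluxes (umol m-2 h-1) used as default simulation targets.
DEFAULT_TRUE_FLUX = {
    ("bare_sand", Gas.CO2): 0.0082,
    ("E_acoroides", Gas.CO2): 0.143,
    ("T_hemprichii", Gas.CO2): 0.0489,
    ("bare_sand", Gas.CH4): 0.0,
    ("E_acoroides", Gas.CH4): 0.130,
    ("T_hemprichii", Gas.CH4): 0.084,
}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chambers_per_area: int = 3
    areas: tuple[AreaSpec, ...] = DEFAULT_AREAS
    true_flux: dict[tuple[str, Gas], float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_FLUX)
    )
    r_hourly: float = -0.1458  # true respiration, mmol O2 m-2 h-1 (negative)
    p_hourly: float = 0.419  # true light-period gross production
    gas_noise_sd: float = 0.1  # ppmv
    do_noise_sd: float = 0.02  # mg O2 L-1
    detection_limit_ch4: float = 2.5  # ppmv
    sample_times: tuple[float, ...] = (0.0, 12.0, 18.0)
    sample_labels: tuple[str, ...] = ("t0", "t1", "t2")
    geometry: ChamberGeometry = field(
        default_factory=lambda: ChamberGeometry(0.25, 10.0, 120.0, 15.0)
    )
    water_volume_l: float = 50.0
    photoperiod_h: float = 12.0
    temperature_profile: list[tuple[float, float]] = field(
        default_factory=_default_temperature_profile
    )
    c0_ppmv: dict[Gas, float] = field(
        default_factory=lambda: {Gas.CO2: 420.0, Gas.CH4: 2.0}
    )
    do_initial: float = 7.0
    constants: Constants = field(default_factory=Constants)

    def __post_init__(self) -> None:
        if self.gas_noise_sd < 0 or self.do_noise_sd < 0:
            raise ValidationError("noise SDs must be >= 0")
        if self.detection_limit_ch4 < 0:
            raise ValidationError("detection_limit_ch4 must be >= 0")
        if len(self.sample_times) != len(self.sample_labels):
            raise ValidationError("sample_times and sample_labels differ in length")
        if self.sample_times and self.sample_times[0] != 0.0:
            raise ValidationError("sample_times must start at 0")
        for a, b in zip(self.sample_times, self.sample_times[1:]):
            if b <= a:
                raise ValidationError("sample_times must be strictly increasing")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _slope_for_flux(config: SimulationConfig, flux_umol_m2_h: float) -> float:
    """Invert the flux equation: concentration slope giving a target flux."""
    c = config.constants
    window = (min(config.sample_times), max(config.sample_times))
    t_k = mean_kelvin(config.temperature_profile, window)
    n_air = c.p_atm * (config.geometry.headspace_volume_l / 1000.0) / (c.r_gas * t_k)
    return flux_umol_m2_h * config.geometry.cross_sectional_area_m2 / n_air


def simulate_gas_series(
    config: SimulationConfig,
    area_label: str,
    gas: Gas,
    rng: Optional[np.random.Generator] = None,
) -> GasSeries:
    """Linear-in-time headspace accumulation with additive Gaussian noise.

    CH4 samples whose concentration falls below the detection limit are
    flagged non-detect (their value is withheld, mimicking an
    instrument that reports nothing below its sensitivity).
    """
    gas = Gas(gas)
    rng = config.rng() if rng is None else rng
    try:
        flux = config.true_flux[(area_label, gas)]
    except KeyError:
        raise ValidationError(f"no true flux configured for ({area_label!r}, {gas})")
    slope = _slope_for_flux(config, flux)
    c0 = config.c0_ppmv[gas]
    samples = []
    for label, t in zip(config.sample_labels, config.sample_times):
        conc = c0 + slope * t + rng.normal(0.0, config.gas_noise_sd)
        conc = max(conc, 0.0)
        detected = gas != Gas.CH4 or conc >= config.detection_limit_ch4
        samples.append(
            GasSample(
                label=label,
                time_h=t,
                concentration_ppmv=conc if detected else None,
                detected=detected,
            )
        )
    return GasSeries(gas=gas, samples=samples)


def simulate_do_series(
    config: SimulationConfig,
    area_label: str = "",
    rng: Optional[np.random.Generator] = None,
) -> DOSeries:
    """Diel DO: respiration-only drawdown in the first (dark) interval,
    net production + respiration afterwards; floored at 0."""
    rng = config.rng() if rng is None else rng
    # mg L-1 change per (mmol m-2): rate * area / volume * molar mass
    conv = (
        config.constants.o2_molar_mass
        * config.geometry.cross_sectional_area_m2
        / config.water_volume_l
    )
    do = config.do_initial
    samples = []
    prev_t = config.sample_times[0]
    for i, (label, t) in enumerate(zip(config.sample_labels, config.sample_times)):
        if i > 0:
            rate = config.r_hourly if i == 1 else config.p_hourly + config.r_hourly
            do = do + rate * conv * (t - prev_t)
        noisy = max(do + rng.normal(0.0, config.do_noise_sd), 0.0)
        samples.append(DOSample(label=label, time_h=t, do_mg_per_l=noisy))
        prev_t = t
    return DOSeries(samples=samples)


def ground_truth(config: SimulationConfig) -> dict[str, float]:
    """Truth on the estimator's scale (mmol O2 m-2 h-1)."""
    cr = config.r_hourly
    ncp = config.p_hourly + config.r_hourly
    return {"cr_hourly": cr, "ncp_hourly": ncp, "gpp_hourly": cr + ncp}


def simulate_study(config: SimulationConfig) -> list[ChamberDeployment]:
    """A full multi-area, multi-chamber synthetic deployment set.

    One shared generator seeded from ``config.seed`` drives every draw
    in a fixed order, so the whole study is reproducible.
    """
    rng = config.rng()
    deployments: list[ChamberDeployment] = []
    for area in config.areas:
        for i in range(1, config.n_chambers_per_area + 1):
            chamber_id = f"{area.label}-{i}"
            gas_series = {
                gas: simulate_gas_series(config, area.label, gas, rng=rng)
                for gas in (Gas.CO2, Gas.CH4)
            }
            do_series = simulate_do_series(config, area.label, rng=rng)
            deployments.append(
                ChamberDeployment(
                    chamber_id=chamber_id,
                    area_type=area.area_type,
                    species_label="" if area.area_type == AreaType.BARE else area.label,
                    patch_area_ha=area.patch_area_ha,
                    geometry=config.geometry,
                    photoperiod_h=config.photoperiod_h,
                    water_volume_l=config.water_volume_l,
                    temperature_series=list(config.temperature_profile),
                    gas_series=gas_series,
                    do_series=do_series,
                )
            )
    return deployments


def write_study(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write deployments.csv, temperature.csv and truth.csv to ``out_dir``."""
    from . import io as bfio  # deferred: io imports models only

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    deployments = simulate_study(config)
    paths = {
        "deployments": out / "deployments.csv",
        "temperature": out / "temperature.csv",
        "truth": out / "truth.csv",
    }
    bfio.write_deployments(deployments, paths["deployments"])
    bfio.write_temperature_log(config.temperature_profile, paths["temperature"])

    truth_rows = []
    for (label, gas), flux in sorted(config.true_flux.items(), key=lambda kv: (kv[0][0], kv[0][1].value)):
        truth_rows.append(
            {"area_label": label, "quantity": f"flux_{gas.value}_umol_m2_h", "value": flux}
        )
    for key, value in ground_truth(config).items():
        truth_rows.append({"area_label": "all", "quantity": key, "value": value})
    import pandas as pd

    pd.DataFrame(truth_rows).to_csv(paths["truth"], index=False)
    return paths
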