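"""Patch-level emission totals and CH4 CO2-equivalent accounting."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from .models import Constants, Gas, ValidationError

__all__ = ["BudgetEntry", "upscale", "co2_equivalent", "build_budget_entry"]

M2_PER_HA = 1.0e4

# Conventional bounds for the sustained-flux warming multiplier of CH4.
SGWP_CH4_RANGE = (45.0, 96.0)


@dataclass(frozen=True)
class BudgetEntry:
    area_type: str
    gas: Gas
    patch_area_ha: float
    areal_flux_umol_m2_h: float
    duration_h: float
    total_emission_g: float
    co2_equivalent_g: Optional[float]
    sgwp_used: Optional[float]


def upscale(
    areal_flux_umol_m2_h: float,
    patch_area_ha: float,
    duration_h: float,
    gas: Gas,
    constants: Optional[Constants] = None,
) -> float:
    """Total emission in grams: flux x patch area x duration x molar mass.

    The flux sign is preserved, so net uptake yields a negative total.
    """
    constants = constants or Constants()
    gas = Gas(gas)
    if patch_area_ha <= 0:
        raise ValidationError("patch_area_ha must be > 0")
    if duration_h <= 0:
        raise ValidationError("duration_h must be > 0")
    mol = areal_flux_umol_m2_h * 1e-6 * patch_area_ha * M2_PER_HA * duration_h
    return mol * constants.molar_mass(gas)


def co2_equivalent(ch4_mass_g: float, sgwp: float) -> float:
    """CH4 mass times its sustained-flux warming multiplier.

    Warns when ``sgwp`` is outside the conventional 45-96 range.
    """
    if ch4_mass_g < 0:
        raise ValidationError("ch4_mass_g must be >= 0")
    lo, hi = SGWP_CH4_RANGE
    if not (lo <= sgwp <= hi):
        warnings.warn(
            f"SGWP {sgwp} is outside the conventional [{lo:g}, {hi:g}] range",
            stacklevel=2,
        )
    return ch4_mass_g * sgwp


def build_budget_entry(
    area_type: str,
    gas: Gas,
    areal_flux_umol_m2_h: float,
    patch_area_ha: float,
    duration_h: float,
    constants: Optional[Constants] = None,
) -> BudgetEntry:
    """Upscale one areal flux; CH4 additionally gets a CO2-equivalent."""
    constants = constants or Constants()
    gas = Gas(gas)
    total = upscale(areal_flux_umol_m2_h, patch_area_ha, duration_h, gas, constants)
    if gas == Gas.CH4 and total >= 0:
        eq = co2_equivalent(total, constants.sgwp_ch4)
        sgwp = constants.sgwp_ch4
    else:
        eq, sgwp = None, None
    return BudgetEntry(
        area_type=area_type,
        gas=gas,
        patch_area_ha=patch_area_ha,
        areal_flux_umol_m2_h=areal_flux_umol_m2_h,
        duration_h=duration_h,
        total_emission_g=total,
        co2_equivalent_g=eq,
        sgwp_used=sgwp,
    )
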