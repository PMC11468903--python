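"""Glue between deployments and per-stage computations.

These helpers are what the CLI drives; tests use them directly for
end-to-end checks.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .budget import BudgetEntry, build_budget_entry
from .chamber_flux import compute_flux, flux_by_interval
from .io import _flux_row
from .metabolism import daily_metabolism, hourly_metabolism
from .models import (
    ChamberDeployment,
    Constants,
    FluxResult,
    FluxStatus,
    Gas,
    MetabolismResult,
    ValidationError,
)

__all__ = [
    "run_flux",
    "run_metabolism",
    "run_budget",
    "flux_frame",
    "area_mean_fluxes",
]


def run_flux(
    deployments: Sequence[ChamberDeployment],
    constants: Optional[Constants] = None,
    per_interval: bool = False,
    temperature_series: Optional[Sequence[tuple[float, float]]] = None,
) -> list[FluxResult]:
    """Whole-series (and optionally per-interval) fluxes for every
    chamber and gas. ``temperature_series`` overrides the per-chamber
    series (the common case: one shared logger per study)."""
    constants = constants or Constants()
    results: list[FluxResult] = []
    for d in deployments:
        temps = temperature_series or d.temperature_series
        if not temps:
            raise ValidationError(
                f"chamber {d.chamber_id!r}: no temperature readings available"
            )
        for gas, series in d.gas_series.items():
            results.append(
                compute_flux(
                    series,
                    d.geometry,
                    temps,
                    constants,
                    chamber_id=d.chamber_id,
                )
            )
            if per_interval:
                results.extend(
                    flux_by_interval(
                        series,
                        d.geometry,
                        temps,
                        constants,
                        chamber_id=d.chamber_id,
                    )
                )
    return results


def run_metabolism(
    deployments: Sequence[ChamberDeployment],
    constants: Optional[Constants] = None,
    trophic_threshold: float = 0.0,
) -> list[MetabolismResult]:
    constants = constants or Constants()
    results: list[MetabolismResult] = []
    for d in deployments:
        if d.do_series is None:
            continue
        volume = d.water_volume_l
        if volume is None:
            # documented fallback; a real water-phase volume is preferred
            volume = d.geometry.headspace_volume_l
        hourly = hourly_metabolism(
            d.do_series,
            volume_l=volume,
            area_m2=d.geometry.cross_sectional_area_m2,
            constants=constants,
        )
        results.append(
            daily_metabolism(
                hourly,
                d.photoperiod_h,
                constants,
                trophic_threshold=trophic_threshold,
                chamber_id=d.chamber_id,
                area_type=d.area_type,
            )
        )
    return results


def flux_frame(
    results: Sequence[FluxResult],
    deployments: Optional[Sequence[ChamberDeployment]] = None,
) -> pd.DataFrame:
    """Flux results as a tidy frame, optionally annotated with the
    deployment's area metadata."""
    df = pd.DataFrame([_flux_row(r) for r in results])
    if deployments is not None and not df.empty:
        meta = pd.DataFrame(
            [
                {
                    "chamber_id": d.chamber_id,
                    "area_type": d.area_type.value,
                    "area_label": d.species_label or d.area_type.value,
                    "patch_area_ha": d.patch_area_ha,
                }
                for d in deployments
            ]
        )
        df = df.merge(meta, on="chamber_id", how="left")
    return df


def area_mean_fluxes(frame: pd.DataFrame, by: str = "area_label") -> pd.DataFrame:
    """Per-area, per-gas mean flux over chambers with status ``ok``.

    Non-detect and insufficient-point chambers are excluded, never
    zero-imputed; an area whose chambers are all non-ok for a gas
    simply has no row.
    """
    ok = frame[frame["status"] == FluxStatus.OK.value]
    if ok.empty:
        return pd.DataFrame(columns=[by, "gas", "mean_flux_umol_m2_h", "n_chambers"])
    grouped = (
        ok.groupby([by, "gas"])["flux_umol_m2_h"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_flux_umol_m2_h", "count": "n_chambers"})
    )
    return grouped


def run_budget(
    flux_results: Sequence[FluxResult],
    deployments: Sequence[ChamberDeployment],
    duration_h: float,
    constants: Optional[Constants] = None,
) -> list[BudgetEntry]:
    """Area-mean fluxes upscaled to patch totals (CH4 also in CO2-eq)."""
    constants = constants or Constants()
    frame = flux_frame(flux_results, deployments)
    frame = frame[frame["interval"] == "all"]
    patch = {
        (d.species_label or d.area_type.value): d.patch_area_ha for d in deployments
    }
    means = area_mean_fluxes(frame)
    entries: list[BudgetEntry] = []
    for _, row in means.iterrows():
        area_label = row["area_label"]
        patch_ha = patch.get(area_label)
        if patch_ha is None:
            continue
        entries.append(
            build_budget_entry(
                area_type=area_label,
                gas=Gas(row["gas"]),
                areal_flux_umol_m2_h=float(row["mean_flux_umol_m2_h"]),
                patch_area_ha=patch_ha,
                duration_h=duration_h,
                constants=constants,
            )
        )
    return entries
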