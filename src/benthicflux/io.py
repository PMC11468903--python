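"""Delimited-file readers and writers for the chamber-data dialect.

``deployments.csv`` is a long-format table: chamber metadata is
repeated on every row; a row carries either one gas sample (``gas`` +
``conc_ppmv``, with the literal token ``ND`` for a non-detect) or one
dissolved-oxygen sample (``do_mg_per_L``), or both. ``temperature.csv``
is a minimal two-column (ISO-8601 timestamp, temp_C) log; vendor
exports must be pre-converted. Decimal separator is the period, the
field delimiter the comma.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .models import (
    AreaType,
    ChamberDeployment,
    ChamberGeometry,
    DOSample,
    DOSeries,
    FluxResult,
    FluxStatus,
    Gas,
    GasSample,
    GasSeries,
    MetabolismResult,
    SchemaError,
    TrophicStatus,
    ValidationError,
)

__all__ = [
    "read_deployments",
    "write_deployments",
    "read_temperature_log",
    "write_temperature_log",
    "write_results",
    "read_flux_results",
    "read_metabolism_results",
]

NONDETECT_TOKEN = "ND"

DEPLOYMENT_COLUMNS = [
    "chamber_id",
    "area_type",
    "species_label",
    "patch_area_ha",
    "area_m2",
    "headspace_volume_L",
    "chamber_length_cm",
    "insertion_depth_cm",
    "photoperiod_h",
    "sample_label",
    "time_h",
    "gas",
    "conc_ppmv",
    "do_mg_per_L",
]
# extension column; optional for backwards compatibility with the
# documented dialect (falls back to the headspace volume, with the
# caveat that metabolism should be fed a real water volume)
WATER_VOLUME_COLUMN = "water_volume_L"

FLUX_COLUMNS = [
    "chamber_id",
    "gas",
    "interval",
    "slope_ppmv_h",
    "r2",
    "n",
    "T_K",
    "flux_umol_m2_h",
    "flux_ug_m2_h",
    "status",
]

METABOLISM_COLUMNS = [
    "chamber_id",
    "area_type",
    "cr_hourly_mmolC_m2_h",
    "ncp_hourly_mmolC_m2_h",
    "gpp_hourly_mmolC_m2_h",
    "gpp_daily_mmolC_m2_d",
    "cr_daily_mmolC_m2_d",
    "ncp_daily_mmolC_m2_d",
    "trophic_status",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _parse_float(value, row_line: int, column: str, optional: bool = False):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        if optional:
            return None
        raise SchemaError(f"line {row_line}: missing value in column {column!r}")
    s = str(value).strip()
    if s == "":
        if optional:
            return None
        raise SchemaError(f"line {row_line}: missing value in column {column!r}")
    try:
        return float(s)
    except ValueError:
        raise SchemaError(
            f"line {row_line}: cannot parse {column!r} value {s!r} as a number"
        )


def read_deployments(path: Union[str, Path], constants=None) -> list[ChamberDeployment]:
    """Parse a long-format deployments CSV into chamber objects.

    Rows are grouped by ``chamber_id`` (order of first appearance) and
    time-sorted within each series; duplicate times within a chamber's
    series raise a validation error naming the chamber. Malformed
    values are reported with their 1-based file line number.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, DEPLOYMENT_COLUMNS, path)
    has_water = WATER_VOLUME_COLUMN in df.columns

    deployments: list[ChamberDeployment] = []
    for chamber_id, group in df.groupby("chamber_id", sort=False):
        first = group.iloc[0]
        first_line = int(group.index[0]) + 2
        geometry = ChamberGeometry(
            cross_sectional_area_m2=_parse_float(first["area_m2"], first_line, "area_m2"),
            headspace_volume_l=_parse_float(
                first["headspace_volume_L"], first_line, "headspace_volume_L"
            ),
            chamber_length_cm=_parse_float(
                first["chamber_length_cm"], first_line, "chamber_length_cm", optional=True
            ),
            insertion_depth_cm=_parse_float(
                first["insertion_depth_cm"], first_line, "insertion_depth_cm", optional=True
            ),
        )
        try:
            area_type = AreaType(first["area_type"].strip())
        except ValueError:
            raise SchemaError(
                f"line {first_line}: unknown area_type {first['area_type']!r}"
            )
        water_volume = (
            _parse_float(first[WATER_VOLUME_COLUMN], first_line, WATER_VOLUME_COLUMN, optional=True)
            if has_water
            else None
        )

        gas_rows: dict[Gas, list[tuple[GasSample, int]]] = {}
        do_rows: list[tuple[DOSample, int]] = []
        for idx, row in group.iterrows():
            line = int(idx) + 2
            label = str(row["sample_label"]).strip()
            time_h = _parse_float(row["time_h"], line, "time_h")
            gas_token = str(row["gas"]).strip()
            if gas_token:
                try:
                    gas = Gas(gas_token)
                except ValueError:
                    raise SchemaError(f"line {line}: unknown gas {gas_token!r}")
                conc_token = str(row["conc_ppmv"]).strip()
                if conc_token.upper() == NONDETECT_TOKEN:
                    sample = GasSample(label, time_h, None, detected=False)
                else:
                    conc = _parse_float(conc_token, line, "conc_ppmv")
                    sample = GasSample(label, time_h, conc, detected=True)
                gas_rows.setdefault(gas, []).append((sample, line))
            do_token = str(row["do_mg_per_L"]).strip()
            if do_token:
                do = _parse_float(do_token, line, "do_mg_per_L")
                do_rows.append((DOSample(label, time_h, do), line))

        gas_series = {}
        for gas, rows in gas_rows.items():
            rows.sort(key=lambda r: r[0].time_h)
            times = [r[0].time_h for r in rows]
            if len(set(times)) != len(times):
                raise ValidationError(
                    f"chamber {chamber_id!r}: duplicate sample times for {gas.value}"
                )
            gas_series[gas] = GasSeries(gas=gas, samples=[r[0] for r in rows])
        do_series = None
        if do_rows:
            do_rows.sort(key=lambda r: r[0].time_h)
            times = [r[0].time_h for r in do_rows]
            if len(set(times)) != len(times):
                raise ValidationError(
                    f"chamber {chamber_id!r}: duplicate DO sample times"
                )
            do_series = DOSeries(samples=[r[0] for r in do_rows])

        deployments.append(
            ChamberDeployment(
                chamber_id=str(chamber_id),
                area_type=area_type,
                species_label=str(first["species_label"]).strip(),
                patch_area_ha=_parse_float(
                    first["patch_area_ha"], first_line, "patch_area_ha", optional=True
                ),
                geometry=geometry,
                photoperiod_h=_parse_float(first["photoperiod_h"], first_line, "photoperiod_h"),
                water_volume_l=water_volume,
                gas_series=gas_series,
                do_series=do_series,
            )
        )
    return deployments


def write_deployments(deployments: Sequence[ChamberDeployment], path) -> Path:
    """Inverse of :func:`read_deployments` (one row per sample)."""
    path = Path(path)
    rows = []
    for d in deployments:
        meta = {
            "chamber_id": d.chamber_id,
            "area_type": d.area_type.value,
            "species_label": d.species_label,
            "patch_area_ha": "" if d.patch_area_ha is None else d.patch_area_ha,
            "area_m2": d.geometry.cross_sectional_area_m2,
            "headspace_volume_L": d.geometry.headspace_volume_l,
            "chamber_length_cm": "" if d.geometry.chamber_length_cm is None else d.geometry.chamber_length_cm,
            "insertion_depth_cm": "" if d.geometry.insertion_depth_cm is None else d.geometry.insertion_depth_cm,
            "photoperiod_h": d.photoperiod_h,
            WATER_VOLUME_COLUMN: "" if d.water_volume_l is None else d.water_volume_l,
        }
        for gas, series in d.gas_series.items():
            for s in series.samples:
                rows.append(
                    meta
                    | {
                        "sample_label": s.label,
                        "time_h": s.time_h,
                        "gas": gas.value,
                        "conc_ppmv": NONDETECT_TOKEN if not s.detected else s.concentration_ppmv,
                        "do_mg_per_L": "",
                    }
                )
        if d.do_series is not None:
            for s in d.do_series.samples:
                rows.append(
                    meta
                    | {
                        "sample_label": s.label,
                        "time_h": s.time_h,
                        "gas": "",
                        "conc_ppmv": "",
                        "do_mg_per_L": s.do_mg_per_l,
                    }
                )
    columns = DEPLOYMENT_COLUMNS + [WATER_VOLUME_COLUMN]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
    return path


_EPOCH = _dt.datetime(2023, 6, 1, 18, 0, 0)


def read_temperature_log(path: Union[str, Path]) -> list[tuple[float, float]]:
    """Two-column (ISO timestamp, degC) log -> hours since first row.

    Timestamps must be strictly increasing; unparseable rows are
    reported with their line number.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["timestamp", "temp_C"], path)
    out: list[tuple[float, float]] = []
    t0: Optional[_dt.datetime] = None
    prev: Optional[float] = None
    for idx, row in df.iterrows():
        line = int(idx) + 2
        try:
            ts = _dt.datetime.fromisoformat(str(row["timestamp"]).strip())
        except ValueError:
            raise SchemaError(
                f"line {line}: cannot parse timestamp {row['timestamp']!r}"
            )
        temp = _parse_float(row["temp_C"], line, "temp_C")
        if t0 is None:
            t0 = ts
        hours = (ts - t0).total_seconds() / 3600.0
        if prev is not None and hours <= prev:
            raise ValidationError(f"line {line}: timestamps out of order")
        out.append((hours, temp))
        prev = hours
    return out


def write_temperature_log(
    series: Sequence[tuple[float, float]], path, start: Optional[_dt.datetime] = None
) -> Path:
    path = Path(path)
    start = start or _EPOCH
    rows = [
        {
            "timestamp": (start + _dt.timedelta(hours=h)).isoformat(sep=" "),
            "temp_C": temp,
        }
        for h, temp in series
    ]
    pd.DataFrame(rows, columns=["timestamp", "temp_C"]).to_csv(path, index=False)
    return path


def _flux_row(r: FluxResult) -> dict:
    return {
        "chamber_id": r.chamber_id,
        "gas": r.gas.value,
        "interval": r.interval,
        "slope_ppmv_h": r.slope_ppmv_h,
        "r2": r.r_squared,
        "n": r.n_points,
        "T_K": r.mean_temperature_k,
        "flux_umol_m2_h": r.flux_umol_m2_h,
        "flux_ug_m2_h": r.flux_ug_m2_h,
        "status": r.status.value,
    }


def _metabolism_row(r: MetabolismResult) -> dict:
    return {
        "chamber_id": r.chamber_id,
        "area_type": "" if r.area_type is None else AreaType(r.area_type).value,
        "cr_hourly_mmolC_m2_h": r.cr_hourly,
        "ncp_hourly_mmolC_m2_h": r.ncp_hourly,
        "gpp_hourly_mmolC_m2_h": r.gpp_hourly,
        "gpp_daily_mmolC_m2_d": r.gpp_daily,
        "cr_daily_mmolC_m2_d": r.cr_daily,
        "ncp_daily_mmolC_m2_d": r.ncp_daily,
        "trophic_status": r.trophic_status.value,
    }


def write_results(
    results: Sequence[Union[FluxResult, MetabolismResult]],
    path,
    kind: Optional[str] = None,
) -> Path:
    """Tidy one-row-per-result CSV; units are embedded in column names.

    ``kind`` ("flux" or "metabolism") disambiguates the header for an
    empty result list; otherwise it is inferred and mixing the two
    result types is rejected.
    """
    path = Path(path)
    kinds = {type(r) for r in results}
    if len(kinds) > 1:
        raise ValidationError("cannot mix flux and metabolism results in one file")
    if results:
        inferred = "flux" if isinstance(results[0], FluxResult) else "metabolism"
        if kind is not None and kind != inferred:
            raise ValidationError(f"kind={kind!r} does not match results ({inferred})")
        kind = inferred
    kind = kind or "flux"
    if kind == "flux":
        df = pd.DataFrame([_flux_row(r) for r in results], columns=FLUX_COLUMNS)
    elif kind == "metabolism":
        df = pd.DataFrame(
            [_metabolism_row(r) for r in results], columns=METABOLISM_COLUMNS
        )
    else:
        raise ValidationError(f"unknown result kind {kind!r}")
    df.to_csv(path, index=False)
    return path


def _opt(value) -> Optional[float]:
    if value is None:
        return None
    f = float(value)
    return None if np.isnan(f) else f


def read_flux_results(path) -> list[FluxResult]:
    df = pd.read_csv(path)
    _require_columns(df, FLUX_COLUMNS, path)
    out = []
    for _, row in df.iterrows():
        out.append(
            FluxResult(
                gas=Gas(row["gas"]),
                slope_ppmv_h=_opt(row["slope_ppmv_h"]),
                r_squared=_opt(row["r2"]),
                n_points=int(row["n"]),
                mean_temperature_k=_opt(row["T_K"]),
                flux_umol_m2_h=_opt(row["flux_umol_m2_h"]),
                flux_ug_m2_h=_opt(row["flux_ug_m2_h"]),
                status=FluxStatus(row["status"]),
                chamber_id=str(row["chamber_id"]),
                interval=str(row["interval"]),
            )
        )
    return out


def read_metabolism_results(path) -> list[MetabolismResult]:
    df = pd.read_csv(path)
    _require_columns(df, METABOLISM_COLUMNS, path)
    out = []
    for _, row in df.iterrows():
        area = str(row["area_type"]) if not pd.isna(row["area_type"]) else ""
        out.append(
            MetabolismResult(
                cr_hourly=float(row["cr_hourly_mmolC_m2_h"]),
                ncp_hourly=float(row["ncp_hourly_mmolC_m2_h"]),
                gpp_hourly=float(row["gpp_hourly_mmolC_m2_h"]),
                gpp_daily=float(row["gpp_daily_mmolC_m2_d"]),
                cr_daily=float(row["cr_daily_mmolC_m2_d"]),
                ncp_daily=float(row["ncp_daily_mmolC_m2_d"]),
                trophic_status=TrophicStatus(row["trophic_status"]),
                chamber_id=str(row["chamber_id"]),
                area_type=AreaType(area) if area else None,
            )
        )
    return out
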