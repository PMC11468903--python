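# benthicflux

Analysis pipeline for closed benthic-chamber greenhouse-gas measurements
over coastal sediments:

- **chamber_flux** — fits a linear slope to headspace CO₂/CH₄
  concentrations (ppmv vs. hours) and converts it to an areal flux via
  the ideal gas law: `F = slope × P·V/(R·T) / A` in µmol m⁻² h⁻¹
  (CH₄ additionally in µg m⁻² h⁻¹). Non-detect samples are flagged,
  never zero-imputed.
- **metabolism** — hourly community respiration (dark interval), net
  community production (light interval) and gross primary production
  (GPP = CR + NCP) from dissolved-oxygen series; daily rates via
  photoperiod scaling (GPP×photoperiod, CR×24, NCP = GPP − CR with CR
  carried negative) and trophic-status classification.
- **group_stats** — Shapiro–Wilk normality check with optional log
  transform, classical one-way ANOVA, and Tukey-HSD post-hoc pairwise
  comparisons.
- **budget** — upscales areal fluxes to patch totals (grams over a
  duration) and expresses CH₄ in CO₂-equivalents using a sustained-flux
  warming multiplier (default 45, conventional range 45–96).
- **synthetic** — forward simulator (gas accumulation, diel DO,
  CH₄ detection limits) with known ground truth, used throughout the
  test suite in place of field data.
- **io / cli** — long-format CSV dialect for deployments, a two-column
  temperature log, tidy result writers, and a `benthicflux` command.

## CLI

```sh
# generate a synthetic study (deployments.csv, temperature.csv, truth.csv)
benthicflux simulate --out-dir study/ --seed 7

# areal fluxes, per chamber and gas
benthicflux flux --input study/deployments.csv \
    --temperature study/temperature.csv --out fluxes.csv

# hourly + daily CR/NCP/GPP and trophic status
benthicflux metabolism --input study/deployments.csv --out metabolism.csv

# one-way ANOVA + Tukey HSD on any results column
benthicflux stats --input fluxes.csv --value-col flux_umol_m2_h \
    --group-col chamber_id --out stats.csv

# patch-level totals and CH4 CO2-equivalents
benthicflux budget --input study/deployments.csv \
    --temperature study/temperature.csv --duration 24 --out budget.csv
```

All commands exit 0 on success and 1 with a named error class
(`SchemaError`, `ValidationError`, …) on failure. Physical constants
(gas constant, pressure, molar masses, PQ/RQ, SGWP) can be overridden
with `--config constants.yaml`.

## Data dialects

`deployments.csv` — one row per sample, chamber metadata repeated:
`chamber_id, area_type (vegetated|bare), species_label, patch_area_ha,
area_m2, headspace_volume_L, chamber_length_cm, insertion_depth_cm,
photoperiod_h, sample_label, time_h, gas, conc_ppmv, do_mg_per_L
[, water_volume_L]`. Times are decimal hours since chamber closure.
A CH₄ non-detect is the literal token `ND` in `conc_ppmv`. The optional
`water_volume_L` column supplies the water-phase volume used by the
metabolism equations (distinct from the gas headspace volume).

`temperature.csv` — `timestamp` (ISO-8601), `temp_C`.

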