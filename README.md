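# heattract

Hourly heat-stress exposure fields — Heat Index (HI), Wet-Bulb Globe
Temperature (WBGT) and Universal Thermal Climate Index (UTCI) — on a fine
(~800 m) reference grid, aggregated to census-tract boundaries with area
and population weights.

## Who this is for

Heat–health researchers need exposure metrics that go beyond dry-bulb
temperature (humidity, solar radiation and wind all shape physiological heat
strain) and that are aligned with the administrative geographies that health
records use.  `heattract` implements the full modeling chain from raw
gridded climate products to tract-hour exposure tables, plus a synthetic
input generator so the entire chain runs and validates on a desktop with no
data downloads.

## The model

**Temporal disaggregation.** A fine-resolution daily product supplies each
cell's daily extrema (Tmin, Tmax) and daily mean dew point; a coarse hourly
reanalysis supplies the shape of the diurnal cycle.  For each cell and
24-hour UTC window (12:00 UTC of the previous day through 11:00 UTC of the
labeled day),

    f(h)  = (T_src(h) − min T_src) / (max T_src − min T_src)        ∈ [0, 1]
    Ta(h) = Ta_min + f(h) · (Ta_max − Ta_min)
    Td(h) = Td_src(h) + (Td_mean − mean_h Td_src)
    e(h)  = min( es(Td(h)), es(Ta(h)) )          (Buck es, saturation cap)

so reconstructed hourly temperature conserves the daily extrema exactly and
the corrected dew point conserves the daily mean exactly.

**Regridding.** Surface pressure, wind components, longwave fluxes (derived
from accumulated radiances by hourly differencing / 3600 s) and the solar
product (half-hourly GHI/DNI/DHI/zenith/albedo, aggregated to hourly with
cosine-space zenith averaging) move onto the reference grid by four-neighbor
inverse-distance weighting with hard distance cutoffs (9 km for the
reanalysis, 4 km for the solar grid).

**Indices.**
* HI: the National Weather Service algorithm (simple averaged formula below
  80 °F, Rothfusz regression with low/high-humidity adjustments above).
* WBGT = 0.7·Tw + 0.2·Tg + 0.1·Ta, with the natural wet-bulb Tw and globe
  Tg solved from the Liljegren energy balances (convective, radiative and
  evaporative exchange on the wick and globe sensors) by damped fixed-point
  iteration; 10 m wind is moved to the 2 m sensor height by a
  stability-class power law.
* Tmrt: fourth-root radiant flux balance for a standing person (half view
  factors sky/ground, shortwave absorptivity 0.7, emissivity 0.97,
  elevation-dependent projected-area fraction), feeding the sixth-order
  UTCI polynomial with its published validity limits
  (−50 ≤ Ta ≤ 50 °C, −30 ≤ Tmrt−Ta ≤ 70 °C, RH > 5 %, e < 50 hPa,
  0.5 ≤ U10 ≤ 17 m/s).

**Aggregation.** Cell centroids are assigned to tract polygons (centroid
rule); tract-hour means use cosine-latitude area weights or resampled
population counts.  One Parquet file per labeled day carries the 15-column
schema (`GEOID, year, month, day, time, temp_C_used_area, …, UTCI_C_pop`).

## Worked example

```sh
$ heattract fixtures --seed 3 --out fx
wrote fixtures for 5 days, 400 cells to fx

$ heattract run --input-dir fx --output-dir out
wrote 5 tract files (12 tracts) to out

$ heattract validate --cell-hourly out/cell_hourly.parquet --input-dir fx
...
pooled: n=1800 bias=-0.028 rmse=1.001 r=0.974
```

The fixture stations observe the synthetic truth field with unit-variance
Gaussian noise, so a pooled RMSE of ≈1.0 °C and near-zero bias mean the
reconstruction reproduces the truth at the stations to well within the
observation noise; r is the pooled Pearson correlation over all 1800
matched station-hours.  `out/` contains one file per day, e.g.
`heatstress_tract_area_and_popweighted_2010-07-14_2010-07-15_popy2010_v2010.parquet`
(the two dates are the half UTC days the window spans; `popy`/`v` are the
population-surface year and the decennial boundary vintage), and
`manifest.json` recording the configuration and constants used.

Library use mirrors the CLI:

```python
>>> import numpy as np
>>> from heattract import heat_index, utci, saturation_vapor_pressure
>>> round(float(heat_index(32.0, 70.0)), 2)  # degC
40.41
>>> e = 0.5 * saturation_vapor_pressure(25.0)
>>> utci(np.array([25.]), np.array([1.]), np.array([25.]), np.array([e]))
array([24.61072316])
```

## Layout

```
src/heattract/
  timegrid.py        reference grid, 24 h UTC windows, nearest-source links
  reconstruction.py  diurnal rescaling, Buck es, dew-point correction
  regrid.py          accumulation→flux, half-hour aggregation, cutoff IDW
  ancillary.py       RH, wind speed, hypsometric pressure adjustment (opt-in)
  heat_indices.py    HI, Liljegren WBGT, Tmrt, UTCI (+ validity masking)
  tract_aggregate.py centroid lookup, population resampling, output schema
  validation.py      station matching, bias/RMSE/r, station-hour pooling
  synthetic.py       seeded generators for every input product
  pipeline.py        orchestration, fixtures I/O, run manifest
  cli.py             heattract fixtures | run | aggregate | validate
```

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
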