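# Methods

This note documents the models implemented in `heattract`, the parameter
choices that matter, what the synthetic input generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Temporal frame

All processing is organised in 24-hour UTC windows owned by a labeled
calendar day: the window runs from 12:00 UTC of the previous day to 11:00
UTC of the labeled day.  This keeps the daily constraints (which are defined
over exactly that span in the daily source product) and the hourly values
they constrain referring to the same physical day, and consecutive windows
tile time with no gap or overlap.  No local-time conversion happens anywhere
in the pipeline.

## Reconstruction

Hourly air temperature on the fine grid is the daily-extrema-constrained
rescaling of the nearest coarse cell's normalized diurnal profile
`f(h) = (T(h) − Tmin)/(Tmax − Tmin)`.  Two conservation laws hold by
construction and are enforced by tests: the reconstructed series attains
exactly the daily Tmin/Tmax whenever the source profile attains 0 and 1
(which a normalized profile always does), and the additively corrected
hourly dew point has a daily mean exactly equal to the daily mean
constraint.

*Flat source day* (`Tmax == Tmin`): `f ≡ 0.5`, i.e. the midpoint of the
constraint range — bounded, symmetric, and avoids a 0/0.  This path is
exercised by the zero-amplitude scenario.

*Saturation handling*: vapor pressure is capped at `es(Ta)` in vapor-pressure
space; the dew point series itself is not truncated.  Relative humidity is
computed after this cap, so its [0, 100] clip only absorbs round-off.

*Saturation vapor pressure*: the Arden Buck over-water fit
`es(T) = 6.1121·exp((18.678 − T/234.5)·T/(257.14 + T))` hPa.  The variant
identifier is written into every run manifest; swapping the fit means
changing one coefficient block in `constants.py`.  The warm-season focus of
heat-stress work makes an over-ice branch unnecessary.

## Regridding

Accumulated longwave radiances (J/m²) become hourly mean fluxes by
differencing successive accumulations and dividing by 3600 s.  The
accumulation day restarts at its source-defined boundary: the step labeled
01:00 UTC is the first of the day and its flux is `acc/3600` directly.
Negative differences are clipped to zero (with a logged warning) *only* for
physically nonnegative accumulations such as downwelling radiation, where
they can only be unexpected resets; net radiation is signed and is never
clipped.

Half-hourly solar series aggregate to hourly by averaging the two
half-hours; a single missing half-hour degrades to the valid sample.  Zenith
angle averages in cosine space (`arccos(mean cos θ)`), which preserves the
quantity that actually scales direct-beam projection.  Albedo is an 8-day
product and is constant within any hour by construction.

Spatial interpolation is four-neighbor inverse-distance weighting on
planar coordinates with hard cutoffs (9 km for the coarse reanalysis grid,
4 km for the solar grid) and weight exponent 2.  The exponent is
configurable and recorded in the run manifest; distance weighting with an
explicit cutoff degrades gracefully to nearest-neighbor when only one valid
source remains, and a target with no valid source within the cutoff becomes
missing rather than raising.  A target coincident with a source receives
that source's value exactly.  Planar distances are computed in a spherical
Albers equal-area conic whose standard parallels follow the 1/6 rule over
the domain's latitude span; any metric projection would serve, and the
projection is configurable.

## Ancillary variables

Relative humidity is `100·e/es(Ta)`; wind speed is the vector magnitude of
the interpolated 10 m components.  An optional hypsometric adjustment moves
interpolated surface pressure from the source-product elevation to the
reference-cell elevation through the window's mean temperature:

    P_target = P_ref · exp( g·(z_source − z_target) / (Rd·T_K) )

with g = 9.80665 m s⁻², Rd = 287.05 J kg⁻¹ K⁻¹ — a target *below* the
source receives *higher* pressure, and the transform is its own inverse
under swapped elevations.  The adjustment ships off by default: it makes no
meaningful difference to the heat-stress outputs at these elevation
contrasts, so interpolated pressure is used directly unless the
`adjust_pressure_to_elevation` flag is set.

## Heat-stress indices

**Heat Index.**  The full National Weather Service algorithm, computed in
Fahrenheit internally: the simple averaged formula everywhere, replaced by
the Rothfusz regression when it reaches 80 °F, with the low-humidity
(RH < 13 %, 80–112 °F) and high-humidity (RH > 85 %, 80–87 °F) adjustment
terms.  No output masking is applied — every cell-hour gets a value.

**Liljegren WBGT.**  Natural wet-bulb and globe temperatures solve the
published instrument energy balances.  Constants (globe 50.8 mm diameter,
emissivity 0.95, albedo 0.05; wick 7 mm × 25.4 mm, emissivity 0.95, albedo
0.4; surface emissivity 0.999, albedo 0.45; the model's own moist-air
saturation curve) are pinned in one table in `constants.py`.  Both balances
iterate as damped fixed points (damping 0.1) to a 0.02 K tolerance with a
50-iteration cap; non-convergence yields a missing value.  10 m wind is
converted to the 2 m sensor height by a rural stability-class power law:
daytime classes come from the published solar-flux/wind-speed table;
nighttime classes — which formally need a vertical temperature gradient the
pipeline does not carry — are assigned from wind speed alone (class 6 below
2 m/s, 5 to 2.5 m/s, else 4), assuming the typical nocturnal surface
inversion.  Wind is floored at the 0.13 m/s anemometer stall speed.  The
sun is treated as below the horizon when cos θz < cos 89.5°, which zeroes
the solar load and keeps the 1/cos θz direct-beam geometry bounded; the
pipeline encodes nighttime as a small negative sentinel (−10⁻⁴,
configurable).

**Mean radiant temperature.**  Fourth-root flux balance for a standing
person: half view factors to sky (downwelling longwave, diffuse shortwave)
and ground (upwelling longwave recovered as `Ldown − Lnet`, reflected
shortwave `GHI − (1−α)GHI`), shortwave absorptivity 0.7, longwave
emissivity 0.97, and direct beam weighted by the projected-area fraction
`fp(γ) = 0.308·cos(γ(0.998 − γ²/50000))` of solar elevation γ.  cos θz is
truncated at zero and negative shortwave fluxes are zeroed.  With all
shortwave zero and zero net longwave the balance reduces exactly to
`Tmrt = (Ldown/σ)^¼`.

**UTCI.**  The sixth-order polynomial approximation in (Ta, U10,
Tmrt − Ta, e[kPa]); the 210-term coefficient table lives in
`_utci_coeffs.py`.  Values are missing exactly where the published validity
domain fails: Ta outside [−50, 50] °C, Tmrt − Ta outside [−30, 70] °C,
RH ≤ 5 % (evaluated on the clipped RH), e ≥ 50 hPa, wind outside
[0.5, 17] m/s, or any non-finite input.  The implementation reproduces the
operational check value UTCI(Ta 25 °C, Tmrt 25 °C, va 1 m/s, RH 50 %) =
24.6 °C.

## Tract aggregation

Each cell centroid is assigned to the tract polygon covering it; boundary
ties go to the first tract in sorted GEOID order.  A tract containing no
centroid adopts its single nearest cell so that every tract receives values
(empty exposure rows would break downstream health linkage).  Area weights
are cos(latitude) — the relative cell area on the sphere; population
weights are raw counts resampled (conservatively summed) from a finer
population lattice, without an additional area factor.  A tract-hour whose
population weights sum to zero falls back to area weights.  Missing member
values are excluded with weights renormalized.  Boundary vintages follow
the decennial rule (2000 boundaries for 1998–2009 data, 2010 for
2010–2019, 2020 onward) and the population surface year is floored at 2000.
Output files carry exactly the 15-column published schema, one Parquet file
per labeled day, named
`heatstress_tract_area_and_popweighted_[D−1]_[D]_popy[Y]_v[V].parquet`.

## Validation protocol

Stations are matched to the nearest grid cell within a threshold sized to
the product resolution (800 m for the fine grid, 9 km for a coarse
comparison).  Errors are summarized as bias (model − obs; a warm model is
positive), RMSE and Pearson r over matched pairs, per window; window
summaries pool with matched-station-hour weights (bias and MSE combine
linearly; pooled RMSE is the root of pooled MSE), which reproduces the
concatenated-pair metrics exactly.  Fewer than two valid pairs leave the
correlation undefined.

## Synthetic scenario

The default scenario is desk-scale: a 20×20 fine grid at ~800 m spacing, a
3×3 coarse grid (~9 km), a 6×6 solar grid (~3 km), five labeled days, 12
tessellating rectangular tracts, and 15 stations with 1.0 °C Gaussian
observation noise; the full pipeline completes in a few seconds on one
core.  The truth field is smooth spatial gradients plus a sinusoidal
diurnal cycle (amplitude 6 °C around a 26 °C warm-season mean, dew point
8 °C below the daily mean temperature) with seeded day-to-day and per-cell
perturbations; solar geometry uses a declination/hour-angle model, and
longwave accumulations restart daily to exercise the reset handling.  All
generators are bit-reproducible under the scenario seed.

What the generator deliberately does **not** emulate: fronts and advection,
cloud fields decoupled from the clear-sky shape, terrain channeling of
wind, heteroscedastic or instrument-specific station error, and coastline
or land-mask irregularity.  Passing tests therefore demonstrate the
correctness of the *machinery* — conservation laws, oracle equivalence of
the index models, masking, weighting, schema — not the real-world skill of
the reconstruction, which can only be established against real station
networks.

## Known limitations

* The reconstruction borrows intraday timing from the coarse product; where
  the true fine-scale diurnal phase differs (valley inversions, sea
  breezes), conserved daily extrema do not correct the timing error.
* The IDW scheme has no elevation or land-surface predictors; it smooths
  gradients sharper than the source grid spacing.
* The Liljegren nighttime stability assignment assumes a surface inversion;
  windy overcast nights are treated as more stable than they are, slightly
  lowering the 2 m wind estimate.
* UTCI beyond its polynomial validity domain is reported missing rather
  than extrapolated.
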