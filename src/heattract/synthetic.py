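"""Synthetic input products for the full pipeline.

Generates, from one seeded scenario, every input the pipeline consumes: an
hourly truth field on the fine grid, the degraded products derived from it
(daily constraints, coarse hourly reanalysis with accumulated longwave,
half-hourly solar), tract polygons, a fine population surface, and noisy
station observations.  The truth field is smooth spatial gradients plus a
sinusoidal diurnal cycle with an analytic solar-geometry model; it makes no
claim of meteorological realism beyond exercising every code path
(flat days, accumulation resets, nighttime, saturation capping).

All generators are deterministic under the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date, timedelta

import numpy as np
import pandas as pd
from shapely.geometry import box

from .constants import STEFAN_BOLTZMANN, ZERO_C_IN_K
from .timegrid import PrismDayWindow, ReferenceGrid, window_range

SOLAR_CONSTANT = 1361.0  # W/m2


@dataclass
class TruthScenario:
    """Desk-scale study conditions for the synthetic domain.

    Defaults: a 20x20 fine grid (~800 m spacing), a 3x3 coarse grid (~9 km),
    a 6x6 solar grid (~3 km), five constraint days, 12 tracts and 15
    stations — the full pipeline runs in well under a minute.
    """

    seed: int = 0
    nx: int = 20
    ny: int = 20
    coarse_nx: int = 3
    coarse_ny: int = 3
    solar_nx: int = 6
    solar_ny: int = 6
    n_days: int = 5
    start_date: date = field(default_factory=lambda: date(2010, 7, 15))
    center_lat: float = 38.0
    center_lon: float = -97.0
    fine_spacing_deg: float = 0.00833  # ~800 m at mid-latitudes (N-S)
    mean_temp: float = 26.0           # degC, warm-season domain mean
    diurnal_amplitude: float = 6.0    # degC, half peak-to-trough swing
    dewpoint_offset: float = 8.0      # degC below the daily mean temperature
    wind_scale: float = 3.0           # m/s
    cloudiness: float = 0.2           # 0..1 attenuation of clear-sky solar
    n_tracts_x: int = 4
    n_tracts_y: int = 3
    n_stations: int = 15
    station_noise_sd: float = 1.0     # degC
    total_population: int = 120_000
    pop_subdivision: int = 4          # fine population lattice per cell axis

    def as_dict(self) -> dict:
        d = asdict(self)
        d["start_date"] = self.start_date.isoformat()
        return d


@dataclass
class TruthFields:
    scenario: TruthScenario
    grid: ReferenceGrid
    hours: pd.DatetimeIndex      # 24 * n_days hourly UTC stamps
    windows: list[PrismDayWindow]
    ta: np.ndarray               # (n_cells, n_hours) degC
    td: np.ndarray               # (n_cells, n_hours) degC


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------

def _rect_grid(nx, ny, center_lat, center_lon, spacing, id_offset=0) -> ReferenceGrid:
    jj, ii = np.meshgrid(np.arange(nx), np.arange(ny))
    lat = center_lat + (ii.ravel() - (ny - 1) / 2.0) * spacing
    lon = center_lon + (jj.ravel() - (nx - 1) / 2.0) * spacing
    rng = np.random.default_rng(12345)  # elevation texture is scenario-independent
    elev = (
        250.0
        + 120.0 * np.sin(2 * np.pi * (lon - lon.min()) / max(np.ptp(lon), 1e-9))
        + 60.0 * np.cos(2 * np.pi * (lat - lat.min()) / max(np.ptp(lat), 1e-9))
    )
    del rng
    cells = pd.DataFrame(
        {
            "cell_id": id_offset + np.arange(nx * ny),
            "lat": lat,
            "lon": lon,
            "elevation": elev,
        }
    )
    return ReferenceGrid(cells)


def fine_grid(sc: TruthScenario) -> ReferenceGrid:
    return _rect_grid(sc.nx, sc.ny, sc.center_lat, sc.center_lon, sc.fine_spacing_deg)


def coarse_grid(sc: TruthScenario) -> ReferenceGrid:
    spacing = sc.fine_spacing_deg * sc.nx / sc.coarse_nx
    return _rect_grid(sc.coarse_nx, sc.coarse_ny, sc.center_lat, sc.center_lon, spacing, id_offset=10_000)


def solar_grid(sc: TruthScenario) -> ReferenceGrid:
    spacing = sc.fine_spacing_deg * sc.nx / sc.solar_nx
    return _rect_grid(sc.solar_nx, sc.solar_ny, sc.center_lat, sc.center_lon, spacing, id_offset=20_000)


# ---------------------------------------------------------------------------
# solar geometry (simple analytic model)
# ---------------------------------------------------------------------------

def solar_cos_zenith(lat_deg, lon_deg, timestamps: pd.DatetimeIndex):
    """cos(zenith) for each (point, timestamp) from declination + hour angle."""
    lat = np.radians(np.asarray(lat_deg, dtype=float))[:, None]
    lon = np.asarray(lon_deg, dtype=float)[:, None]
    doy = timestamps.dayofyear.to_numpy()[None, :]
    frac_hour = (timestamps.hour + timestamps.minute / 60.0).to_numpy()[None, :]
    decl = np.radians(23.45) * np.sin(2 * np.pi * (284 + doy) / 365.0)
    solar_time = frac_hour + lon / 15.0
    hour_angle = np.radians(15.0 * (solar_time - 12.0))
    return np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(hour_angle)


# ---------------------------------------------------------------------------
# truth fields
# ---------------------------------------------------------------------------

def make_truth_fields(sc: TruthScenario) -> TruthFields:
    """Hourly truth air and dew-point temperature on the fine grid."""
    grid = fine_grid(sc)
    windows = window_range(sc.start_date, sc.start_date + timedelta(days=sc.n_days - 1))
    hours = windows[0].hours.append([w.hours for w in windows[1:]])
    rng = np.random.default_rng(sc.seed)

    lat, lon = grid.lat[:, None], grid.lon[:, None]
    lat_span = max(np.ptp(grid.lat), 1e-9)
    lon_span = max(np.ptp(grid.lon), 1e-9)
    spatial = (
        2.0 * (lat - grid.lat.min()) / lat_span
        + 1.0 * (lon - grid.lon.min()) / lon_span
        - 0.5 * (grid.elevation[:, None] - grid.elevation.mean()) / 100.0
    )

    day_index = np.repeat(np.arange(sc.n_days), 24)[None, :]
    day_offset = rng.normal(0.0, 1.5, size=sc.n_days)[day_index[0]][None, :]

    frac_hour = (hours.hour + hours.minute / 60.0).to_numpy()[None, :]
    local_hour = frac_hour + lon / 15.0
    diurnal = -np.cos(2 * np.pi * (local_hour - 2.0) / 24.0)  # peak ~14:00 local

    # smooth per-cell noise: small seeded perturbation varying by cell & day
    cell_noise = rng.normal(0.0, 0.3, size=(len(grid), sc.n_days))[:, day_index[0]]

    ta = sc.mean_temp + spatial + day_offset + sc.diurnal_amplitude * diurnal + cell_noise

    td_diurnal = 0.8 * np.sin(2 * np.pi * (local_hour - 6.0) / 24.0)
    td_noise = rng.normal(0.0, 0.2, size=(len(grid), sc.n_days))[:, day_index[0]]
    td = (
        sc.mean_temp + spatial + day_offset
        - sc.dewpoint_offset + td_diurnal + td_noise
    )
    return TruthFields(scenario=sc, grid=grid, hours=hours, windows=windows, ta=ta, td=td)


# ---------------------------------------------------------------------------
# degraded products
# ---------------------------------------------------------------------------

def degrade_to_daily(truth: TruthFields) -> pd.DataFrame:
    """Per-cell, per-window Ta min/max and mean Td over each 24 h window."""
    n_hours = len(truth.hours)
    if n_hours % 24 != 0:
        raise ValueError("truth does not cover whole constraint-day windows")
    rows = []
    for wi, window in enumerate(truth.windows):
        sl = slice(24 * wi, 24 * (wi + 1))
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": truth.grid.cell_ids,
                    "label_date": window.label_date.isoformat(),
                    "ta_min": truth.ta[:, sl].min(axis=1),
                    "ta_max": truth.ta[:, sl].max(axis=1),
                    "td_mean": truth.td[:, sl].mean(axis=1),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _block_average(truth_values, fine: ReferenceGrid, coarse: ReferenceGrid):
    """Average fine-cell values into their nearest coarse cell."""
    from .timegrid import nearest_source_map

    mapping = nearest_source_map(fine, coarse)
    codes = pd.Series(
        pd.Categorical(mapping["source_cell_id"], categories=coarse.cell_ids).codes
    ).to_numpy()
    out = np.zeros((len(coarse), truth_values.shape[1]))
    cnt = np.zeros(len(coarse))
    np.add.at(out, codes, truth_values)
    np.add.at(cnt, codes, 1.0)
    return out / np.maximum(cnt, 1.0)[:, None]


def degrade_to_coarse_hourly(truth: TruthFields) -> dict:
    """Coarse hourly reanalysis-like product derived from the truth.

    Returns a dict with the coarse grid, hourly timestamps, per-variable
    arrays (n_coarse, n_hours) for ta, td, ps, u10, v10, and *accumulated*
    longwave (ldown_acc, lnet_acc, J/m2) on timestamps shifted to include
    one leading hour so the first window hour's flux is recoverable.  The
    accumulations restart at each accumulation day (first step labeled at
    01:00 UTC), exercising the reset handling downstream.
    """
    sc = truth.scenario
    cg = coarse_grid(sc)
    rng = np.random.default_rng(sc.seed + 1)

    ta_c = _block_average(truth.ta, truth.grid, cg)
    td_c = _block_average(truth.td, truth.grid, cg)

    n_hours = len(truth.hours)
    ps = 101325.0 * np.exp(-cg.elevation / 8434.0)
    ps = ps[:, None] + rng.normal(0.0, 40.0, size=(len(cg), n_hours))

    phase = rng.uniform(0, 2 * np.pi, size=len(cg))[:, None]
    hour_frac = np.arange(n_hours)[None, :] * 2 * np.pi / 24.0
    u10 = sc.wind_scale * (0.6 + 0.4 * np.sin(hour_frac + phase))
    v10 = sc.wind_scale * 0.5 * np.cos(hour_frac + 0.5 * phase)

    # longwave fluxes for the hour ending at each "extended" timestamp
    ext_hours = pd.DatetimeIndex([truth.hours[0] - pd.Timedelta(hours=1)]).append(truth.hours)
    ta_ext = np.concatenate([ta_c[:, :1], ta_c], axis=1)
    emis = 0.70 + 0.18 * sc.cloudiness
    ldown_flux = emis * STEFAN_BOLTZMANN * (ta_ext + ZERO_C_IN_K) ** 4
    lup_flux = 0.98 * STEFAN_BOLTZMANN * (ta_ext + ZERO_C_IN_K) ** 4
    lnet_flux = ldown_flux - lup_flux

    def accumulate(flux):
        # acc at timestamp t = sum of hourly fluxes (x3600 J) since the
        # accumulation-day start; the hour ending at 01:00 opens the day and
        # the 00:00 stamp carries the full previous-day total.
        acc_day = (ext_hours - pd.Timedelta(hours=1)).normalize()
        acc = np.empty_like(flux)
        for day in pd.unique(acc_day):
            cols = np.where(acc_day == day)[0]
            acc[:, cols] = np.cumsum(flux[:, cols] * 3600.0, axis=1)
        return acc

    return {
        "grid": cg,
        "hours": truth.hours,
        "ext_hours": ext_hours,
        "ta": ta_c,
        "td": td_c,
        "ps": ps,
        "u10": u10,
        "v10": v10,
        "ldown_acc": accumulate(ldown_flux),
        "lnet_acc": accumulate(lnet_flux),
        "ldown_flux": ldown_flux,
        "lnet_flux": lnet_flux,
    }


def make_halfhourly_solar(sc: TruthScenario) -> dict:
    """Half-hourly clear-sky-shaped solar product on the solar grid."""
    sg = solar_grid(sc)
    windows = window_range(sc.start_date, sc.start_date + timedelta(days=sc.n_days - 1))
    first = windows[0].hours[0]
    stamps = pd.date_range(first, periods=24 * sc.n_days * 2, freq="30min", tz="UTC")

    cosz = solar_cos_zenith(sg.lat, sg.lon, stamps)
    up = np.clip(cosz, 0.0, None)
    transmittance = 0.75 * (1.0 - 0.5 * sc.cloudiness)
    ghi = SOLAR_CONSTANT * up * transmittance
    diffuse_frac = np.clip(0.15 + 0.6 * sc.cloudiness, 0.0, 1.0)
    dhi = ghi * diffuse_frac
    with np.errstate(invalid="ignore", divide="ignore"):
        dni = np.where(up > 0.05, (ghi - dhi) / np.maximum(up, 0.05), 0.0)
    zenith = np.degrees(np.arccos(np.clip(cosz, -1.0, 1.0)))

    # 8-day albedo blocks, constant within each block
    block = ((stamps.normalize() - stamps.normalize()[0]).days // 8).to_numpy()
    albedo = 0.20 + 0.02 * (block % 3 - 1)
    albedo = np.broadcast_to(albedo[None, :], ghi.shape).copy()

    return {
        "grid": sg,
        "stamps": stamps,
        "ghi": ghi,
        "dni": dni,
        "dhi": dhi,
        "zenith": zenith,
        "albedo": albedo,
    }


# ---------------------------------------------------------------------------
# tracts, population, stations
# ---------------------------------------------------------------------------

def make_tracts_and_population(sc: TruthScenario):
    """Tessellating rectangular tracts + a log-normal clumped population
    lattice finer than the reference grid.

    Returns (tracts: {geoid: polygon}, pop: DataFrame[lat, lon, count]).
    """
    grid = fine_grid(sc)
    half = sc.fine_spacing_deg / 2.0
    lon0, lon1 = grid.lon.min() - half, grid.lon.max() + half
    lat0, lat1 = grid.lat.min() - half, grid.lat.max() + half

    tracts: dict[str, object] = {}
    dx = (lon1 - lon0) / sc.n_tracts_x
    dy = (lat1 - lat0) / sc.n_tracts_y
    k = 0
    for iy in range(sc.n_tracts_y):
        for ix in range(sc.n_tracts_x):
            geoid = f"36081{k:06d}"
            tracts[geoid] = box(lon0 + ix * dx, lat0 + iy * dy, lon0 + (ix + 1) * dx, lat0 + (iy + 1) * dy)
            k += 1

    rng = np.random.default_rng(sc.seed + 2)
    sub = sc.pop_subdivision
    step = sc.fine_spacing_deg / sub
    plon = np.arange(lon0 + step / 2.0, lon1, step)
    plat = np.arange(lat0 + step / 2.0, lat1, step)
    pj, pi = np.meshgrid(plon, plat)
    pj, pi = pj.ravel(), pi.ravel()
    centers = np.column_stack(
        [rng.uniform(lon0, lon1, size=5), rng.uniform(lat0, lat1, size=5)]
    )
    sigma = 0.15 * (lon1 - lon0)
    density = np.zeros(len(pj))
    for cx, cy in centers:
        density += np.exp(-((pj - cx) ** 2 + (pi - cy) ** 2) / (2 * sigma**2))
    density *= rng.lognormal(mean=0.0, sigma=0.8, size=len(pj))
    counts = density / density.sum() * sc.total_population
    pop = pd.DataFrame({"lat": pi, "lon": pj, "count": counts})
    return tracts, pop


def make_stations(truth: TruthFields, n: int | None = None, noise_sd: float | None = None, seed: int | None = None):
    """Random in-domain stations observing truth Ta plus Gaussian noise.

    Returns (stations: DataFrame[station_id, lat, lon],
             obs: DataFrame[station_id, timestamp, ta]).
    """
    sc = truth.scenario
    n = sc.n_stations if n is None else n
    noise_sd = sc.station_noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(sc.seed + 3 if seed is None else seed)
    grid = truth.grid
    half = sc.fine_spacing_deg / 2.0
    lat = rng.uniform(grid.lat.min() - half * 0.9, grid.lat.max() + half * 0.9, size=n)
    lon = rng.uniform(grid.lon.min() - half * 0.9, grid.lon.max() + half * 0.9, size=n)
    stations = pd.DataFrame(
        {"station_id": [f"ST{k:04d}" for k in range(n)], "lat": lat, "lon": lon}
    )
    # sample truth at the nearest fine cell
    from scipy.spatial import cKDTree

    tree = cKDTree(np.column_stack([grid.lon, grid.lat]))
    _, idx = tree.query(np.column_stack([lon, lat]))
    obs_vals = truth.ta[idx] + rng.normal(0.0, noise_sd, size=(n, len(truth.hours)))
    obs = pd.DataFrame(
        {
            "station_id": np.repeat(stations["station_id"].to_numpy(), len(truth.hours)),
            "timestamp": pd.DatetimeIndex(np.tile(truth.hours.tz_localize(None).to_numpy(), n)).tz_localize("UTC"),
            "ta": obs_vals.ravel(),
        }
    )
    return stations, obs
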