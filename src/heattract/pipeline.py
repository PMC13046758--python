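"""End-to-end orchestration: fixtures -> reconstruction -> regridding ->
indices -> tract aggregation -> validation.

Stages exchange long-format Parquet tables keyed by (cell_id, timestamp);
every timestamp is UTC.  A JSON manifest next to the outputs records the
configuration, the model constants in effect, and per-stage row counts, so
a run is reproducible from its manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import constants as c
from . import synthetic
from .ancillary import adjust_pressure, relative_humidity, wind_speed
from .heat_indices import (
    direct_beam_fraction,
    heat_index,
    mean_radiant_temperature,
    utci,
    wbgt_liljegren,
)
from .reconstruction import diurnal_profile, reconstruct_temperature, reconstruct_vapor_pressure
from .regrid import accumulated_to_flux, aggregate_zenith, halfhour_to_hour, idw_interpolate
from .timegrid import ReferenceGrid, nearest_source_map, window_range
from .tract_aggregate import (
    TractLookup,
    build_lookup,
    population_year,
    read_tracts_geojson,
    resample_population,
    tract_hourly_records,
    vintage_for_year,
    write_tract_parquet,
    write_tracts_geojson,
)
from .validation import ValidationSummary, error_metrics, match_stations, pool_windows

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_dir: str
    output_dir: str
    start_date: str | None = None      # ISO dates; default: all fixture days
    end_date: str | None = None
    idw_power: float = 2.0
    cutoff_coarse_m: float = 9000.0    # reanalysis product cutoff
    cutoff_solar_m: float = 4000.0     # solar product cutoff
    idw_neighbors: int = 4
    adjust_pressure_to_elevation: bool = False
    night_cos_zenith_sentinel: float = c.NIGHT_COS_ZENITH_SENTINEL
    station_match_distance_m: float = 800.0
    seed: int = 0                      # fixtures only; the pipeline is deterministic

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        if self.cutoff_coarse_m <= 0 or self.cutoff_solar_m <= 0:
            raise ValueError("IDW cutoffs must be positive")
        if self.idw_neighbors < 1:
            raise ValueError("idw_neighbors must be >= 1")


# ---------------------------------------------------------------------------
# long/wide helpers
# ---------------------------------------------------------------------------

def wide_to_long(cell_ids, timestamps, variables: dict[str, np.ndarray]) -> pd.DataFrame:
    n_cells, n_times = next(iter(variables.values())).shape
    out = {
        "cell_id": np.repeat(np.asarray(cell_ids), n_times),
        "timestamp": pd.DatetimeIndex(
            np.tile(pd.DatetimeIndex(timestamps).tz_localize(None).to_numpy(), n_cells)
        ).tz_localize("UTC"),
    }
    for name, arr in variables.items():
        out[name] = np.asarray(arr).ravel()
    return pd.DataFrame(out)


def long_to_wide(frame: pd.DataFrame, value: str) -> pd.DataFrame:
    """Pivot a long table to cells x timestamps (sorted both ways)."""
    wide = frame.pivot(index="cell_id", columns="timestamp", values=value)
    return wide.sort_index().sort_index(axis=1)


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------

def write_fixtures(scenario: synthetic.TruthScenario, out_dir) -> dict:
    """Generate and write every pipeline input for a scenario.

    Returns a small manifest of what was written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth = synthetic.make_truth_fields(scenario)
    daily = synthetic.degrade_to_daily(truth)
    coarse = synthetic.degrade_to_coarse_hourly(truth)
    solar = synthetic.make_halfhourly_solar(scenario)
    tracts, pop = synthetic.make_tracts_and_population(scenario)
    stations, obs = synthetic.make_stations(truth)

    truth.grid.to_parquet(out / "grid_fine.parquet")
    coarse["grid"].to_parquet(out / "grid_coarse.parquet")
    solar["grid"].to_parquet(out / "grid_solar.parquet")
    daily.to_parquet(out / "daily_constraints.parquet", index=False)
    wide_to_long(
        coarse["grid"].cell_ids,
        coarse["hours"],
        {k: coarse[k] for k in ("ta", "td", "ps", "u10", "v10")},
    ).to_parquet(out / "coarse_hourly.parquet", index=False)
    wide_to_long(
        coarse["grid"].cell_ids,
        coarse["ext_hours"],
        {"ldown_acc": coarse["ldown_acc"], "lnet_acc": coarse["lnet_acc"]},
    ).to_parquet(out / "coarse_longwave_acc.parquet", index=False)
    wide_to_long(
        solar["grid"].cell_ids,
        solar["stamps"],
        {k: solar[k] for k in ("ghi", "dni", "dhi", "zenith", "albedo")},
    ).to_parquet(out / "solar_halfhourly.parquet", index=False)
    write_tracts_geojson(tracts, out / "tracts.geojson")
    pop.to_parquet(out / "population.parquet", index=False)
    stations.to_parquet(out / "stations.parquet", index=False)
    obs.to_parquet(out / "station_obs.parquet", index=False)
    wide_to_long(
        truth.grid.cell_ids, truth.hours, {"ta": truth.ta, "td": truth.td}
    ).to_parquet(out / "truth_hourly.parquet", index=False)
    with open(out / "scenario.json", "w") as fh:
        json.dump(scenario.as_dict(), fh, indent=2)
    return {"n_days": scenario.n_days, "n_cells": len(truth.grid), "dir": str(out)}


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _read_inputs(input_dir: Path) -> dict:
    req = [
        "grid_fine.parquet", "grid_coarse.parquet", "grid_solar.parquet",
        "daily_constraints.parquet", "coarse_hourly.parquet",
        "coarse_longwave_acc.parquet", "solar_halfhourly.parquet",
        "tracts.geojson", "population.parquet",
    ]
    missing = [n for n in req if not (input_dir / n).exists()]
    if missing:
        raise FileNotFoundError(f"missing pipeline inputs in {input_dir}: {missing}")
    return {
        "fine": ReferenceGrid.read(input_dir / "grid_fine.parquet"),
        "coarse": ReferenceGrid.read(input_dir / "grid_coarse.parquet"),
        "solar": ReferenceGrid.read(input_dir / "grid_solar.parquet"),
        "daily": pd.read_parquet(input_dir / "daily_constraints.parquet"),
        "coarse_hourly": pd.read_parquet(input_dir / "coarse_hourly.parquet"),
        "lw_acc": pd.read_parquet(input_dir / "coarse_longwave_acc.parquet"),
        "solar_hh": pd.read_parquet(input_dir / "solar_halfhourly.parquet"),
        "tracts": read_tracts_geojson(input_dir / "tracts.geojson"),
        "population": pd.read_parquet(input_dir / "population.parquet"),
    }


def _hourly_solar(solar_hh: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Aggregate the half-hourly solar product to hourly (cells x hours)."""
    frames = {v: long_to_wide(solar_hh, v) for v in ("ghi", "dni", "dhi", "zenith", "albedo")}
    stamps = frames["ghi"].columns
    on_hour = stamps[stamps.minute == 0]
    out: dict[str, pd.DataFrame] = {}
    for var, frame in frames.items():
        first = frame[on_hour].to_numpy()
        half = on_hour + pd.Timedelta(minutes=30)
        second = frame.reindex(columns=half).to_numpy()
        if var == "zenith":
            hourly = aggregate_zenith(first, second)
        elif var == "albedo":
            hourly = first  # 8-day product: constant within the hour
        else:
            hourly = halfhour_to_hour(first, second)
        out[var] = pd.DataFrame(hourly, index=frame.index, columns=on_hour)
    return out


def compute_hourly_fields(config: RunConfig, inputs: dict) -> dict:
    """Run reconstruction, regridding, ancillary and index stages.

    Returns per-variable DataFrames (fine cells x hours) plus bookkeeping.
    """
    fine: ReferenceGrid = inputs["fine"]
    coarse: ReferenceGrid = inputs["coarse"]
    solar_grid: ReferenceGrid = inputs["solar"]

    daily = inputs["daily"]
    label_dates = sorted(daily["label_date"].unique())
    if config.start_date:
        label_dates = [d for d in label_dates if d >= config.start_date]
    if config.end_date:
        label_dates = [d for d in label_dates if d <= config.end_date]
    if not label_dates:
        raise ValueError("no constraint days selected")
    windows = window_range(label_dates[0], label_dates[-1])

    # --- align coarse hourly series -------------------------------------
    coarse_wide = {
        v: long_to_wide(inputs["coarse_hourly"], v) for v in ("ta", "td", "ps", "u10", "v10")
    }
    hours = pd.DatetimeIndex([h for w in windows for h in w.hours])
    for v, frame in coarse_wide.items():
        coarse_wide[v] = frame.reindex(columns=hours)

    # accumulated longwave -> hourly flux
    lw = inputs["lw_acc"]
    lw_wide = {v: long_to_wide(lw, v) for v in ("ldown_acc", "lnet_acc")}
    flux = {}
    for v, frame in lw_wide.items():
        converted = accumulated_to_flux(
            frame.columns, frame.to_numpy().T, reset_hour=1,
            clip_negative=(v == "ldown_acc"),
        )
        flux[v.replace("_acc", "")] = pd.DataFrame(
            converted.to_numpy().T, index=frame.index, columns=frame.columns[1:]
        ).reindex(columns=hours)

    # --- spatial interpolation to the fine grid --------------------------
    proj = fine.projection()
    fine_xy = fine.projected_xy(proj)
    coarse_xy = proj.xy(coarse.lat, coarse.lon)
    solar_xy = proj.xy(solar_grid.lat, solar_grid.lon)

    def idw_coarse(frame: pd.DataFrame) -> np.ndarray:
        return idw_interpolate(
            coarse_xy, frame.to_numpy(), fine_xy,
            cutoff=config.cutoff_coarse_m, k=config.idw_neighbors, power=config.idw_power,
        )

    ps = idw_coarse(coarse_wide["ps"])
    u10 = idw_coarse(coarse_wide["u10"])
    v10 = idw_coarse(coarse_wide["v10"])
    ldown = idw_coarse(flux["ldown"])
    lnet = idw_coarse(flux["lnet"])

    solar_hourly = _hourly_solar(inputs["solar_hh"])
    solar_fine = {}
    for var, frame in solar_hourly.items():
        frame = frame.reindex(columns=hours)
        solar_fine[var] = idw_interpolate(
            solar_xy, frame.to_numpy(), fine_xy,
            cutoff=config.cutoff_solar_m, k=config.idw_neighbors, power=config.idw_power,
        )

    # --- reconstruction ---------------------------------------------------
    link = nearest_source_map(fine, coarse, projection=proj)
    src_pos = pd.Index(coarse_wide["ta"].index).get_indexer(link["source_cell_id"])
    fine_order = pd.Index(link["target_cell_id"])

    daily_p = {
        v: daily.pivot(index="cell_id", columns="label_date", values=v).reindex(fine_order)
        for v in ("ta_min", "ta_max", "td_mean")
    }

    n_cells, n_hours = len(fine_order), len(hours)
    ta_recon = np.empty((n_cells, n_hours))
    td_recon = np.empty((n_cells, n_hours))
    e_recon = np.empty((n_cells, n_hours))
    for wi, window in enumerate(windows):
        sl = slice(24 * wi, 24 * (wi + 1))
        label = window.label_date.isoformat()
        ta_src = coarse_wide["ta"].to_numpy()[src_pos][:, sl]
        td_src = coarse_wide["td"].to_numpy()[src_pos][:, sl]
        f = diurnal_profile(ta_src)
        ta_w = reconstruct_temperature(
            f, daily_p["ta_min"][label].to_numpy(), daily_p["ta_max"][label].to_numpy()
        )
        td_w, e_w = reconstruct_vapor_pressure(td_src, daily_p["td_mean"][label].to_numpy(), ta_w)
        ta_recon[:, sl], td_recon[:, sl], e_recon[:, sl] = ta_w, td_w, e_w

    # --- ancillary --------------------------------------------------------
    if config.adjust_pressure_to_elevation:
        z_src = coarse.elevation[src_pos][:, None]
        z_tgt = fine.elevation[:, None]
        t_day_mean = ta_recon.reshape(n_cells, -1, 24).mean(axis=2)
        t_mean = np.repeat(t_day_mean, 24, axis=1)
        ps = adjust_pressure(ps, z_src, z_tgt, t_mean)
    rh = relative_humidity(ta_recon, e_recon)
    wspd = wind_speed(u10, v10)

    # --- heat-stress indices ----------------------------------------------
    cosz = np.cos(np.radians(solar_fine["zenith"]))
    cosz_s = np.where(cosz <= 0.0, config.night_cos_zenith_sentinel, cosz)
    ghi, dni, dhi, albedo = (
        solar_fine["ghi"], solar_fine["dni"], solar_fine["dhi"], solar_fine["albedo"]
    )
    fdir = direct_beam_fraction(ghi, dhi)
    hi = heat_index(ta_recon, rh)
    tw, tg, wbgt = wbgt_liljegren(ta_recon, rh, ps, wspd, ghi, fdir, cosz_s)
    cosz_pos = np.clip(cosz, 0.0, None)
    tmrt = mean_radiant_temperature(
        ghi, (1.0 - albedo) * ghi, dni, dni * cosz_pos, ldown, lnet, cosz_pos
    )
    utci_v = utci(ta_recon, wspd, tmrt, e_recon)

    return {
        "grid": fine,
        "cell_ids": fine_order.to_numpy(),
        "hours": hours,
        "windows": windows,
        "fields": {
            "ta": ta_recon, "td": td_recon, "e": e_recon, "rh": rh,
            "ps": ps, "wind": wspd, "hi": hi, "tw": tw, "tg": tg,
            "wbgt": wbgt, "tmrt": tmrt, "utci": utci_v,
        },
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write per-day outputs plus a run manifest."""
    config.validate()
    input_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    logger.info("stage align: reading inputs from %s", input_dir)
    inputs = _read_inputs(input_dir)

    logger.info("stage reconstruct/regrid/ancillary/indices")
    result = compute_hourly_fields(config, inputs)
    fields, hours = result["fields"], result["hours"]
    cell_ids = result["cell_ids"]

    cell_long = wide_to_long(cell_ids, hours, fields)
    cell_path = out_dir / "cell_hourly.parquet"
    cell_long.to_parquet(cell_path, index=False)

    logger.info("stage aggregate: %d tracts", len(inputs["tracts"]))
    grid = result["grid"]
    pop = inputs["population"]
    pop_w = resample_population(
        pop["lat"].to_numpy(), pop["lon"].to_numpy(), pop["count"].to_numpy(), grid
    )
    pop_on_link = pd.Series(pop_w, index=grid.cell_ids).reindex(cell_ids).to_numpy()
    lookup = build_lookup(grid, inputs["tracts"], pop_weight=None)
    # attach population weights in lookup order
    lookup.table["pop_weight"] = (
        pd.Series(pop_on_link, index=cell_ids).reindex(lookup.table["cell_id"]).to_numpy()
    )

    files = []
    for wi, window in enumerate(result["windows"]):
        sl = hours[24 * wi: 24 * (wi + 1)]
        day_fields = {
            var: pd.DataFrame(fields[key][:, 24 * wi: 24 * (wi + 1)], index=cell_ids, columns=sl)
            for var, key in (("temp", "ta"), ("rh", "rh"), ("hi", "hi"), ("wbgt", "wbgt"), ("utci", "utci"))
        }
        records = tract_hourly_records(day_fields, lookup, sl)
        year = window.label_date.year
        path = write_tract_parquet(
            records, window.label_date, out_dir,
            pop_year=population_year(year), vintage=vintage_for_year(year),
        )
        files.append(path.name)

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "constants": {
            "buck_variant": c.BUCK_VARIANT,
            "night_cos_zenith_sentinel": config.night_cos_zenith_sentinel,
            "idw_power": config.idw_power,
            "liljegren_convergence_K": c.LILJEGREN.convergence,
            "liljegren_max_iter": c.LILJEGREN.max_iter,
        },
        "rows": {
            "cell_hourly": int(len(cell_long)),
            "tract_files": len(files),
            "tracts": int(lookup.table["geoid"].nunique()),
        },
        "outputs": {"cell_hourly": cell_path.name, "tract_files": files},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


# ---------------------------------------------------------------------------
# validation harness
# ---------------------------------------------------------------------------

def validate_field_against_stations(
    field: pd.DataFrame,
    grid: ReferenceGrid,
    stations: pd.DataFrame,
    obs: pd.DataFrame,
    max_distance: float = 800.0,
    obs_value: str = "ta",
    variable: str = "air_temperature",
) -> tuple[list[ValidationSummary], ValidationSummary]:
    """Match stations to cells and score a gridded field window by window.

    ``field`` is cells x hourly timestamps; ``obs`` holds columns
    station_id, timestamp, and the observed value.  Returns (per-window
    summaries, pooled summary) with station-hour weights.
    """
    matched = match_stations(stations, grid, max_distance)
    if matched.empty:
        raise ValueError("no stations matched within the distance threshold")
    obs_m = obs.merge(matched, on="station_id")
    hours = field.columns
    model_vals = field.reindex(obs_m["cell_id"]).to_numpy()
    col_pos = pd.Index(hours).get_indexer(pd.DatetimeIndex(obs_m["timestamp"]))
    ok = col_pos >= 0
    obs_m = obs_m[ok]
    model = model_vals[ok, col_pos[ok]]

    labels = pd.DatetimeIndex(obs_m["timestamp"])
    # assign each hour to its constraint-day window (12:00 rolls forward)
    window_label = (labels + pd.Timedelta(hours=12)).normalize()
    summaries = []
    for _, idx in pd.Series(range(len(obs_m)), index=window_label).groupby(level=0):
        rows = idx.to_numpy()
        summaries.append(
            error_metrics(
                obs_m[obs_value].to_numpy()[rows], model[rows],
                variable=variable, n_stations=int(obs_m["station_id"].iloc[rows].nunique()),
            )
        )
    return summaries, pool_windows(summaries)
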