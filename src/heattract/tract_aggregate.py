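"""Grid-to-tract assignment and area/population-weighted aggregation.

Each reference-grid cell centroid is assigned to the census tract polygon
containing it (centroid rule; cells split by a boundary are not fractionally
apportioned).  Tract-hour values are weighted means over member cells:

* area scheme  — cos(latitude) weights, the relative cell area on the sphere;
* population scheme — resampled population counts as raw weights.

Output rows follow the published 15-column schema and one Parquet file is
written per constraint day.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely import STRtree
from shapely.geometry import Point, shape, mapping

from .timegrid import ReferenceGrid

logger = logging.getLogger(__name__)

#: Published output schema, in order.
TRACT_SCHEMA = [
    "GEOID", "year", "month", "day", "time",
    "temp_C_used_area", "temp_C_used_pop",
    "rh_pct_used_area", "rh_pct_used_pop",
    "HI_C_area", "HI_C_pop",
    "WBGT_C_area", "WBGT_C_pop",
    "UTCI_C_area", "UTCI_C_pop",
]

#: Maps (variable, scheme) -> output column.
_VALUE_COLUMNS = {
    ("temp", "area"): "temp_C_used_area", ("temp", "pop"): "temp_C_used_pop",
    ("rh", "area"): "rh_pct_used_area", ("rh", "pop"): "rh_pct_used_pop",
    ("hi", "area"): "HI_C_area", ("hi", "pop"): "HI_C_pop",
    ("wbgt", "area"): "WBGT_C_area", ("wbgt", "pop"): "WBGT_C_pop",
    ("utci", "area"): "UTCI_C_area", ("utci", "pop"): "UTCI_C_pop",
}

FILENAME_PATTERN = (
    "heatstress_tract_area_and_popweighted_{d0}_{d1}_popy{pop_year}_v{vintage}.parquet"
)


def vintage_for_year(year: int) -> int:
    """Decennial boundary vintage for a data year (2000 boundaries serve
    1998-2009, 2010 for 2010-2019, 2020 onward)."""
    if year < 2010:
        return 2000
    if year < 2020:
        return 2010
    return 2020


def population_year(year: int) -> int:
    """Population-surface year; the 2000 surface backs 1998-1999."""
    return max(year, 2000)


# ---------------------------------------------------------------------------
# Tract geometry
# ---------------------------------------------------------------------------

def read_tracts_geojson(path) -> dict[str, object]:
    """Read tract polygons from a GeoJSON FeatureCollection with a GEOID
    property.  Returns {geoid: shapely geometry}."""
    with open(path) as fh:
        collection = json.load(fh)
    out: dict[str, object] = {}
    for feature in collection["features"]:
        geoid = str(feature["properties"]["GEOID"])
        out[geoid] = shape(feature["geometry"])
    return out


def write_tracts_geojson(tracts: dict[str, object], path) -> None:
    features = [
        {"type": "Feature", "properties": {"GEOID": geoid}, "geometry": mapping(geom)}
        for geoid, geom in tracts.items()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


@dataclass
class TractLookup:
    """Static cell-to-tract mapping with per-cell weights.

    ``table`` columns: geoid, cell_id, area_weight (cos latitude),
    pop_weight (persons).
    """

    table: pd.DataFrame

    def members(self, geoid: str) -> pd.DataFrame:
        return self.table[self.table["geoid"] == geoid]

    @property
    def geoids(self) -> list[str]:
        return sorted(self.table["geoid"].unique())


def build_lookup(
    grid: ReferenceGrid,
    tracts: dict[str, object],
    pop_weight: np.ndarray | None = None,
) -> TractLookup:
    """Assign each cell centroid to the tract polygon covering it.

    Boundary ties go to the first tract in sorted GEOID order.  A tract
    containing no centroid is assigned its single nearest cell centroid so
    every tract receives values.  Invalid polygon geometry is rejected with
    the offending identifier.
    """
    for geoid, geom in tracts.items():
        if not geom.is_valid:
            raise ValueError(f"invalid tract geometry: {geoid}")
    geoids = sorted(tracts)
    geoms = [tracts[g] for g in geoids]
    tree = STRtree(geoms)
    points = [Point(xy) for xy in zip(grid.lon, grid.lat)]

    assigned = np.full(len(grid), -1, dtype=int)
    for ci, pt in enumerate(points):
        candidates = sorted(tree.query(pt, predicate="covered_by"))
        if len(candidates):
            assigned[ci] = candidates[0]

    area_w = np.cos(np.radians(grid.lat))
    pop_w = np.zeros(len(grid)) if pop_weight is None else np.asarray(pop_weight, dtype=float)

    rows = {
        "geoid": [geoids[t] for t in assigned if t >= 0],
        "cell_id": grid.cell_ids[assigned >= 0],
        "area_weight": area_w[assigned >= 0],
        "pop_weight": pop_w[assigned >= 0],
    }
    table = pd.DataFrame(rows)

    # Empty tracts adopt the nearest centroid (duplicate membership allowed).
    empty = [g for g in geoids if g not in set(table["geoid"])]
    if empty:
        cell_xy = np.column_stack([grid.lon, grid.lat])
        kdt = cKDTree(cell_xy)
        extra = []
        for geoid in empty:
            centroid = tracts[geoid].centroid
            _, ci = kdt.query([centroid.x, centroid.y])
            extra.append(
                {
                    "geoid": geoid,
                    "cell_id": grid.cell_ids[ci],
                    "area_weight": area_w[ci],
                    "pop_weight": pop_w[ci],
                }
            )
            logger.info("tract %s has no member centroid; using nearest cell", geoid)
        table = pd.concat([table, pd.DataFrame(extra)], ignore_index=True)
    return TractLookup(table=table)


def resample_population(
    pop_lat: np.ndarray,
    pop_lon: np.ndarray,
    pop_counts: np.ndarray,
    grid: ReferenceGrid,
) -> np.ndarray:
    """Sum fine-lattice population counts into the containing reference cell.

    Fine points are assigned to the nearest cell centroid, which for a
    nesting lattice is the containing cell; the domain total is conserved
    exactly.
    """
    tree = cKDTree(np.column_stack([grid.lon, grid.lat]))
    _, idx = tree.query(np.column_stack([np.asarray(pop_lon), np.asarray(pop_lat)]))
    out = np.zeros(len(grid))
    np.add.at(out, idx, np.asarray(pop_counts, dtype=float))
    return out


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate_to_tracts(
    field: pd.DataFrame,
    lookup: TractLookup,
    scheme: str,
) -> pd.DataFrame:
    """Weighted tract means of per-cell values.

    ``field`` is indexed by cell_id with one column per hour (or variable).
    Missing member values are excluded with weights renormalized; a tract
    whose population weights sum to zero falls back to area weights for
    coverage; a tract with no valid members yields NaN.
    Returns a DataFrame indexed by geoid with ``field``'s columns.
    """
    if scheme not in ("area", "pop"):
        raise ValueError("scheme must be 'area' or 'pop'")
    tbl = lookup.table
    values = field.reindex(tbl["cell_id"]).to_numpy(dtype=float)   # (members, cols)
    weights = tbl[f"{scheme}_weight"].to_numpy(dtype=float)

    if scheme == "pop":
        # zero-total-population tracts fall back to area weights
        totals = tbl.groupby("geoid")["pop_weight"].transform("sum").to_numpy()
        fallback = totals <= 0
        if fallback.any():
            logger.info(
                "%d tracts have zero population weight; falling back to area weights",
                tbl.loc[fallback, "geoid"].nunique(),
            )
            weights = np.where(fallback, tbl["area_weight"].to_numpy(dtype=float), weights)

    valid = np.isfinite(values)
    w = weights[:, None] * valid
    wx = np.where(valid, values, 0.0) * w
    geoid_codes, geoid_index = pd.factorize(tbl["geoid"], sort=True)
    num = np.zeros((len(geoid_index), values.shape[1]))
    den = np.zeros_like(num)
    np.add.at(num, geoid_codes, wx)
    np.add.at(den, geoid_codes, w)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return pd.DataFrame(out, index=pd.Index(geoid_index, name="geoid"), columns=field.columns)


def tract_hourly_records(
    fields: dict[str, pd.DataFrame],
    lookup: TractLookup,
    hours: pd.DatetimeIndex,
) -> pd.DataFrame:
    """Build the per-tract-hour output table from per-cell hourly fields.

    ``fields`` maps variable name in {temp, rh, hi, wbgt, utci} to a
    DataFrame indexed by cell_id with one column per hour in ``hours``.
    """
    pieces: dict[str, pd.DataFrame] = {}
    for var, frame in fields.items():
        for scheme in ("area", "pop"):
            col = _VALUE_COLUMNS[(var, scheme)]
            agg = aggregate_to_tracts(frame, lookup, scheme)
            stacked = agg.stack(future_stack=True)
            pieces[col] = stacked

    wide = pd.DataFrame(pieces)
    wide.index.names = ["geoid", "hour"]
    wide = wide.reset_index()
    ts = pd.DatetimeIndex(wide["hour"])
    out = pd.DataFrame(
        {
            "GEOID": wide["geoid"].astype(str),
            "year": ts.year.astype("int32"),
            "month": ts.month.astype("int32"),
            "day": ts.day.astype("int32"),
            "time": ts.hour.astype("int32"),
        }
    )
    for col in TRACT_SCHEMA[5:]:
        out[col] = wide[col].to_numpy()
    return out.sort_values(["GEOID", "year", "month", "day", "time"], ignore_index=True)


def output_filename(label_date: date, pop_year: int, vintage: int) -> str:
    """Published per-day file name; the two dates are the half UTC days the
    window spans (label_date - 1 and label_date)."""
    d0 = (label_date - timedelta(days=1)).isoformat()
    return FILENAME_PATTERN.format(d0=d0, d1=label_date.isoformat(), pop_year=pop_year, vintage=vintage)


def write_tract_parquet(
    records: pd.DataFrame,
    label_date: date,
    out_dir,
    pop_year: int | None = None,
    vintage: int | None = None,
) -> Path:
    """Write one constraint day of tract-hour records to Parquet.

    Refuses to write if the column set deviates from the published schema or
    any tract has other than 24 hourly rows.
    """
    if list(records.columns) != TRACT_SCHEMA:
        raise ValueError(
            f"schema mismatch: expected {TRACT_SCHEMA}, got {list(records.columns)}"
        )
    counts = records.groupby("GEOID").size()
    if not (counts == 24).all():
        bad = counts[counts != 24].index.tolist()
        raise ValueError(f"tracts without a complete 24-hour window: {bad[:5]}")
    if pop_year is None:
        pop_year = population_year(label_date.year)
    if vintage is None:
        vintage = vintage_for_year(label_date.year)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / output_filename(label_date, pop_year, vintage)
    records.to_parquet(path, index=False)
    return path


def parse_output_filename(name: str) -> dict:
    m = re.fullmatch(
        r"heatstress_tract_area_and_popweighted_(\d{4}-\d{2}-\d{2})_(\d{4}-\d{2}-\d{2})"
        r"_popy(\d{4})_v(\d{4})\.parquet",
        name,
    )
    if not m:
        raise ValueError(f"unrecognized output file name: {name}")
    return {
        "start_date": date.fromisoformat(m.group(1)),
        "label_date": date.fromisoformat(m.group(2)),
        "pop_year": int(m.group(3)),
        "vintage": int(m.group(4)),
    }
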