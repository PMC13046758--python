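"""Reference grid, the daily 24-hour UTC window convention, and grid linking.

The fine-resolution grid that the daily constraint product is delivered on is
adopted as the reference grid: every reconstructed or interpolated field is
expressed on its cells.  Time is organised in "constraint days": each labeled
calendar day owns the 24 UTC hours running from 12:00 of the previous day to
11:00 of the labeled day, so daily extrema and the hourly window they
constrain always refer to the same span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .projection import AlbersEqualArea

GRID_COLUMNS = ["cell_id", "lat", "lon", "elevation"]


@dataclass
class ReferenceGrid:
    """A flat table of grid cells (centroid lat/lon, elevation).

    A flat cell table rather than a 2-D raster, so irregular subsets
    (e.g. land-only cells) are first-class.
    """

    cells: pd.DataFrame
    spacing_tolerance: float = 0.05  # relative tolerance on regular spacing
    land_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in GRID_COLUMNS if c not in self.cells.columns]
        if missing:
            raise ValueError(f"grid table missing columns: {missing}")
        cid = self.cells["cell_id"].to_numpy()
        if len(np.unique(cid)) != len(cid):
            raise ValueError("cell_ids must be unique")
        lat = self.cells["lat"].to_numpy(dtype=float)
        lon = self.cells["lon"].to_numpy(dtype=float)
        if np.any((lat < -90) | (lat > 90)):
            raise ValueError("latitude out of [-90, 90]")
        if np.any((lon < -180) | (lon > 180)):
            raise ValueError("longitude out of [-180, 180]")
        self._check_regular_spacing()

    def _check_regular_spacing(self) -> None:
        # Unique coordinate levels must be evenly spaced within tolerance.
        for col in ("lat", "lon"):
            levels = np.unique(self.cells[col].to_numpy(dtype=float))
            if len(levels) < 3:
                continue
            steps = np.diff(levels)
            mean_step = steps.mean()
            if mean_step > 0 and np.any(np.abs(steps - mean_step) > self.spacing_tolerance * mean_step):
                raise ValueError(f"{col} levels are not regularly spaced within tolerance")

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def cell_ids(self) -> np.ndarray:
        return self.cells["cell_id"].to_numpy()

    @property
    def lat(self) -> np.ndarray:
        return self.cells["lat"].to_numpy(dtype=float)

    @property
    def lon(self) -> np.ndarray:
        return self.cells["lon"].to_numpy(dtype=float)

    @property
    def elevation(self) -> np.ndarray:
        return self.cells["elevation"].to_numpy(dtype=float)

    def projection(self) -> AlbersEqualArea:
        return AlbersEqualArea.for_domain(self.lat, self.lon)

    def projected_xy(self, projection: AlbersEqualArea | None = None) -> np.ndarray:
        proj = projection or self.projection()
        return proj.xy(self.lat, self.lon)

    # -- I/O ---------------------------------------------------------------

    def to_parquet(self, path) -> None:
        self.cells[GRID_COLUMNS].to_parquet(path, index=False)

    @classmethod
    def read(cls, path, **kwargs) -> "ReferenceGrid":
        path = str(path)
        if path.endswith(".csv"):
            return cls(pd.read_csv(path), **kwargs)
        return cls(pd.read_parquet(path), **kwargs)


@dataclass(frozen=True)
class PrismDayWindow:
    """The 24-hour UTC window owned by one labeled calendar day."""

    label_date: date
    hours: pd.DatetimeIndex

    def __post_init__(self) -> None:
        if len(self.hours) != 24:
            raise ValueError("window must contain exactly 24 hours")


def prism_day_window(label_date: date | str) -> PrismDayWindow:
    """24 hourly UTC timestamps from 12:00 of label_date-1 to 11:00 of label_date."""
    if isinstance(label_date, str):
        label_date = date.fromisoformat(label_date)
    start = datetime(label_date.year, label_date.month, label_date.day, 12, tzinfo=timezone.utc) - timedelta(days=1)
    hours = pd.date_range(start, periods=24, freq="h", tz="UTC")
    return PrismDayWindow(label_date=label_date, hours=hours)


def window_range(start: date | str, end: date | str) -> list[PrismDayWindow]:
    """Windows for every labeled day from start to end inclusive."""
    if isinstance(start, str):
        start = date.fromisoformat(start)
    if isinstance(end, str):
        end = date.fromisoformat(end)
    if end < start:
        raise ValueError("end date before start date")
    out = []
    d = start
    while d <= end:
        out.append(prism_day_window(d))
        d += timedelta(days=1)
    return out


def nearest_source_map(
    target: ReferenceGrid,
    source: ReferenceGrid,
    projection: AlbersEqualArea | None = None,
) -> pd.DataFrame:
    """Link each target cell to its geometrically nearest source cell.

    Distances are planar, in the configured equal-area projection (built over
    the union of both grids by default).  Ties are broken toward the lowest
    source cell_id for determinism.

    Returns a DataFrame with columns target_cell_id, source_cell_id, distance
    (meters).
    """
    if len(source) == 0:
        raise ValueError("source grid is empty")
    if len(target) == 0:
        raise ValueError("target grid is empty")
    if projection is None:
        projection = AlbersEqualArea.for_domain(
            np.concatenate([target.lat, source.lat]),
            np.concatenate([target.lon, source.lon]),
        )
    # Sort sources by cell_id so cKDTree's lowest-index tie-break realises
    # the lowest-cell_id rule.
    order = np.argsort(source.cell_ids, kind="stable")
    src_xy = projection.xy(source.lat[order], source.lon[order])
    tree = cKDTree(src_xy)
    dist, idx = tree.query(projection.xy(target.lat, target.lon), k=1)
    return pd.DataFrame(
        {
            "target_cell_id": target.cell_ids,
            "source_cell_id": source.cell_ids[order][idx],
            "distance": dist,
        }
    )
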