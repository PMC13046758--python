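"""Station-based validation: matching, error metrics, station-hour pooling.

Stations are matched to the nearest grid cell and kept only within a
distance threshold sized to the grid's resolution (800 m for the fine
reconstructed grid, 9 km for the coarse reference product).  Errors are
summarized as bias (model - obs), RMSE and Pearson r; window-level
summaries combine into a pooled estimate weighted by matched station-hours,
which reproduces exactly the metrics over the concatenated pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .projection import AlbersEqualArea
from .timegrid import ReferenceGrid

logger = logging.getLogger(__name__)


@dataclass
class ValidationSummary:
    variable: str
    n_stations: int
    matched_hours: int
    bias: float
    rmse: float
    pearson_r: float

    def as_dict(self) -> dict:
        return {
            "variable": self.variable,
            "n_stations": self.n_stations,
            "matched_hours": self.matched_hours,
            "bias": self.bias,
            "rmse": self.rmse,
            "pearson_r": self.pearson_r,
        }


def match_stations(
    stations: pd.DataFrame,
    grid: ReferenceGrid,
    max_distance: float,
) -> pd.DataFrame:
    """Match stations (columns station_id, lat, lon) to nearest grid cells.

    Stations farther than ``max_distance`` meters from any cell centroid are
    excluded (logged).  Returns columns station_id, cell_id, distance.
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be positive")
    proj = AlbersEqualArea.for_domain(
        np.concatenate([grid.lat, stations["lat"].to_numpy(dtype=float)]),
        np.concatenate([grid.lon, stations["lon"].to_numpy(dtype=float)]),
    )
    tree = cKDTree(proj.xy(grid.lat, grid.lon))
    dist, idx = tree.query(proj.xy(stations["lat"].to_numpy(), stations["lon"].to_numpy()))
    keep = dist <= max_distance
    if (~keep).any():
        logger.info("excluded %d stations beyond %.0f m", int((~keep).sum()), max_distance)
    return pd.DataFrame(
        {
            "station_id": stations["station_id"].to_numpy()[keep],
            "cell_id": grid.cell_ids[idx[keep]],
            "distance": dist[keep],
        }
    )


def error_metrics(
    obs,
    model,
    variable: str = "",
    n_stations: int = 0,
) -> ValidationSummary:
    """Bias = mean(model - obs), RMSE, and Pearson r over aligned pairs.

    Pairs with a missing member are dropped; fewer than two valid pairs (or
    a degenerate constant series) leave the correlation undefined (NaN).
    """
    o = np.asarray(obs, dtype=float)
    m = np.asarray(model, dtype=float)
    if o.shape != m.shape:
        raise ValueError("obs and model must be aligned, equal-length series")
    ok = np.isfinite(o) & np.isfinite(m)
    o, m = o[ok], m[ok]
    n = len(o)
    if n == 0:
        return ValidationSummary(variable, n_stations, 0, np.nan, np.nan, np.nan)
    err = m - o
    bias = float(err.mean())
    rmse = float(np.sqrt(np.mean(err**2)))
    if n >= 2 and o.std() > 0 and m.std() > 0:
        r = float(np.corrcoef(o, m)[0, 1])
    else:
        r = np.nan
    return ValidationSummary(variable, n_stations, n, bias, rmse, r)


def pool_windows(summaries: list[ValidationSummary], weights=None) -> ValidationSummary:
    """Combine window-level summaries, weighting by matched station-hours.

    Bias and mean-squared error are pooled linearly by weight and the pooled
    RMSE is the square root of the pooled MSE, so with pair counts as
    weights the result equals metrics over the concatenated pairs.  The
    pooled correlation is the weighted mean of window correlations.
    """
    if not summaries:
        raise ValueError("no summaries to pool")
    w = np.array(
        [s.matched_hours for s in summaries] if weights is None else list(weights),
        dtype=float,
    )
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with a positive sum")
    w = w / w.sum()
    bias = float(np.sum(w * np.array([s.bias for s in summaries])))
    mse = float(np.sum(w * np.array([s.rmse for s in summaries]) ** 2))
    rs = np.array([s.pearson_r for s in summaries])
    r = float(np.sum(w * rs)) if np.all(np.isfinite(rs)) else np.nan
    return ValidationSummary(
        variable=summaries[0].variable,
        n_stations=max(s.n_stations for s in summaries),
        matched_hours=int(sum(s.matched_hours for s in summaries)),
        bias=bias,
        rmse=float(np.sqrt(mse)),
        pearson_r=r,
    )


def summaries_to_frame(summaries: list[ValidationSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.as_dict() for s in summaries])
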