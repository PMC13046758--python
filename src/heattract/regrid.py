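"""Temporal preprocessing of radiation series and IDW spatial interpolation.

Accumulated longwave radiation (J/m2, resetting at the source's accumulation
day boundary) is converted to hourly mean fluxes (W/m2); half-hourly solar
series are aggregated to hourly; coarse fields are moved onto the reference
grid with a local, k-nearest inverse-distance-weighted scheme with a hard
distance cutoff per source product.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

SECONDS_PER_HOUR = 3600.0


def accumulated_to_flux(
    timestamps: pd.DatetimeIndex,
    accumulated,
    reset_hour: int | None = 1,
    clip_negative: bool = False,
) -> pd.Series | pd.DataFrame:
    """Convert hourly accumulations [J/m2] to mean fluxes [W/m2].

    The flux labeled at timestamp t covers the hour ending at t and equals
    (acc(t) - acc(t-1)) / 3600.  At the first step of an accumulation day
    (hour == ``reset_hour``) the accumulator has restarted, so the flux is
    acc(t)/3600.  With ``clip_negative`` (appropriate for physically
    nonnegative accumulations such as downwelling radiation), negative
    differences — unexpected resets — are clipped to zero with a warning;
    signed accumulations such as net radiation must leave it off.  The first
    timestamp has no predecessor and is dropped.  ``accumulated`` may be 1-D
    (series) or 2-D (n_times, n_cells).
    """
    ts = pd.DatetimeIndex(timestamps)
    if not ts.is_monotonic_increasing or ts.has_duplicates:
        raise ValueError("timestamps must be strictly increasing")
    acc = np.asarray(accumulated, dtype=float)
    diff = (acc[1:] - acc[:-1]) / SECONDS_PER_HOUR
    out_ts = ts[1:]
    if reset_hour is not None:
        at_reset = out_ts.hour == reset_hour
        if at_reset.any():
            first = acc[1:][at_reset] / SECONDS_PER_HOUR
            diff[at_reset] = first
    if clip_negative:
        negative = diff < 0
        if negative.any():
            logger.warning("clipped %d negative accumulation differences to zero", int(negative.sum()))
            diff = np.where(negative, 0.0, diff)
    if diff.ndim == 1:
        return pd.Series(diff, index=out_ts)
    return pd.DataFrame(diff, index=out_ts)


def halfhour_to_hour(first, second):
    """Mean of two aligned half-hour samples; one missing -> the other,
    both missing -> missing."""
    a = np.asarray(first, dtype=float)
    b = np.asarray(second, dtype=float)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pair -> NaN
        out = np.nanmean(np.stack([a, b]), axis=0)
    return out


def aggregate_zenith(theta1_deg, theta2_deg):
    """Hourly zenith angle: arccos of the mean cosine of the two half hours.

    Averaging in cosine space preserves radiative consistency (the mean of
    cos(theta) is what scales direct-beam projection).
    """
    t1 = np.asarray(theta1_deg, dtype=float)
    t2 = np.asarray(theta2_deg, dtype=float)
    for t in (t1, t2):
        valid = np.isnan(t) | ((t >= 0.0) & (t <= 180.0))
        if not np.all(valid):
            raise ValueError("zenith angle out of [0, 180] degrees")
    mean_cos = halfhour_to_hour(np.cos(np.radians(t1)), np.cos(np.radians(t2)))
    return np.degrees(np.arccos(np.clip(mean_cos, -1.0, 1.0)))


def idw_interpolate(
    source_xy: np.ndarray,
    source_values: np.ndarray,
    target_xy: np.ndarray,
    cutoff: float,
    k: int = 4,
    power: float = 2.0,
) -> np.ndarray:
    """Inverse-distance-weighted interpolation from the k nearest sources.

    Parameters
    ----------
    source_xy, target_xy : (n, 2) projected coordinates in meters.
    source_values : (n_source,) or (n_source, n_fields) values; NaN entries
        are ignored per target (weights renormalized), so the scheme degrades
        to nearest-neighbor when only one valid source remains.
    cutoff : hard distance limit in meters; sources beyond it never
        contribute.  A target with no valid source within the cutoff yields
        NaN.
    k : number of nearest sources considered.
    power : weight exponent, w = 1/d**power.

    A target coincident with a source receives that source's value exactly.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    src = np.asarray(source_xy, dtype=float)
    tgt = np.asarray(target_xy, dtype=float)
    vals = np.asarray(source_values, dtype=float)
    squeeze = vals.ndim == 1
    if squeeze:
        vals = vals[:, None]

    kk = min(k, len(src))
    tree = cKDTree(src)
    dist, idx = tree.query(tgt, k=kk, distance_upper_bound=cutoff)
    dist = np.atleast_2d(dist.reshape(len(tgt), kk))
    idx = np.atleast_2d(idx.reshape(len(tgt), kk))

    in_range = np.isfinite(dist)
    idx_safe = np.where(in_range, idx, 0)
    neigh = vals[idx_safe]                       # (n_tgt, kk, n_fields)
    # Coincident source dominates: a tiny floor keeps 1/d finite while making
    # its weight larger than any other by ~30 orders of magnitude, which is
    # exact in float64.
    d = np.maximum(dist, 1e-12)
    w = np.where(in_range, 1.0 / d**power, 0.0)  # (n_tgt, kk)
    valid = np.isfinite(neigh) & in_range[:, :, None]
    w3 = np.where(valid, w[:, :, None], 0.0)
    wsum = w3.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.einsum("tkf,tkf->tf", w3, np.nan_to_num(neigh)) / wsum
    out = np.where(wsum > 0, out, np.nan)
    return out[:, 0] if squeeze else out
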