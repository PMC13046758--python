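"""Hourly temperature and vapor-pressure reconstruction on the reference grid.

The coarse hourly reanalysis supplies the *shape* of the diurnal cycle; the
fine-resolution daily product supplies the *amplitude* (daily Tmin/Tmax) and
the daily mean moisture state.  Per cell and constraint-day window:

    f(h)   = (T_src(h) - min_h T_src) / (max_h T_src - min_h T_src)
    Ta(h)  = Ta_min + f(h) * (Ta_max - Ta_min)
    dTd    = Td_mean_daily - mean_h Td_src(h)
    Td(h)  = Td_src(h) + dTd
    e(h)   = min(es(Td(h)), es(Ta(h)))        [saturation cap]

so the reconstructed series conserves the daily extrema exactly (when the
source profile attains 0 and 1) and the daily mean dew point exactly, while
inheriting the source's intraday timing.

All temperatures in degC, vapor pressures in hPa.  Arrays may carry a leading
cell dimension; the hour axis is the last axis.
"""

from __future__ import annotations

import numpy as np

from .constants import BUCK_A, BUCK_B, BUCK_C, BUCK_D


def saturation_vapor_pressure(t_c):
    """Saturation vapor pressure over water [hPa] at temperature t_c [degC].

    Arden Buck fit: es = 6.1121 * exp((18.678 - T/234.5) * T / (257.14 + T)).
    Non-finite input propagates as NaN.
    """
    t = np.asarray(t_c, dtype=float)
    return BUCK_A * np.exp((BUCK_B - t / BUCK_D) * t / (BUCK_C + t))


def diurnal_profile(ta_source_hourly, flat_value: float = 0.5):
    """Normalize an hourly temperature series to its own daily extrema.

    Returns f with f[argmin] = 0 and f[argmax] = 1.  A flat source day
    (max == min) yields the constant ``flat_value`` (default 0.5: the
    midpoint of the constraint range, bounded and symmetric).
    """
    t = np.asarray(ta_source_hourly, dtype=float)
    tmin = np.nanmin(t, axis=-1, keepdims=True)
    tmax = np.nanmax(t, axis=-1, keepdims=True)
    span = tmax - tmin
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(span > 0, (t - tmin) / np.where(span == 0, 1.0, span), flat_value)
    return f


def reconstruct_temperature(profile, ta_min, ta_max):
    """Rescale a [0,1] diurnal profile to the daily extrema constraints.

    ``ta_min``/``ta_max`` broadcast against the profile's leading axes.
    """
    f = np.asarray(profile, dtype=float)
    lo = np.asarray(ta_min, dtype=float)
    hi = np.asarray(ta_max, dtype=float)
    if lo.ndim == f.ndim - 1 and lo.ndim > 0:
        lo = lo[..., None]
    if hi.ndim == f.ndim - 1 and hi.ndim > 0:
        hi = hi[..., None]
    if np.any(lo > hi):
        raise ValueError("daily constraint has Ta_min > Ta_max")
    return lo + f * (hi - lo)


def reconstruct_vapor_pressure(td_source_hourly, td_mean_daily, ta_recon):
    """Shift the source dew-point profile to the daily mean and derive e.

    Returns ``(td, e)`` where the corrected dew point td has hourly mean
    exactly ``td_mean_daily`` and e = min(es(td), es(ta_recon)) caps
    supersaturation in vapor-pressure space (the dew point itself is not
    truncated).
    """
    td_src = np.asarray(td_source_hourly, dtype=float)
    ta = np.asarray(ta_recon, dtype=float)
    mean_src = np.nanmean(td_src, axis=-1, keepdims=True)
    td_mean = np.asarray(td_mean_daily, dtype=float)
    if td_mean.ndim == td_src.ndim - 1:
        td_mean = td_mean[..., None]
    td = td_src + (td_mean - mean_src)
    e = np.minimum(saturation_vapor_pressure(td), saturation_vapor_pressure(ta))
    return td, e
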