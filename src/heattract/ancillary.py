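"""Derived surface variables: relative humidity, wind speed, pressure.

Relative humidity is computed *after* the vapor-pressure saturation cap, so
the [0, 100] clip here is a numerical guard against round-off, not a
physical correction.  The hypsometric pressure adjustment ships as an opt-in
flag (default off): moving the interpolated pressure from the source
product's elevation to the reference-cell elevation made no meaningful
difference to the heat-stress outputs, so interpolated values are used
directly by default.
"""

from __future__ import annotations

import numpy as np

from .constants import GRAVITY, R_DRY_AIR, ZERO_C_IN_K
from .reconstruction import saturation_vapor_pressure


def relative_humidity(ta_c, e_hpa):
    """RH [%] = 100 * e / es(Ta), clipped to [0, 100]."""
    e = np.asarray(e_hpa, dtype=float)
    rh = 100.0 * e / saturation_vapor_pressure(ta_c)
    return np.clip(rh, 0.0, 100.0)


def wind_speed(u, v):
    """Horizontal wind magnitude [m/s] from zonal/meridional components."""
    return np.hypot(np.asarray(u, dtype=float), np.asarray(v, dtype=float))


def adjust_pressure(ps_ref_pa, z_source_m, z_target_m, t_mean_c):
    """Move surface pressure between elevations with the hypsometric equation.

    Assumes hydrostatic balance with the layer at the daily mean temperature:

        P_target = P_ref * exp( g * (z_source - z_target) / (Rd * T_K) )

    so a target *below* the source receives *higher* pressure; the identity
    holds when the elevations coincide and the transform is its own inverse
    under swapped elevations.
    """
    t_k = np.asarray(t_mean_c, dtype=float) + ZERO_C_IN_K
    if np.any(t_k <= 0):
        raise ValueError("nonpositive absolute temperature")
    dz = np.asarray(z_source_m, dtype=float) - np.asarray(z_target_m, dtype=float)
    return np.asarray(ps_ref_pa, dtype=float) * np.exp(GRAVITY * dz / (R_DRY_AIR * t_k))
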