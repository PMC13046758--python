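"""Heat-stress indices: Heat Index, Liljegren WBGT, mean radiant temperature, UTCI.

All public functions are vectorized over numpy arrays, take Celsius / hPa /
Pa / m/s as stated per argument, and return Celsius.

* ``heat_index`` — the National Weather Service algorithm: the simple
  averaged formula in the cool regime, the Rothfusz regression above 80 degF
  with the low- and high-humidity adjustment terms.  No output masking.
* ``wbgt_liljegren`` — the full Liljegren energy-balance model.  The natural
  wet-bulb temperature solves the wick balance (convection + radiation =
  evaporation) and the globe temperature the globe balance (solar + longwave
  absorption = convection + emission), both by damped fixed-point iteration;
  WBGT = 0.7 Tw + 0.2 Tg + 0.1 Ta.
* ``mean_radiant_temperature`` — fourth-root radiant-flux balance for a
  standing person: half view factors to sky and ground for longwave,
  absorbed diffuse + reflected + projected direct shortwave.
* ``utci`` — the sixth-order polynomial approximation of the Universal
  Thermal Climate Index, masked outside its published validity domain.
"""

from __future__ import annotations

import numpy as np

from . import constants as c
from ._utci_coeffs import UTCI_POLYNOMIAL
from .reconstruction import saturation_vapor_pressure

__all__ = [
    "heat_index",
    "direct_beam_fraction",
    "wbgt_liljegren",
    "mean_radiant_temperature",
    "utci",
]


# ---------------------------------------------------------------------------
# Heat Index (NWS / Rothfusz)
# ---------------------------------------------------------------------------

def heat_index(ta_c, rh_pct):
    """NWS Heat Index [degC] from air temperature [degC] and RH [%].

    Computed in Fahrenheit internally as the regression requires.  Every
    input combination returns a number (no validity masking).
    """
    t = np.asarray(ta_c, dtype=float) * 1.8 + 32.0
    rh = np.asarray(rh_pct, dtype=float)
    t, rh = np.broadcast_arrays(t, rh)

    simple = 0.5 * (t + 61.0 + (t - 68.0) * 1.2 + rh * 0.094)

    hi = -42.379 + 2.04901523 * t + 10.14333127 * rh \
        - 0.22475541 * t * rh - 6.83783e-3 * t * t \
        - 5.481717e-2 * rh * rh + 1.22874e-3 * t * t * rh \
        + 8.5282e-4 * t * rh * rh - 1.99e-6 * t * t * rh * rh

    with np.errstate(invalid="ignore"):
        low_rh = (rh < 13.0) & (t >= 80.0) & (t <= 112.0)
        adj = ((13.0 - rh) / 4.0) * np.sqrt(
            np.clip(17.0 - np.abs(t - 95.0), 0.0, None) / 17.0
        )
        hi = np.where(low_rh, hi - adj, hi)
        high_rh = (rh > 85.0) & (t >= 80.0) & (t <= 87.0)
        hi = np.where(high_rh, hi + ((rh - 85.0) / 10.0) * ((87.0 - t) / 2.0), hi)

    out_f = np.where(simple >= 80.0, hi, simple)
    return (out_f - 32.0) / 1.8


# ---------------------------------------------------------------------------
# Solar geometry helper
# ---------------------------------------------------------------------------

def direct_beam_fraction(ghi, dhi):
    """f_dir = 1 - DHI/GHI clamped to [0, 1]; zero whenever GHI <= 1 W/m2."""
    g = np.asarray(ghi, dtype=float)
    d = np.asarray(dhi, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = 1.0 - d / g
    f = np.clip(f, 0.0, 1.0)
    return np.where(g <= 1.0, 0.0, f)


# ---------------------------------------------------------------------------
# Liljegren WBGT
# ---------------------------------------------------------------------------

_L = c.LILJEGREN
# critical-point constants of the binary diffusivity correlation
_PCRIT_AIR, _PCRIT_H2O = 36.4, 218.0
_TCRIT_AIR, _TCRIT_H2O = 132.0, 647.3
_DIFF_A, _DIFF_B = 3.640e-4, 2.334


def _esat_lil(tk):
    """Saturation vapor pressure [hPa] with the model's own moist-air fit."""
    return 1.004 * 6.1121 * np.exp(17.502 * (tk - 273.15) / (tk - 32.18))


def _dewpoint_lil(e_hpa):
    z = np.log(e_hpa / (1.004 * 6.1121))
    return 273.15 + 240.97 * z / (17.502 - z)


def _viscosity(tk):
    return 1.458e-6 * tk**1.5 / (tk + 110.4)


def _thermal_conductivity(tk):
    return (_L.cp + 1.25 * _L.r_air) * _viscosity(tk)


def _diffusivity(tk, p_hpa):
    pcrit13 = (_PCRIT_AIR * _PCRIT_H2O) ** (1.0 / 3.0)
    tcrit512 = (_TCRIT_AIR * _TCRIT_H2O) ** (5.0 / 12.0)
    tcrit12 = (_TCRIT_AIR * _TCRIT_H2O) ** 0.5
    mmix = (1.0 / _L.m_air + 1.0 / _L.m_h2o) ** 0.5
    return _DIFF_A * (tk / tcrit12) ** _DIFF_B * pcrit13 * tcrit512 * mmix / (p_hpa / 1013.25) * 1e-4


def _heat_of_evaporation(tk):
    return (313.15 - tk) / 30.0 * (-71100.0) + 2.4073e6


def _emissivity_atm(tk, rh_frac):
    return 0.575 * (rh_frac * _esat_lil(tk)) ** 0.143


def _h_sphere(tk, p_hpa, speed):
    density = p_hpa * 100.0 / (_L.r_air * tk)
    reynolds = speed * density * _L.globe_diameter / _viscosity(tk)
    nusselt = 2.0 + 0.6 * np.sqrt(reynolds) * _L.prandtl ** (1.0 / 3.0)
    return nusselt * _thermal_conductivity(tk) / _L.globe_diameter


def _h_cylinder(tk, p_hpa, speed):
    a, cexp = 0.56, 0.4
    density = p_hpa * 100.0 / (_L.r_air * tk)
    reynolds = speed * density * _L.wick_diameter / _viscosity(tk)
    nusselt = 0.281 * reynolds ** (1.0 - cexp) * _L.prandtl ** (1.0 - a)
    return nusselt * _thermal_conductivity(tk) / _L.wick_diameter


def _stability_class(speed, solar):
    """Pasquill stability class (1..6) from wind speed and solar flux.

    Daytime (solar > 0) uses the published solar/speed table; at night,
    without a vertical temperature gradient, the class is set from wind
    speed alone assuming the usual nocturnal surface inversion.
    """
    speed = np.asarray(speed, dtype=float)
    solar = np.asarray(solar, dtype=float)
    speed, solar = np.broadcast_arrays(speed, solar)
    day_table = np.array([
        [1, 1, 2, 4],
        [1, 2, 3, 4],
        [2, 2, 3, 4],
        [3, 3, 4, 4],
        [3, 4, 4, 4],
    ])
    i = np.digitize(speed, [2.0, 3.0, 5.0, 6.0])
    j = 3 - np.digitize(solar, [175.0, 675.0, 925.0])
    day_class = day_table[i, j]
    night_class = np.where(speed < 2.0, 6, np.where(speed < 2.5, 5, 4))
    return np.where(solar > 0, day_class, night_class)


def wind_to_reference_height(u10, solar, measurement_height: float = 10.0):
    """Estimate wind at the 2 m instrument height from 10 m wind.

    Power-law profile with a rural stability-class-dependent exponent, then
    floored at the anemometer stall speed.
    """
    u10 = np.asarray(u10, dtype=float)
    exponent = np.take(np.asarray(c.WIND_EXPONENT_RURAL), _stability_class(u10, solar) - 1)
    u2 = u10 * (_L.wind_ref_height / measurement_height) ** exponent
    return np.maximum(u2, _L.min_speed)


def _iterate(update, start, tol, max_iter, damping=0.1):
    """Damped fixed-point iteration with per-element convergence."""
    prev = np.array(start, dtype=float)
    done = np.zeros(prev.shape, dtype=bool)
    result = np.full(prev.shape, np.nan)
    for _ in range(max_iter):
        new = update(prev)
        just = (np.abs(new - prev) < tol) & ~done
        result[just] = new[just]
        done |= just
        if done.all():
            break
        prev = np.where(done, prev, (1.0 - damping) * prev + damping * new)
    return result


def _globe_temperature(tk, rh_frac, p_hpa, speed, solar, fdir, cza):
    tsfc = tk
    ea = _emissivity_atm(tk, rh_frac)
    sig_eps = c.STEFAN_BOLTZMANN * _L.globe_emissivity
    solar_term = solar / (2.0 * sig_eps) * (1.0 - _L.globe_albedo) * (
        fdir * (1.0 / (2.0 * cza) - 1.0) + 1.0 + _L.surface_albedo
    )

    def update(tg):
        tref = 0.5 * (tg + tk)
        h = _h_sphere(tref, p_hpa, speed)
        rad = 0.5 * (ea * tk**4 + _L.surface_emissivity * tsfc**4) \
            - h / sig_eps * (tg - tk) + solar_term
        return np.maximum(rad, 1.0) ** 0.25

    return _iterate(update, tk, _L.convergence, _L.max_iter)


def _natural_wetbulb(tk, rh_frac, p_hpa, speed, solar, fdir, cza):
    tsfc = tk
    ea = _emissivity_atm(tk, rh_frac)
    eair = rh_frac * _esat_lil(tk)
    sza = np.arccos(np.clip(cza, -1.0, 1.0))
    aspect = 0.25 * _L.wick_diameter / _L.wick_length
    solar_term = (1.0 - _L.wick_albedo) * solar * (
        (1.0 - fdir) * (1.0 + aspect)
        + fdir * (np.tan(sza) / np.pi + aspect)
        + _L.surface_albedo
    )

    def update(tw):
        tref = 0.5 * (tw + tk)
        h = _h_cylinder(tref, p_hpa, speed)
        f_atm = c.STEFAN_BOLTZMANN * _L.wick_emissivity * (
            0.5 * (ea * tk**4 + _L.surface_emissivity * tsfc**4) - tw**4
        ) + solar_term
        ewick = _esat_lil(tw)
        schmidt = _viscosity(tref) / (
            (p_hpa * 100.0 / (_L.r_air * tref)) * _diffusivity(tref, p_hpa)
        )
        return tk - _heat_of_evaporation(tref) / _L.ratio \
            * (ewick - eair) / (p_hpa - ewick) \
            * (_L.prandtl / schmidt) ** 0.56 + f_atm / h

    return _iterate(update, _dewpoint_lil(eair), _L.convergence, _L.max_iter)


def wbgt_liljegren(ta_c, rh_pct, ps_pa, u10, ghi, f_dir, cos_zenith):
    """Liljegren natural wet-bulb, globe temperature and WBGT [degC].

    Parameters: air temperature [degC], relative humidity [%] (clipped to
    0-100), surface pressure [Pa], 10 m wind speed [m/s] (converted to the
    2 m instrument height internally), global horizontal irradiance [W/m2],
    direct-beam fraction, and cos(solar zenith) with nighttime encoded by a
    small negative sentinel.

    Returns ``(tw, tg, wbgt)``; elements where either balance failed to
    converge are NaN.
    """
    tk = np.asarray(ta_c, dtype=float) + c.ZERO_C_IN_K
    rh = np.clip(np.asarray(rh_pct, dtype=float), 0.0, 100.0) / 100.0
    p_hpa = np.asarray(ps_pa, dtype=float) / 100.0
    solar = np.clip(np.asarray(ghi, dtype=float), 0.0, None)
    fdir = np.asarray(f_dir, dtype=float)
    cza = np.asarray(cos_zenith, dtype=float)
    tk, rh, p_hpa, u10b, solar, fdir, cza = np.broadcast_arrays(
        tk, rh, p_hpa, np.asarray(u10, dtype=float), solar, fdir, cza
    )

    # Sun effectively below the horizon: no solar load, and the direct-beam
    # geometry (1/cos terms) must not blow up.
    night = cza < c.MIN_COS_ZENITH
    solar = np.where(night, 0.0, solar)
    fdir = np.where(night | (solar <= 1.0), 0.0, fdir)
    cza_safe = np.where(night, 1.0, cza)

    speed = wind_to_reference_height(u10b, solar)

    tg_k = _globe_temperature(tk, rh, p_hpa, speed, solar, fdir, cza_safe)
    tw_k = _natural_wetbulb(tk, rh, p_hpa, speed, solar, fdir, cza_safe)

    tw = tw_k - c.ZERO_C_IN_K
    tg = tg_k - c.ZERO_C_IN_K
    ta = tk - c.ZERO_C_IN_K
    return tw, tg, 0.7 * tw + 0.2 * tg + 0.1 * ta


# ---------------------------------------------------------------------------
# Mean radiant temperature
# ---------------------------------------------------------------------------

def projected_area_fraction(elevation_deg):
    """Projected-area fraction of a standing person vs solar elevation [deg]."""
    g = np.asarray(elevation_deg, dtype=float)
    return 0.308 * np.cos(np.radians(g * (0.998 - g * g / 50000.0)))


def mean_radiant_temperature(ghi, net_shortwave, dni, dni_horizontal, ldown, lnet, cos_zenith):
    """Mean radiant temperature [degC] from shortwave and longwave fluxes.

    Inputs [W/m2]: global horizontal irradiance, net shortwave
    ((1 - albedo) * GHI), direct normal irradiance and its horizontal
    projection (DNI * cos zenith), downwelling longwave, and net longwave
    (down - up convention).  ``cos_zenith`` is truncated at zero; negative
    shortwave fluxes are set to zero.
    """
    csza = np.clip(np.asarray(cos_zenith, dtype=float), 0.0, 1.0)
    g = np.clip(np.asarray(ghi, dtype=float), 0.0, None)
    nsw = np.clip(np.asarray(net_shortwave, dtype=float), 0.0, None)
    dni_ = np.clip(np.asarray(dni, dtype=float), 0.0, None)
    dni_h = np.clip(np.asarray(dni_horizontal, dtype=float), 0.0, None)
    ldn = np.asarray(ldown, dtype=float)
    lup = ldn - np.asarray(lnet, dtype=float)   # surface-emitted longwave

    diffuse = np.clip(g - dni_h, 0.0, None)
    reflected = np.clip(g - nsw, 0.0, None)
    fp = projected_area_fraction(np.degrees(np.arcsin(csza)))
    direct = np.where(csza > 0.0, fp * dni_, 0.0)

    absorbed = (
        c.MRT_VIEW_FACTOR_SKY * ldn
        + c.MRT_VIEW_FACTOR_GROUND * lup
        + (c.MRT_SHORTWAVE_ABSORPTION / c.MRT_LONGWAVE_EMISSIVITY)
        * (c.MRT_VIEW_FACTOR_SKY * diffuse + c.MRT_VIEW_FACTOR_GROUND * reflected + direct)
    )
    tmrt_k = np.clip(absorbed / c.STEFAN_BOLTZMANN, 0.0, None) ** 0.25
    return tmrt_k - c.ZERO_C_IN_K


# ---------------------------------------------------------------------------
# UTCI
# ---------------------------------------------------------------------------

def utci_polynomial(ta_c, va, d_tmrt, pa_kpa):
    """Raw sixth-order UTCI polynomial [degC]; no validity masking."""
    ta = np.asarray(ta_c, dtype=float)
    v = np.asarray(va, dtype=float)
    d = np.asarray(d_tmrt, dtype=float)
    p = np.asarray(pa_kpa, dtype=float)
    ta, v, d, p = np.broadcast_arrays(ta, v, d, p)
    # power tables up to degree 6
    pw = {
        "ta": [np.ones_like(ta)], "va": [np.ones_like(v)],
        "d": [np.ones_like(d)], "pa": [np.ones_like(p)],
    }
    for name, base in (("ta", ta), ("va", v), ("d", d), ("pa", p)):
        for _ in range(6):
            pw[name].append(pw[name][-1] * base)
    offset = np.zeros_like(ta)
    for i, j, k, l, coeff in UTCI_POLYNOMIAL:
        offset += coeff * pw["ta"][i] * pw["va"][j] * pw["d"][k] * pw["pa"][l]
    return ta + offset


def utci(ta_c, u10, tmrt_c, e_hpa):
    """UTCI [degC], NaN outside the published validity domain.

    Valid where -50 <= Ta <= 50 degC, -30 <= Tmrt - Ta <= 70 degC,
    RH > 5 % (evaluated on the clipped RH), e < 50 hPa, and
    0.5 <= U10 <= 17 m/s; non-finite inputs propagate NaN.
    """
    ta = np.asarray(ta_c, dtype=float)
    v = np.asarray(u10, dtype=float)
    tm = np.asarray(tmrt_c, dtype=float)
    e = np.asarray(e_hpa, dtype=float)
    ta, v, tm, e = np.broadcast_arrays(ta, v, tm, e)
    d = tm - ta
    with np.errstate(invalid="ignore", divide="ignore"):
        rh = np.clip(100.0 * e / saturation_vapor_pressure(ta), 0.0, 100.0)
        valid = (
            np.isfinite(ta) & np.isfinite(v) & np.isfinite(tm) & np.isfinite(e)
            & (ta >= c.UTCI_TA_MIN) & (ta <= c.UTCI_TA_MAX)
            & (d >= c.UTCI_DTMRT_MIN) & (d <= c.UTCI_DTMRT_MAX)
            & (rh > c.UTCI_RH_MIN) & (e < c.UTCI_E_MAX)
            & (v >= c.UTCI_WIND_MIN) & (v <= c.UTCI_WIND_MAX)
        )
    out = np.full(ta.shape, np.nan)
    if np.any(valid):
        out[valid] = utci_polynomial(ta[valid], v[valid], d[valid], e[valid] / 10.0)
    return out
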