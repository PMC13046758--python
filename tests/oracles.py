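"""Independent scalar reference implementations used as test oracles.

Each function here is a direct, loop-based transcription of the published
algorithm it checks (NWS heat-index procedure, Liljegren WBGT energy
balances, outdoor mean-radiant-temperature flux balance, UTCI polynomial)
or a brute-force restatement of a geometric operation.  They are written
with plain ``math`` scalars, deliberately sharing no code with the
vectorized package implementations.
"""

from __future__ import annotations

import math

# ---------------------------------------------------------------------------
# NWS heat index (Fahrenheit internally)
# ---------------------------------------------------------------------------

def nws_heat_index_c(ta_c: float, rh: float) -> float:
    t = ta_c * 9.0 / 5.0 + 32.0
    hi = 0.5 * (t + 61.0 + (t - 68.0) * 1.2 + rh * 0.094)
    if hi >= 80.0:
        hi = (
            -42.379 + 2.04901523 * t + 10.14333127 * rh
            - 0.22475541 * t * rh - 6.83783e-3 * t * t
            - 5.481717e-2 * rh * rh + 1.22874e-3 * t * t * rh
            + 8.5282e-4 * t * rh * rh - 1.99e-6 * t * t * rh * rh
        )
        if rh < 13.0 and 80.0 <= t <= 112.0:
            hi -= ((13.0 - rh) / 4.0) * math.sqrt((17.0 - abs(t - 95.0)) / 17.0)
        elif rh > 85.0 and 80.0 <= t <= 87.0:
            hi += ((rh - 85.0) / 10.0) * ((87.0 - t) / 2.0)
    return (hi - 32.0) * 5.0 / 9.0


# ---------------------------------------------------------------------------
# Liljegren WBGT components (Kelvin / hPa internally)
# ---------------------------------------------------------------------------

_CP = 1003.5
_MAIR = 28.97
_MH2O = 18.015
_RGAS = 8314.34
_RAIR = _RGAS / _MAIR
_PR = _CP / (_CP + 1.25 * _RAIR)
_RATIO = _CP * _MAIR / _MH2O
_SB = 5.670374419e-8
_EMIS_GLOBE, _ALB_GLOBE, _D_GLOBE = 0.95, 0.05, 0.0508
_EMIS_WICK, _ALB_WICK, _D_WICK, _L_WICK = 0.95, 0.4, 0.007, 0.0254
_EMIS_SFC, _ALB_SFC = 0.999, 0.45
_CONVERGENCE, _MAX_ITER = 0.02, 50


def _esat(tk: float) -> float:
    return 1.004 * 6.1121 * math.exp(17.502 * (tk - 273.15) / (tk - 32.18))


def _dewpoint(e: float) -> float:
    z = math.log(e / (1.004 * 6.1121))
    return 273.15 + 240.97 * z / (17.502 - z)


def _visc(tk: float) -> float:
    return 1.458e-6 * tk**1.5 / (tk + 110.4)


def _therm_cond(tk: float) -> float:
    return (_CP + 1.25 * _RAIR) * _visc(tk)


def _diffusivity(tk: float, p_hpa: float) -> float:
    pcrit13 = (36.4 * 218.0) ** (1.0 / 3.0)
    tcrit512 = (132.0 * 647.3) ** (5.0 / 12.0)
    tcrit12 = (132.0 * 647.3) ** 0.5
    mmix = (1.0 / _MAIR + 1.0 / _MH2O) ** 0.5
    return 3.640e-4 * (tk / tcrit12) ** 2.334 * pcrit13 * tcrit512 * mmix / (p_hpa / 1013.25) * 1e-4


def _evap(tk: float) -> float:
    return (313.15 - tk) / 30.0 * (-71100.0) + 2.4073e6


def _emis_atm(tk: float, rh_frac: float) -> float:
    return 0.575 * (rh_frac * _esat(tk)) ** 0.143


def _h_sphere(tk: float, p_hpa: float, speed: float) -> float:
    density = p_hpa * 100.0 / (_RAIR * tk)
    re = speed * density * _D_GLOBE / _visc(tk)
    nu = 2.0 + 0.6 * math.sqrt(re) * _PR ** (1.0 / 3.0)
    return nu * _therm_cond(tk) / _D_GLOBE


def _h_cylinder(tk: float, p_hpa: float, speed: float) -> float:
    a, cexp = 0.56, 0.4
    density = p_hpa * 100.0 / (_RAIR * tk)
    re = speed * density * _D_WICK / _visc(tk)
    nu = 0.281 * re ** (1.0 - cexp) * _PR ** (1.0 - a)
    return nu * _therm_cond(tk) / _D_WICK


def liljegren_globe_k(tk, rh_frac, p_hpa, speed, solar, fdir, cza) -> float:
    tsfc = tk
    prev = tk
    for _ in range(_MAX_ITER):
        tref = 0.5 * (prev + tk)
        h = _h_sphere(tref, p_hpa, speed)
        rad = (
            0.5 * (_emis_atm(tk, rh_frac) * tk**4 + _EMIS_SFC * tsfc**4)
            - h / (_SB * _EMIS_GLOBE) * (prev - tk)
            + solar / (2.0 * _SB * _EMIS_GLOBE) * (1.0 - _ALB_GLOBE)
            * (fdir * (1.0 / (2.0 * cza) - 1.0) + 1.0 + _ALB_SFC)
        )
        new = max(rad, 1.0) ** 0.25
        if abs(new - prev) < _CONVERGENCE:
            return new
        prev = 0.9 * prev + 0.1 * new
    return float("nan")


def liljegren_wetbulb_k(tk, rh_frac, p_hpa, speed, solar, fdir, cza) -> float:
    tsfc = tk
    eair = rh_frac * _esat(tk)
    sza = math.acos(max(-1.0, min(1.0, cza)))
    aspect = 0.25 * _D_WICK / _L_WICK
    prev = _dewpoint(eair)
    for _ in range(_MAX_ITER):
        tref = 0.5 * (prev + tk)
        h = _h_cylinder(tref, p_hpa, speed)
        f_atm = _SB * _EMIS_WICK * (
            0.5 * (_emis_atm(tk, rh_frac) * tk**4 + _EMIS_SFC * tsfc**4) - prev**4
        ) + (1.0 - _ALB_WICK) * solar * (
            (1.0 - fdir) * (1.0 + aspect)
            + fdir * (math.tan(sza) / math.pi + aspect)
            + _ALB_SFC
        )
        ewick = _esat(prev)
        density = p_hpa * 100.0 / (_RAIR * tref)
        sc = _visc(tref) / (density * _diffusivity(tref, p_hpa))
        new = (
            tk - _evap(tref) / _RATIO * (ewick - eair) / (p_hpa - ewick)
            * (_PR / sc) ** 0.56 + f_atm / h
        )
        if abs(new - prev) < _CONVERGENCE:
            return new
        prev = 0.9 * prev + 0.1 * new
    return float("nan")


_DAY_TABLE = [
    [1, 1, 2, 4],
    [1, 2, 3, 4],
    [2, 2, 3, 4],
    [3, 3, 4, 4],
    [3, 4, 4, 4],
]
_RURAL_EXP = [0.07, 0.07, 0.10, 0.15, 0.35, 0.55]


def wind_2m_reference(u10: float, solar: float) -> float:
    """Scalar 10 m -> 2 m wind estimate via rural stability-class power law."""
    if solar > 0:
        if u10 < 2.0:
            i = 0
        elif u10 < 3.0:
            i = 1
        elif u10 < 5.0:
            i = 2
        elif u10 < 6.0:
            i = 3
        else:
            i = 4
        if solar >= 925.0:
            j = 0
        elif solar >= 675.0:
            j = 1
        elif solar >= 175.0:
            j = 2
        else:
            j = 3
        sclass = _DAY_TABLE[i][j]
    else:
        sclass = 6 if u10 < 2.0 else (5 if u10 < 2.5 else 4)
    return max(u10 * (2.0 / 10.0) ** _RURAL_EXP[sclass - 1], 0.13)


def liljegren_reference_c(ta_c, rh_pct, ps_pa, speed_2m, ghi, fdir, cza):
    """(Tw, Tg) degC for 2 m wind speed; night encoded by cza < cos(89.5deg)."""
    tk = ta_c + 273.15
    rh = min(max(rh_pct, 0.0), 100.0) / 100.0
    p = ps_pa / 100.0
    if cza < 0.00872:
        solar, fd, cz = 0.0, 0.0, 1.0
    else:
        solar, fd, cz = max(ghi, 0.0), (fdir if ghi > 1.0 else 0.0), cza
    speed = max(speed_2m, 0.13)
    tg = liljegren_globe_k(tk, rh, p, speed, solar, fd, cz) - 273.15
    tw = liljegren_wetbulb_k(tk, rh, p, speed, solar, fd, cz) - 273.15
    return tw, tg


# ---------------------------------------------------------------------------
# mean radiant temperature
# ---------------------------------------------------------------------------

def mrt_reference_c(ghi, net_sw, dni, dni_h, ldown, lnet, cza) -> float:
    cz = max(0.0, min(1.0, cza))
    g = max(ghi, 0.0)
    diffuse = max(g - max(dni_h, 0.0), 0.0)
    reflected = max(g - max(net_sw, 0.0), 0.0)
    lup = ldown - lnet
    gamma = math.degrees(math.asin(cz))
    fp = 0.308 * math.cos(math.radians(gamma * (0.998 - gamma * gamma / 50000.0)))
    direct = fp * max(dni, 0.0) if cz > 0 else 0.0
    total = 0.5 * ldown + 0.5 * lup + (0.7 / 0.97) * (0.5 * diffuse + 0.5 * reflected + direct)
    return max(total / 5.670374419e-8, 0.0) ** 0.25 - 273.15


# ---------------------------------------------------------------------------
# UTCI polynomial (scalar evaluation of the published coefficient table)
# ---------------------------------------------------------------------------

def utci_reference_c(ta_c, va, tmrt_c, e_hpa) -> float:
    # The coefficient table is the published polynomial itself; this scalar
    # fsum evaluation is machinery-independent of the package's vectorized
    # power-table accumulation.
    from heattract._utci_coeffs import UTCI_POLYNOMIAL

    d = tmrt_c - ta_c
    pa = e_hpa / 10.0
    terms = [
        coeff * ta_c**i * va**j * d**k * pa**l
        for i, j, k, l, coeff in UTCI_POLYNOMIAL
    ]
    return ta_c + math.fsum(terms)


# ---------------------------------------------------------------------------
# geometric brute forces
# ---------------------------------------------------------------------------

def nearest_brute(target_xy, source_xy):
    """Index of the nearest source for each target, lowest index on ties."""
    out = []
    for tx, ty in target_xy:
        best, best_d = 0, float("inf")
        for si, (sx, sy) in enumerate(source_xy):
            dd = (tx - sx) ** 2 + (ty - sy) ** 2
            if dd < best_d - 1e-12:
                best, best_d = si, dd
        out.append(best)
    return out


def idw_brute(source_xy, values, target_xy, cutoff, k=4, power=2.0):
    """Exhaustive k-nearest cutoff IDW with NaN-neighbor exclusion."""
    out = []
    for tx, ty in target_xy:
        dists = sorted(
            (math.hypot(tx - sx, ty - sy), si)
            for si, (sx, sy) in enumerate(source_xy)
        )
        neighbors = [(d, si) for d, si in dists[:k] if d <= cutoff]
        num = den = 0.0
        exact = None
        for d, si in neighbors:
            v = values[si]
            if v != v:  # NaN
                continue
            if d == 0.0 and exact is None:
                exact = v
            w = 1.0 / max(d, 1e-12) ** power
            num += w * v
            den += w
        if exact is not None:
            out.append(exact)
        elif den == 0.0:
            out.append(float("nan"))
        else:
            out.append(num / den)
    return out
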