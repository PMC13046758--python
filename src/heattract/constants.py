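"""Physical constants and model parameter tables.

Every hard-coded coefficient used by the thermodynamic and radiative models
lives here so a single table documents the model configuration.  Values are
grouped by the component that consumes them.
"""

from __future__ import annotations

from dataclasses import dataclass

# --- general physical constants -------------------------------------------

#: Standard gravitational acceleration [m s-2].
GRAVITY = 9.80665
#: Specific gas constant of dry air [J kg-1 K-1].
R_DRY_AIR = 287.05
#: Stefan-Boltzmann constant [W m-2 K-4].
STEFAN_BOLTZMANN = 5.670374419e-8
#: Conversion offset between Celsius and Kelvin.
ZERO_C_IN_K = 273.15

# --- Buck saturation vapor pressure (over water) --------------------------
# es(T) = BUCK_A * exp((BUCK_B - T/BUCK_D) * T / (BUCK_C + T))   [hPa, T in degC]
# Arden Buck's 1996 over-water curve; the variant in use is recorded in run
# metadata so it can be swapped if a different fit is preferred.

BUCK_VARIANT = "buck-1996-water"
BUCK_A = 6.1121
BUCK_B = 18.678
BUCK_C = 257.14
BUCK_D = 234.5

# --- solar geometry --------------------------------------------------------

#: Sentinel substituted for cos(zenith) at night so the globe-temperature
#: solver sees an unambiguous "sun below horizon" flag.  Configurable.
NIGHT_COS_ZENITH_SENTINEL = -1.0e-4
#: cos(zenith) below this (sun within ~0.5 deg of the horizon) is treated as
#: nighttime for the direct-beam geometry to avoid a divergent 1/cos term.
MIN_COS_ZENITH = 0.00872  # cos(89.5 deg)

# --- Liljegren wet-bulb-globe model ---------------------------------------
# Geometry, radiative properties and thermodynamic constants of the standard
# WBGT instrument, as published with the Liljegren energy-balance model.


@dataclass(frozen=True)
class LiljegrenConstants:
    # thermodynamics
    cp: float = 1003.5           # specific heat of dry air [J kg-1 K-1]
    m_air: float = 28.97         # molecular weight of dry air [g mol-1]
    m_h2o: float = 18.015        # molecular weight of water [g mol-1]
    r_gas: float = 8314.34       # universal gas constant [J kmol-1 K-1]
    # globe sensor
    globe_diameter: float = 0.0508   # [m]
    globe_emissivity: float = 0.95
    globe_albedo: float = 0.05
    # wick sensor
    wick_diameter: float = 0.007     # [m]
    wick_length: float = 0.0254      # [m]
    wick_emissivity: float = 0.95
    wick_albedo: float = 0.4
    # ground surface
    surface_emissivity: float = 0.999
    surface_albedo: float = 0.45
    # numerics
    convergence: float = 0.02        # fixed-point tolerance [K]
    max_iter: int = 50
    min_speed: float = 0.13          # anemometer stall speed [m s-1]
    wind_ref_height: float = 2.0     # height the model's correlations expect [m]

    @property
    def r_air(self) -> float:
        return self.r_gas / self.m_air

    @property
    def prandtl(self) -> float:
        return self.cp / (self.cp + 1.25 * self.r_air)

    @property
    def ratio(self) -> float:
        # cp * M_air / M_h2o, used in the evaporative term of the wick balance
        return self.cp * self.m_air / self.m_h2o


LILJEGREN = LiljegrenConstants()

# Wind-profile power-law exponents by Pasquill stability class (1..6),
# rural terrain, used to move 10 m wind to the 2 m instrument height.
WIND_EXPONENT_RURAL = (0.07, 0.07, 0.10, 0.15, 0.35, 0.55)

# --- mean radiant temperature ---------------------------------------------
# Coefficients of the operational outdoor MRT flux balance for a standing
# person: half view factors to sky and ground, shortwave absorption and
# longwave emissivity of the body, and the projected-area fraction fit
# fp(gamma) = 0.308 * cos(gamma * (0.998 - gamma^2 / 50000)), gamma the solar
# elevation in degrees.

MRT_SHORTWAVE_ABSORPTION = 0.7
MRT_LONGWAVE_EMISSIVITY = 0.97
MRT_VIEW_FACTOR_SKY = 0.5
MRT_VIEW_FACTOR_GROUND = 0.5

# --- UTCI validity domain --------------------------------------------------

UTCI_TA_MIN = -50.0     # [degC]
UTCI_TA_MAX = 50.0      # [degC]
UTCI_DTMRT_MIN = -30.0  # [degC]
UTCI_DTMRT_MAX = 70.0   # [degC]
UTCI_RH_MIN = 5.0       # [%]  valid strictly above
UTCI_E_MAX = 50.0       # [hPa] valid strictly below
UTCI_WIND_MIN = 0.5     # [m s-1]
UTCI_WIND_MAX = 17.0    # [m s-1]
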