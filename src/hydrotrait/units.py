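"""Physical constants and unit conversions shared across the pipeline.

The package uses one canonical unit system throughout: vapour pressure
deficit ``D`` in kPa, stomatal conductance ``gs`` in mol m-2 s-1, sap flux
density ``Js`` in cm h-1 (volumetric water flux per unit sapwood area),
Huber value ``Hv`` in cm2 cm-2 and water potential in MPa.  Every factor
that maps between these units and SI lives in this module so no other
module hard-codes a conversion.
"""

from __future__ import annotations

import numpy as np

#: Universal gas constant, J mol-1 K-1.
R_GAS = 8.31446

#: Specific gas constant of dry air, J kg-1 K-1.
R_DRY_AIR = 287.058

#: Heat capacity of air at constant pressure, J kg-1 K-1.
CP_AIR = 1013.0

#: Ratio of molecular weights, water vapour over dry air.
EPSILON = 0.622

#: Density of liquid water at 20 degC, kg m-3.
WATER_DENSITY_20C = 998.2

#: Dynamic viscosity of water at 20 degC, MPa s.
WATER_VISCOSITY_20C = 1.002e-9

#: Celsius to Kelvin offset.
KELVIN = 273.15

#: cm h-1 (liquid water column) to m s-1.
CM_PER_H_TO_M_PER_S = 0.01 / 3600.0

#: mm h-1 to cm h-1.
MM_PER_H_TO_CM_PER_H = 0.1

#: Square micrometres to square metres.
UM2_TO_M2 = 1e-12

#: Micrometres to metres.
UM_TO_M = 1e-6

#: Per-mm2 counts to per-m2.
PER_MM2_TO_PER_M2 = 1e6

#: mm2 to m2.
MM2_TO_M2 = 1e-6


def saturation_vapour_pressure(t_c):
    """Saturation vapour pressure (kPa) at air temperature ``t_c`` (degC).

    Tetens formula: ``es = 0.6108 * exp(17.27 T / (T + 237.3))``.
    """
    t_c = np.asarray(t_c, dtype=float)
    return 0.6108 * np.exp(17.27 * t_c / (t_c + 237.3))


def latent_heat_vaporization(t_c: float) -> float:
    """Latent heat of vaporization of water, J kg-1, at ``t_c`` degC."""
    return (2.501 - 2.361e-3 * t_c) * 1e6


def psychrometric_constant(t_c: float, pressure_kpa: float) -> float:
    """Psychrometric constant gamma, kPa K-1, at (T, P)."""
    return CP_AIR * pressure_kpa / (EPSILON * latent_heat_vaporization(t_c))


def air_density(t_c: float, pressure_kpa: float) -> float:
    """Dry-air density, kg m-3, from the ideal gas law at (T, P)."""
    return pressure_kpa * 1000.0 / (R_DRY_AIR * (t_c + KELVIN))


def molar_volume_air(t_c: float, pressure_kpa: float) -> float:
    """Molar volume of air, m3 mol-1, from the ideal gas law at (T, P)."""
    return R_GAS * (t_c + KELVIN) / (pressure_kpa * 1000.0)
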