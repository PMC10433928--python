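"""Anatomical and functional hydraulic traits.

Implements the trait calculators used across the pipeline:

* theoretical maximum stomatal conductance from stomatal density and pore
  geometry (anatomical upper bound on gs);
* theoretical specific hydraulic conductivity of a xylem transect from
  the Hagen-Poiseuille law (fourth power of vessel diameters);
* whole-plant hydraulic conductance from gas exchange and the pre-dawn
  to midday water-potential drawdown;
* Huber value (sapwood area per unit leaf area) with leaf area estimated
  through a log-log branch-diameter allometry;
* leaf vein density, the gs reduction at the flux optimum, and the
  Jsmax/gsmax ratio (the functional analogue of the Huber value).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import units

__all__ = [
    "StomatalAnatomy",
    "VesselTransect",
    "AllometryModel",
    "TreeTraitRecord",
    "default_pore_depth_um",
    "diffusive_gsmax",
    "theoretical_gsmax",
    "hagen_poiseuille_ks",
    "kplant",
    "huber_value",
    "allometry_fit",
    "allometry_predict",
    "gs_reduction",
    "jsmax_over_gsmax",
    "vein_density",
]


@dataclass(frozen=True)
class StomatalAnatomy:
    """Stomatal census of one leaf side (abaxial unless amphistomatous).

    ``d`` and ``v`` are configuration with defaults at 25 degC, not
    hard-wired constants: the diffusivity of water vapour in air
    (m2 s-1) and the molar volume of air (m3 mol-1).
    """

    n_sto_mm2: float          # stomatal density, mm-2
    size_um2: float           # stomatal size S = length x width, um2
    amax_um2: float           # mean maximum pore area, um2
    d_m2_s: float = 2.49e-5
    v_m3_mol: float = 0.0245
    amphistomatous: bool = False

    def __post_init__(self):
        if self.n_sto_mm2 < 0:
            raise ValueError("stomatal density cannot be negative")
        if self.size_um2 <= 0 or self.amax_um2 <= 0:
            raise ValueError("stomatal size and pore area must be positive")
        if self.d_m2_s <= 0 or self.v_m3_mol <= 0:
            raise ValueError("d and v must be positive")
        if not self.alpha < 1:
            raise ValueError(
                f"pore-area fraction alpha = {self.alpha:.3f} must be < 1")

    @property
    def alpha(self) -> float:
        """Pore area as a fraction of stomatal size, amax/S."""
        return self.amax_um2 / self.size_um2


def default_pore_depth_um(anatomy: StomatalAnatomy) -> float:
    """Stomatal pore depth (um) derived from stomatal size.

    Pore depth is taken as half the guard-cell width, with width obtained
    from ``S = length x width`` under the usual ``length ~ 2 x width``
    proportion: ``pd = 0.5 * sqrt(S / 2)``.
    """
    return 0.5 * math.sqrt(anatomy.size_um2 / 2.0)


def diffusive_gsmax(anatomy: StomatalAnatomy,
                    pore_depth_um: Callable[[StomatalAnatomy], float]
                    = default_pore_depth_um) -> float:
    """Canonical diffusion form of the anatomical maximum conductance.

        gsmax = d * n * amax / (v * (pd + (pi/2) sqrt(amax/pi)))

    with ``n`` the stomatal density, ``amax`` the mean maximum pore area,
    ``pd`` the pore depth and the second denominator term the end
    correction of the diffusion pathway.  Returns mol m-2 s-1.
    """
    n_m2 = anatomy.n_sto_mm2 * units.PER_MM2_TO_PER_M2
    amax_m2 = anatomy.amax_um2 * units.UM2_TO_M2
    depth_m = (pore_depth_um(anatomy) * units.UM_TO_M
               + (math.pi / 2.0) * math.sqrt(amax_m2 / math.pi))
    return anatomy.d_m2_s * n_m2 * amax_m2 / (anatomy.v_m3_mol * depth_m)


def theoretical_gsmax(anatomy: StomatalAnatomy,
                      formula: Callable[[StomatalAnatomy], float]
                      = diffusive_gsmax) -> float:
    """Anatomical maximum stomatal conductance, mol m-2 s-1.

    The algebraic arrangement is a swappable formula object; the default
    is :func:`diffusive_gsmax`.  Stomata are assumed confined to the
    abaxial side; set ``amphistomatous=True`` on the anatomy record and
    pass combined densities for two-sided leaves.  Zero density returns
    zero conductance.
    """
    if anatomy.n_sto_mm2 == 0:
        return 0.0
    return formula(anatomy)


@dataclass(frozen=True)
class VesselTransect:
    """All vessel equivalent diameters within one branch transect."""

    diameters_um: np.ndarray
    area_mm2: float
    rho_kg_m3: float = units.WATER_DENSITY_20C
    eta_mpa_s: float = units.WATER_VISCOSITY_20C

    def __post_init__(self):
        object.__setattr__(self, "diameters_um",
                           np.asarray(self.diameters_um, dtype=float))
        if self.diameters_um.size == 0:
            raise ValueError("vessel list is empty")
        if np.any(self.diameters_um <= 0):
            raise ValueError("vessel diameters must be positive")
        if self.area_mm2 <= 0:
            raise ValueError("transect area must be positive")


def hagen_poiseuille_ks(transect: VesselTransect) -> float:
    """Theoretical specific conductivity ks, kg m-1 MPa-1 s-1.

        ks = (pi * rho / (128 * eta * A)) * sum(d_i^4)

    with water density and viscosity at 20 degC, transect area ``A`` and
    vessel equivalent diameters ``d_i``.
    """
    d_m = transect.diameters_um * units.UM_TO_M
    a_m2 = transect.area_mm2 * units.MM2_TO_M2
    return (math.pi * transect.rho_kg_m3
            / (128.0 * transect.eta_mpa_s * a_m2)) * float(np.sum(d_m ** 4))


def kplant(gs: float, d_kpa: float, psi_pd_mpa: float,
           psi_min_mpa: float) -> float:
    """Whole-plant hydraulic conductance, mol m-2 s-1 MPa-1.

        Kplant = gs * D / (psi_pd - psi_min)

    ``gs`` must be the conductance measured at the same time of day as
    the minimum water potential.  The numeric convention keeps D in kPa
    and the water-potential drawdown in MPa, matching how the field
    values are reported.
    """
    if psi_pd_mpa == psi_min_mpa:
        raise ZeroDivisionError("psi_pd equals psi_min; drawdown is zero")
    if psi_pd_mpa < psi_min_mpa:
        raise ValueError("inverted gradient: psi_pd < psi_min")
    return gs * d_kpa / (psi_pd_mpa - psi_min_mpa)


def huber_value(sapwood_area_cm2: float, leaf_area_cm2: float) -> float:
    """Huber value Hv = sapwood area / supplied leaf area, cm2 cm-2."""
    if leaf_area_cm2 <= 0:
        raise ValueError("leaf area must be positive")
    if sapwood_area_cm2 <= 0:
        raise ValueError("sapwood area must be positive")
    return sapwood_area_cm2 / leaf_area_cm2


@dataclass(frozen=True)
class AllometryModel:
    """Power-law branch allometry fit on the log-log scale.

    ``ln(leaf area) = c0 + c1 ln(diameter)``; ``diam_range_mm`` is the
    diameter range of the fitted branches — predictions outside it are
    extrapolations and always flagged as such.
    """

    c0: float
    c1: float
    r2: float
    n: int
    diam_range_mm: tuple[float, float]


def allometry_fit(diameters_mm, leaf_areas_cm2) -> AllometryModel:
    """OLS of ln(leaf area) on ln(branch diameter)."""
    d = np.asarray(diameters_mm, dtype=float)
    la = np.asarray(leaf_areas_cm2, dtype=float)
    if d.size != la.size:
        raise ValueError("diameters and leaf areas must pair up")
    if d.size < 3:
        raise ValueError("allometry fit needs at least 3 branches")
    if np.any(d <= 0) or np.any(la <= 0):
        raise ValueError("diameters and leaf areas must be positive")
    x = np.log(d)
    y = np.log(la)
    if np.ptp(x) == 0:
        raise ValueError("all branch diameters identical")
    design = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / sst if sst > 0 else -np.inf
    return AllometryModel(float(beta[0]), float(beta[1]), r2, d.size,
                          (float(d.min()), float(d.max())))


def allometry_predict(model: AllometryModel, diameter_mm):
    """Predict leaf area (cm2) from branch diameter (mm).

    Returns ``(leaf_area, extrapolated)``; ``extrapolated`` is True for
    diameters outside the fitted range (prediction still returned, as in
    the field procedure where wider branches had to be extrapolated).
    """
    d = np.asarray(diameter_mm, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    la = np.exp(model.c0 + model.c1 * np.log(d))
    lo, hi = model.diam_range_mm
    extrapolated = (d < lo) | (d > hi)
    if np.isscalar(diameter_mm):
        return float(la), bool(extrapolated)
    return la, extrapolated


def gs_reduction(gs_at_djsmax: float, measured_gsmax: float) -> float:
    """Fractional gs remaining at the sap-flux optimum.

    Ratio of gs at D_Jsmax to the measured maximum gs; values above 1
    (sampling noise) are clipped to 1 with a warning.
    """
    if measured_gsmax <= 0:
        raise ValueError("measured gsmax must be positive")
    if gs_at_djsmax < 0:
        raise ValueError("gs at D_Jsmax cannot be negative")
    ratio = gs_at_djsmax / measured_gsmax
    if ratio > 1.0:
        warnings.warn(f"gs reduction {ratio:.3f} > 1 clipped to 1 "
                      "(sampling noise)")
        ratio = 1.0
    return ratio


def jsmax_over_gsmax(jsmax_cm_h: float, measured_gsmax: float) -> float:
    """Jsmax/gsmax ratio, (cm h-1) / (mol m-2 s-1).

    The functional analogue of the Huber value: both extrema come from
    the same tree's measurement days though not necessarily the same
    instant.
    """
    if measured_gsmax <= 0:
        raise ValueError("measured gsmax must be positive")
    return jsmax_cm_h / measured_gsmax


def vein_density(total_vein_length_mm: float, leaf_area_mm2: float) -> float:
    """Vein length per unit leaf area, mm mm-2 (major first vein excluded
    upstream)."""
    if leaf_area_mm2 <= 0:
        raise ValueError("leaf area must be positive")
    if total_vein_length_mm < 0:
        raise ValueError("vein length cannot be negative")
    return total_vein_length_mm / leaf_area_mm2


@dataclass
class TreeTraitRecord:
    """Bundle of per-tree anatomical and functional traits."""

    tree_id: str
    species: str = ""
    hv: float = np.nan                   # cm2 cm-2
    hv_extrapolated: bool = False
    theoretical_gsmax: float = np.nan    # mol m-2 s-1
    measured_gsmax: float = np.nan       # mol m-2 s-1
    ks: float = np.nan                   # kg m-1 MPa-1 s-1
    kplant: float = np.nan               # mol m-2 s-1 MPa-1
    vein_density: float = np.nan         # mm mm-2
    jsmax_over_gsmax: float = np.nan     # (cm h-1)/(mol m-2 s-1)
    gs_reduction: float = np.nan
    extra: dict = field(default_factory=dict)
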