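"""Mechanistic trait-based stomatal-conductance model.

For a canopy tightly coupled to the atmosphere, inverting the simplified
Penman-Monteith equation gives stomatal conductance as

    gs = (lambda * gamma / (rho_air * Cp)) * E / D

where ``E`` is transpiration per unit leaf area and ``D`` the vapour
pressure deficit.  Transpiration can be estimated from sap flux density
``Js`` (per unit sapwood area) via the Huber value ``Hv`` (sapwood area /
leaf area), ``E = Js * Hv``, which yields the trait-based model

    gs = C * Hv * Js / D

with a single constant ``C`` shared by all species.  This module computes
``C`` (with the unit conversions that map Js in cm h-1 and D in kPa onto
gs in mol m-2 s-1), calibrates empirical per-tree gs vs Js/D
relationships, predicts continuous gs series, and regresses calibration
slopes on Hv across trees.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import units

logger = logging.getLogger(__name__)

__all__ = [
    "MechanisticConstant",
    "CalibrationFit",
    "RegressionSummary",
    "mechanistic_constant",
    "leaf_vpd",
    "pair_gs_to_flux",
    "calibrate",
    "predict_gs",
    "slope_vs_hv",
]


@dataclass(frozen=True)
class MechanisticConstant:
    """The constant factor of the inverted Penman-Monteith model.

    ``c`` is the physical constant lambda*gamma/(rho_air*Cp) in
    kPa m3 kg-1; ``js_to_gs`` additionally folds in the unit conversions
    (liquid-water density, cm h-1 -> m s-1, air molar volume) so that
    ``gs = js_to_gs * Hv * Js / D`` maps Js in cm h-1 and D in kPa
    directly onto gs in mol m-2 s-1.
    """

    lambda_j_kg: float
    gamma_kpa_k: float
    rho_air_kg_m3: float
    cp_j_kg_k: float
    tair_c: float
    pressure_kpa: float
    c: float
    js_to_gs: float
    audit: dict = field(default_factory=dict, compare=False)


def mechanistic_constant(tair_c: float = 25.0,
                         pressure_kpa: float = 101.325) -> MechanisticConstant:
    """Evaluate the model constant at a single reference (T, P).

    All four constituents are temperature dependent but are treated as
    constant over a campaign compared with the dynamic range of Js and D.

    Parameters
    ----------
    tair_c:
        Reference air temperature, degC.
    pressure_kpa:
        Atmospheric pressure, kPa.
    """
    if not (-40.0 < tair_c < 60.0) or not (50.0 < pressure_kpa < 110.0):
        raise ValueError(
            f"implausible reference state T={tair_c} degC, P={pressure_kpa} kPa")
    lam = units.latent_heat_vaporization(tair_c)
    gamma = units.psychrometric_constant(tair_c, pressure_kpa)
    rho_air = units.air_density(tair_c, pressure_kpa)
    cp = units.CP_AIR
    c = lam * gamma / (rho_air * cp)
    v_air = units.molar_volume_air(tair_c, pressure_kpa)
    js_to_gs = (c * units.WATER_DENSITY_20C * units.CM_PER_H_TO_M_PER_S
                / v_air)
    audit = {
        "lambda_J_kg": lam,
        "gamma_kPa_K": gamma,
        "rho_air_kg_m3": rho_air,
        "Cp_J_kg_K": cp,
        "C_kPa_m3_kg": c,
        "water_density_kg_m3": units.WATER_DENSITY_20C,
        "cm_h_to_m_s": units.CM_PER_H_TO_M_PER_S,
        "molar_volume_air_m3_mol": v_air,
        "js_to_gs_mol_m2_s_per_(cmh_over_kPa)": js_to_gs,
    }
    return MechanisticConstant(lam, gamma, rho_air, cp, tair_c, pressure_kpa,
                               c, js_to_gs, audit)


def leaf_vpd(tleaf_c, tair_c, rh):
    """Leaf-to-air vapour pressure deficit, kPa.

    ``D = es(Tleaf) - RH * es(Tair)``; using leaf temperature is a more
    precise estimate of the deficit driving leaf transpiration than the
    air-to-air D.  Where ``tleaf_c`` is missing (NaN) the air temperature
    is used instead (air-to-air D).  Negative results (supersaturation)
    are floored at zero with a warning.
    """
    tleaf_c = np.asarray(tleaf_c, dtype=float)
    tair_c = np.asarray(tair_c, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if np.any((rh <= 0) | (rh > 1)):
        raise ValueError("RH must lie in (0, 1]")
    tleaf_eff = np.where(np.isnan(tleaf_c), tair_c, tleaf_c)
    d = (units.saturation_vapour_pressure(tleaf_eff)
         - rh * units.saturation_vapour_pressure(tair_c))
    if np.any(d < 0):
        warnings.warn("negative leaf-to-air D floored at 0 kPa")
        d = np.maximum(d, 0.0)
    return d


@dataclass(frozen=True)
class CalibrationFit:
    """Per-tree OLS fit of gs on Js/D.

    Under the mechanistic model the slope estimates ``C * Hv`` for that
    tree.  ``slope`` carries units mol m-2 s-1 per (cm h-1 kPa-1) unless
    inputs were pre-harmonized.
    """

    tree_id: str
    slope: float
    intercept: float
    r2: float
    n: int
    pvalue: float

    def significant(self, alpha: float = 0.05) -> bool:
        return bool(self.pvalue < alpha)


@dataclass(frozen=True)
class RegressionSummary:
    """Simple-OLS summary used for cross-tree trait regressions."""

    slope: float
    intercept: float
    r2: float
    pvalue: float
    n: int


def pair_gs_to_flux(gs_df: pd.DataFrame, flux_df: pd.DataFrame,
                    tolerance: str = "15min") -> pd.DataFrame:
    """Match spot gs measurements to the half-hourly sap flux record.

    Nearest-timestamp join within ``tolerance``; unmatched gs rows are
    dropped and their count logged.  Both frames need a ``timestamp``
    column; ``flux_df`` needs ``Js_cm_per_h``.
    """
    gs_sorted = gs_df.sort_values("timestamp").reset_index(drop=True)
    flux_sorted = flux_df.sort_values("timestamp").reset_index(drop=True)
    merged = pd.merge_asof(gs_sorted, flux_sorted, on="timestamp",
                           direction="nearest",
                           tolerance=pd.Timedelta(tolerance))
    n_drop = int(merged["Js_cm_per_h"].isna().sum())
    if n_drop:
        logger.info("pair_gs_to_flux: dropped %d unmatched gs rows", n_drop)
    return merged.dropna(subset=["Js_cm_per_h"]).reset_index(drop=True)


def calibrate(gs, js, d, tree_id: str = "", *,
              intercept: bool = True) -> CalibrationFit:
    """Fit the empirical gs ~ Js/D calibration for one tree.

    Parameters
    ----------
    gs, js, d:
        Time-aligned morning samples of stomatal conductance
        (mol m-2 s-1), sap flux density (cm h-1) and vapour pressure
        deficit (kPa).
    intercept:
        Default fits ``gs = slope*(Js/D) + b`` (an empirical calibration
        equation); ``intercept=False`` forces the strict proportional
        form of the mechanistic model.

    The two-sided p-value of the slope comes from the t distribution of
    the OLS estimate.
    """
    gs = np.asarray(gs, dtype=float)
    js = np.asarray(js, dtype=float)
    d = np.asarray(d, dtype=float)
    if not (gs.shape == js.shape == d.shape):
        raise ValueError("gs, js, d must have identical shapes")
    if np.any(d <= 0):
        raise ValueError("D must be positive at all calibration samples")
    x = js / d
    n = x.size
    if n < 3:
        raise ValueError("calibration needs at least 3 samples")
    if not 10 <= n <= 100:
        warnings.warn(f"calibration n={n} outside the usual 10-100 band")
    if np.ptp(x) == 0:
        raise ValueError("Js/D has zero variance; calibration undefined")
    if intercept:
        res = stats.linregress(x, gs)
        return CalibrationFit(tree_id, float(res.slope), float(res.intercept),
                              float(res.rvalue ** 2), n, float(res.pvalue))
    # no-intercept OLS: slope = sum(xy)/sum(x^2); t-test with n-1 dof
    slope = float(np.dot(x, gs) / np.dot(x, x))
    resid = gs - slope * x
    dof = n - 1
    se = float(np.sqrt(np.sum(resid ** 2) / dof / np.dot(x, x)))
    tstat = slope / se if se > 0 else np.inf
    p = float(2 * stats.t.sf(abs(tstat), dof))
    sst = float(np.sum((gs - gs.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / sst if sst > 0 else np.nan
    return CalibrationFit(tree_id, slope, 0.0, r2, n, p)


def predict_gs(js, d, hv: float,
               constant: MechanisticConstant) -> np.ndarray:
    """Predict gs (mol m-2 s-1) pointwise from Js (cm h-1) and D (kPa).

    Rows with D == 0 are dropped (count logged); the caller keeps
    alignment through the returned mask when needed.
    """
    js = np.asarray(js, dtype=float)
    d = np.asarray(d, dtype=float)
    if hv <= 0:
        raise ValueError("Hv must be positive")
    keep = d > 0
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("predict_gs: dropped %d rows with D == 0", n_drop)
    out = np.full(js.shape, np.nan)
    out[keep] = constant.js_to_gs * hv * js[keep] / d[keep]
    return out


def slope_vs_hv(fits: list[CalibrationFit], hv_by_tree: dict[str, float],
                alpha: float = 0.05) -> RegressionSummary:
    """Regress calibration slopes on Hv across trees.

    Only trees whose calibration is statistically significant at
    ``alpha`` enter the regression, mirroring the inclusion rule used
    when testing whether the slope of gs-Js/D is set by Hv.
    """
    qualifying = [f for f in fits if f.significant(alpha)]
    if len(qualifying) < 3:
        raise ValueError(
            f"only {len(qualifying)} trees have significant calibrations; "
            "need at least 3")
    hv = np.array([hv_by_tree[f.tree_id] for f in qualifying])
    slopes = np.array([f.slope for f in qualifying])
    if np.ptp(hv) == 0:
        raise ValueError("no variance in Hv across qualifying trees")
    res = stats.linregress(hv, slopes)
    return RegressionSummary(float(res.slope), float(res.intercept),
                             float(res.rvalue ** 2), float(res.pvalue),
                             len(qualifying))
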