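"""Forward simulation of a multi-species sap-flow field campaign.

Generates, for N trees x S species with known ground-truth traits, the
full set of observables the analysis pipeline consumes: diurnal
microclimate (with vapour pressure deficit D rising along a truncated
sine from dawn to solar noon), spot stomatal conductance following the
log-linear decline ``gs = gsref - m ln(D)``, half-hourly sap flux density
obtained by inverting the mechanistic model ``gs = C Hv Js / D`` plus
Gaussian noise, pre-dawn/midday leaf water potentials consistent with the
whole-plant conductance definition, and the anatomical sample tables
(vessel transects, stomatal counts, branch diameter-leaf area pairs,
vein lengths).

Because every observable is generated from a stated closed form, each
downstream estimator has an exact parameter-recovery oracle: with all
noise at zero the calibration slope equals ``C * Hv_true``, the
water-potential inversion returns ``Kplant_true``, and the allometry
coefficients are recovered exactly.

All randomness flows from a single seed through per-(species, tree,
stage) spawned generators, so any sub-table can be regenerated
independently and the full campaign is byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import units
from .gs_model import mechanistic_constant

__all__ = [
    "SpeciesPreset",
    "SimulationConfig",
    "TreeTruth",
    "Campaign",
    "default_config",
    "tree_truth",
    "generate_diurnal",
    "generate_anatomy",
    "generate_tree_structure",
    "generate_water_potentials",
    "simulate_campaign",
]

# stage tags for seed spawning
_STAGE_DIURNAL = 1
_STAGE_ANATOMY = 2
_STAGE_TREE = 3
_STAGE_PSI = 4


@dataclass(frozen=True)
class SpeciesPreset:
    """Ground-truth trait bundle for one species.

    ``gsref`` is the stomatal conductance at D = 1 kPa and ``m`` the
    log-linear sensitivity, so the noise-free sap flux hump sits at
    ``D* = exp(gsref/m - 1)``.  Allometry coefficients are on natural
    logs: ``ln(leaf area cm2) = c0 + c1 ln(diameter mm)``.
    """

    name: str
    hv: float                    # cm2 cm-2
    gsref: float                 # mol m-2 s-1 at D = 1 kPa
    m: float                     # mol m-2 s-1 per ln(kPa)
    kplant: float                # mol m-2 s-1 MPa-1
    vessel_mu: float             # lognormal mu of diameters, ln(um)
    vessel_sigma: float          # lognormal sigma
    vessel_density_mm2: float
    stomatal_density_mm2: float
    stomatal_size_um2: float
    pore_fraction: float         # amax / S
    allom_c0: float
    allom_c1: float
    vein_density_mm_mm2: float

    def __post_init__(self):
        for name in ("hv", "gsref", "m", "kplant", "vessel_density_mm2",
                     "stomatal_density_mm2", "stomatal_size_um2",
                     "pore_fraction", "vein_density_mm_mm2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.name}: preset {name} must be "
                                 "strictly positive")

    @property
    def d_star(self) -> float:
        """Closed-form D (kPa) maximizing the noise-free flux curve."""
        return float(np.exp(self.gsref / self.m - 1.0))


def _preset(name, hv, gsref, d_jsmax, kplant, vessel_mu, vein):
    """Species preset with m chosen so the flux hump sits at d_jsmax."""
    return SpeciesPreset(
        name=name, hv=hv, gsref=gsref,
        m=gsref / (1.0 + np.log(d_jsmax)),
        kplant=kplant, vessel_mu=vessel_mu, vessel_sigma=0.30,
        vessel_density_mm2=80.0,
        stomatal_density_mm2={"almond": 420.0, "olive": 520.0,
                              "lemon": 340.0, "orange": 380.0,
                              "grapefruit": 360.0}[name],
        stomatal_size_um2=260.0, pore_fraction=0.12,
        allom_c0=1.5, allom_c1=2.0, vein_density_mm_mm2=vein)


#: Five presets spanning the study species: Huber value 1.2-3.83 x 1e-3
#: cm2 cm-2, gs at D=1 kPa 0.11-0.27 mol m-2 s-1, flux hump 2.88-4.85 kPa.
DEFAULT_SPECIES = (
    _preset("almond", 3.83e-3, 0.27, 4.85, 3.94, 3.40, 11.51),
    _preset("olive", 2.50e-3, 0.24, 4.28, 5.04, 3.20, 9.0),
    _preset("lemon", 1.20e-3, 0.11, 2.88, 1.25, 3.60, 6.0),
    _preset("orange", 1.80e-3, 0.15, 4.50, 2.50, 3.55, 7.0),
    _preset("grapefruit", 1.50e-3, 0.13, 3.90, 2.00, 3.70, 6.5),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Campaign design and noise model.

    Defaults mimic the field study: three clear measurement days, 30-min
    sap-flow cadence, hourly gas-exchange spot readings, four trees of
    each of five species, D ramping 0.1 to 4.5 kPa between dawn and
    solar noon.  Noise: sap flux sd is a fraction of each tree's
    noise-free maximum (instrument repeatability); gs spot-measurement
    error is absolute with magnitude inversely proportional to the
    tree's Huber value (leaf-to-crown sampling mismatch, which makes
    calibration quality Hv-driven as in the field data); tree-to-tree
    trait variation is a coordinated lognormal factor on (Hv, gsref, m)
    plus an independent one on Kplant.
    """

    species: tuple[SpeciesPreset, ...] = DEFAULT_SPECIES
    n_trees: int = 4
    n_days: int = 3
    interval_minutes: int = 30
    gs_interval_minutes: int = 60
    start_date: str = "2020-06-10"
    d_min: float = 0.1
    d_max: float = 4.5
    d_night: float = 0.05
    dawn_hour: float = 6.0
    solar_noon_hour: float = 13.0
    dusk_hour: float = 20.0
    tair_night_c: float = 16.0
    tair_peak_c: float = 38.0
    pressure_kpa: float = 101.325
    ref_temp_c: float = 25.0
    sigma_js_rel: float = 0.05      # fraction of tree's noise-free max Js
    sigma_gs: float = 0.05          # mol m-2 s-1 at hv = hv_ref
    hv_ref: float = 2.0e-3          # cm2 cm-2; gs noise scales as hv_ref/hv
    sigma_la: float = 0.10          # ln(cm2) on allometry leaf areas
    tree_sigma: float = 0.16        # lognormal sd of coordinated factor
    kplant_tree_sigma: float = 0.17
    psi_pd_range: tuple[float, float] = (-0.5, -0.3)
    branch_diam_range_mm: tuple[float, float] = (6.2, 20.0)
    tree_branch_diam_range_mm: tuple[float, float] = (8.0, 24.0)
    n_branches_allometry: int = 8
    n_branches_per_tree: int = 5
    n_transects: int = 6
    transect_area_mm2: float = 1.0
    n_stomata_plots: int = 6
    n_vein_leaves: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.d_min >= self.d_max:
            raise ValueError("d_min must be below d_max")
        if (24 * 60) % self.interval_minutes != 0:
            raise ValueError("sampling interval must divide 24 h")
        for name in ("sigma_js_rel", "sigma_gs", "sigma_la", "tree_sigma",
                     "kplant_tree_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} cannot be negative")
        if not self.dawn_hour < self.solar_noon_hour < self.dusk_hour:
            raise ValueError("need dawn < solar noon < dusk")

    @property
    def constant(self):
        """Mechanistic constant evaluated at the reference (T, P)."""
        return mechanistic_constant(self.ref_temp_c, self.pressure_kpa)


def default_config(**overrides) -> SimulationConfig:
    """The default campaign, with keyword overrides."""
    return SimulationConfig(**overrides)


@dataclass(frozen=True)
class TreeTruth:
    """Ground-truth traits of one simulated tree."""

    tree_id: str
    species: str
    hv: float
    gsref: float
    m: float
    kplant: float

    @property
    def d_star(self) -> float:
        return float(np.exp(self.gsref / self.m - 1.0))


def _rng(config: SimulationConfig, *keys: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((config.seed,) + keys))


def _species_index(config: SimulationConfig, species: str) -> int:
    for i, sp in enumerate(config.species):
        if sp.name == species:
            return i
    raise KeyError(f"unknown species {species!r}")


def tree_truth(config: SimulationConfig, species: str,
               tree: int) -> TreeTruth:
    """Deterministic per-tree ground truth.

    A coordinated lognormal factor scales Hv, gsref and m together
    (within-species coupling of sapwood allocation with stomatal
    capacity; scaling m with gsref keeps the flux hump D* species
    specific), and an independent factor scales Kplant.
    """
    si = _species_index(config, species)
    sp = config.species[si]
    rng = _rng(config, _STAGE_TREE, si, tree)
    f = float(np.exp(rng.normal(0.0, config.tree_sigma)))
    g = float(np.exp(rng.normal(0.0, config.kplant_tree_sigma)))
    return TreeTruth(
        tree_id=f"{species}_{tree}", species=species,
        hv=sp.hv * f, gsref=sp.gsref * f, m=sp.m * f,
        kplant=sp.kplant * g)


def _day_hours(config: SimulationConfig, minutes: int) -> np.ndarray:
    return np.arange(0.0, 24.0, minutes / 60.0)


def _d_profile(config: SimulationConfig, hours: np.ndarray) -> np.ndarray:
    """Truncated-sine D course: quarter-sine rise dawn->noon, mirrored
    fall noon->dusk, flat ``d_night`` otherwise."""
    d = np.full(hours.shape, config.d_night)
    rise = (hours >= config.dawn_hour) & (hours <= config.solar_noon_hour)
    fall = (hours > config.solar_noon_hour) & (hours <= config.dusk_hour)
    amp = config.d_max - config.d_min
    d[rise] = config.d_min + amp * np.sin(
        np.pi / 2.0 * (hours[rise] - config.dawn_hour)
        / (config.solar_noon_hour - config.dawn_hour))
    d[fall] = config.d_min + amp * np.sin(
        np.pi / 2.0 * (config.dusk_hour - hours[fall])
        / (config.dusk_hour - config.solar_noon_hour))
    return d


def _tair_profile(config: SimulationConfig, d: np.ndarray) -> np.ndarray:
    """Air temperature tied monotonically to D so that RH stays in
    (0, 1] when D is decomposed as es(Tleaf) - RH es(Tair)."""
    frac = (d - config.d_night) / (config.d_max - config.d_night)
    return config.tair_night_c + (config.tair_peak_c
                                  - config.tair_night_c) * frac


def _gs_true(truth: TreeTruth, d: np.ndarray) -> np.ndarray:
    return np.maximum(0.0, truth.gsref - truth.m * np.log(d))


def generate_diurnal(config: SimulationConfig, species: str, tree: int):
    """Microclimate, gas-exchange and sap-flux series for one tree.

    Returns ``(met, gas, flux)`` DataFrames covering ``n_days`` days.
    The noise-free flux is the mechanistic model inverted,
    ``Js = gs * D / (C * Hv_true)``; leaf temperature equals air
    temperature (tightly coupled canopy) and RH is chosen so that
    recomputing D from (Tleaf, RH) reproduces the stored column exactly.
    """
    truth = tree_truth(config, species, tree)
    si = _species_index(config, species)
    rng = _rng(config, _STAGE_DIURNAL, si, tree)
    js_factor = config.constant.js_to_gs

    hours = _day_hours(config, config.interval_minutes)
    d_day = _d_profile(config, hours)
    tair_day = _tair_profile(config, d_day)
    days = pd.date_range(config.start_date, periods=config.n_days,
                         freq="D")

    met_rows, gas_rows, flux_rows = [], [], []
    gs_every = config.gs_interval_minutes // config.interval_minutes
    if gs_every < 1 or config.gs_interval_minutes % config.interval_minutes:
        raise ValueError("gs cadence must be a multiple of the sampling "
                         "interval")
    for day in days:
        ts = day + pd.to_timedelta(hours, unit="h")
        d = d_day
        tair = tair_day
        es_air = units.saturation_vapour_pressure(tair)
        rh = 1.0 - d / es_air
        rs = np.where(
            (hours >= config.dawn_hour) & (hours <= config.dusk_hour),
            950.0 * np.sin(np.pi * (hours - config.dawn_hour)
                           / (config.dusk_hour - config.dawn_hour)),
            0.0)
        met_rows.append(pd.DataFrame({
            "timestamp": ts, "Tair_C": tair, "Tleaf_C": tair,
            "RH_frac": rh, "D_kPa": d, "Rs_W_m2": rs, "u_m_s": 1.5}))

        gs_true = _gs_true(truth, d)
        js_true = gs_true * d / (js_factor * truth.hv)
        sigma_js = config.sigma_js_rel * js_true.max()
        js_obs = js_true + (rng.normal(0.0, sigma_js, js_true.shape)
                            if sigma_js > 0 else 0.0)
        flux_rows.append(pd.DataFrame({
            "timestamp": ts, "tree_id": truth.tree_id,
            "Js_cm_per_h": js_obs}))

        idx = np.arange(0, hours.size, gs_every)
        # Spot readings sample two leaves of a heterogeneous crown; the
        # leaf-to-crown mismatch shrinks with sapwood allocation per
        # leaf area, so the gs error scales inversely with the tree's Hv
        # (calibration quality is Hv-driven, as in the field data).
        sigma_gs_tree = config.sigma_gs * (config.hv_ref / truth.hv)
        gs_obs = gs_true[idx] + (
            rng.normal(0.0, sigma_gs_tree, idx.shape)
            if sigma_gs_tree > 0 else 0.0)
        gas_rows.append(pd.DataFrame({
            "timestamp": ts[idx], "tree_id": truth.tree_id,
            "gs_mol_m2_s": np.maximum(0.0, gs_obs),
            "Tleaf_C": tair[idx]}))

    met = pd.concat(met_rows, ignore_index=True)
    gas = pd.concat(gas_rows, ignore_index=True)
    flux = pd.concat(flux_rows, ignore_index=True)
    return met, gas, flux


def generate_anatomy(config: SimulationConfig, species: str):
    """Anatomical sample tables for one species (border trees).

    Returns a dict of DataFrames: ``vessels`` (one row per vessel with
    its transect id and area), ``stomata`` (one row per counting plot),
    ``branches`` (diameter-leaf area pairs for the allometry), and
    ``veins`` (vein length and leaf area per cleared leaf).
    """
    si = _species_index(config, species)
    sp = config.species[si]
    rng = _rng(config, _STAGE_ANATOMY, si)

    vessel_rows = []
    for t in range(config.n_transects):
        n_vessels = max(1, int(rng.poisson(
            sp.vessel_density_mm2 * config.transect_area_mm2)))
        diam = rng.lognormal(sp.vessel_mu, sp.vessel_sigma, n_vessels)
        vessel_rows.append(pd.DataFrame({
            "species": species, "sample_id": f"{species}_T{t}",
            "transect_area_mm2": config.transect_area_mm2,
            "diameter_um": diam}))
    vessels = pd.concat(vessel_rows, ignore_index=True)

    dens = rng.normal(sp.stomatal_density_mm2,
                      0.05 * sp.stomatal_density_mm2,
                      config.n_stomata_plots)
    size = rng.normal(sp.stomatal_size_um2, 0.05 * sp.stomatal_size_um2,
                      config.n_stomata_plots)
    stomata = pd.DataFrame({
        "species": species,
        "sample_id": [f"{species}_S{i}"
                      for i in range(config.n_stomata_plots)],
        "density_mm2": np.maximum(dens, 1.0),
        "size_um2": np.maximum(size, 1.0)})
    stomata["amax_um2"] = sp.pore_fraction * stomata["size_um2"]

    lo, hi = config.branch_diam_range_mm
    diam = rng.uniform(lo, hi, config.n_branches_allometry)
    log_la = (sp.allom_c0 + sp.allom_c1 * np.log(diam)
              + (rng.normal(0.0, config.sigma_la, diam.shape)
                 if config.sigma_la > 0 else 0.0))
    branches = pd.DataFrame({
        "species": species,
        "sample_id": [f"{species}_B{i}" for i in range(diam.size)],
        "diameter_mm": diam, "leaf_area_cm2": np.exp(log_la)})

    vd = rng.normal(sp.vein_density_mm_mm2, 0.05 * sp.vein_density_mm_mm2,
                    config.n_vein_leaves)
    leaf_area = rng.uniform(9.0, 11.0, config.n_vein_leaves)
    veins = pd.DataFrame({
        "species": species,
        "sample_id": [f"{species}_V{i}"
                      for i in range(config.n_vein_leaves)],
        "leaf_area_mm2": leaf_area,
        "vein_length_mm": np.maximum(vd, 0.1) * leaf_area})

    return {"vessels": vessels, "stomata": stomata, "branches": branches,
            "veins": veins}


def generate_tree_structure(config: SimulationConfig, species: str,
                            tree: int):
    """Branch diameters and sapwood area of one instrumented tree.

    The tree's true leaf area follows the species allometry exactly
    (noise enters only through the sampled allometry table), and sapwood
    area is set to ``Hv_true x leaf area`` so the Huber-value pipeline
    has an exact recovery target.
    """
    truth = tree_truth(config, species, tree)
    si = _species_index(config, species)
    sp = config.species[si]
    rng = _rng(config, _STAGE_TREE, si, tree, 99)
    lo, hi = config.tree_branch_diam_range_mm
    diam = rng.uniform(lo, hi, config.n_branches_per_tree)
    leaf_area = float(np.sum(np.exp(sp.allom_c0
                                    + sp.allom_c1 * np.log(diam))))
    return {
        "tree_id": truth.tree_id,
        "species": species,
        "branch_diameters_mm": diam,
        "leaf_area_cm2": leaf_area,
        "sapwood_area_cm2": truth.hv * leaf_area,
    }


def generate_water_potentials(config: SimulationConfig, species: str,
                              tree: int, gs_at_midday: float,
                              d_at_midday: float, day: int = 0):
    """Pre-dawn and midday leaf water potentials for one tree-day.

    ``psi_min = psi_pd - gs * D / Kplant_true`` (D in kPa, psi in MPa),
    so inverting the drawdown recovers the true whole-plant conductance.
    """
    truth = tree_truth(config, species, tree)
    if truth.kplant <= 0:
        raise ValueError("Kplant_true must be positive")
    if gs_at_midday < 0 or d_at_midday < 0:
        raise ValueError("gs and D must be non-negative")
    si = _species_index(config, species)
    rng = _rng(config, _STAGE_PSI, si, tree, day)
    psi_pd = float(rng.uniform(*config.psi_pd_range))
    drawdown = gs_at_midday * d_at_midday / truth.kplant
    psi_min = psi_pd - drawdown
    if psi_min > psi_pd:
        raise ValueError("computed psi_min above psi_pd")
    return {"tree_id": truth.tree_id, "species": species, "day": day,
            "psi_pd_MPa": psi_pd, "psi_min_MPa": psi_min,
            "gs_mol_m2_s": gs_at_midday, "D_kPa": d_at_midday}


@dataclass
class Campaign:
    """All simulated tables plus the ground-truth sidecar."""

    config: SimulationConfig
    met: pd.DataFrame
    gas: pd.DataFrame
    flux: pd.DataFrame
    water_potentials: pd.DataFrame
    tree_meta: pd.DataFrame
    tree_branches: pd.DataFrame
    anatomy: dict[str, pd.DataFrame]
    truth: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        from . import io
        io.write_campaign(self, outdir)


def simulate_campaign(config: SimulationConfig | None = None) -> Campaign:
    """Run the full forward simulation for every species and tree."""
    config = config or default_config()
    gas_all, flux_all, psi_all = [], [], []
    meta_rows, branch_rows = [], []
    anatomy = {k: [] for k in ("vessels", "stomata", "branches", "veins")}
    met = None
    truth = {"trees": {}, "species": {}, "constant_js_to_gs":
             config.constant.js_to_gs}

    for sp in config.species:
        truth["species"][sp.name] = {
            "hv": sp.hv, "gsref": sp.gsref, "m": sp.m, "d_star": sp.d_star,
            "kplant": sp.kplant, "allom_c0": sp.allom_c0,
            "allom_c1": sp.allom_c1,
            "vein_density_mm_mm2": sp.vein_density_mm_mm2}
        tables = generate_anatomy(config, sp.name)
        for key in anatomy:
            anatomy[key].append(tables[key])
        for tree in range(config.n_trees):
            t = tree_truth(config, sp.name, tree)
            truth["trees"][t.tree_id] = {
                "species": sp.name, "hv": t.hv, "gsref": t.gsref,
                "m": t.m, "d_star": t.d_star, "kplant": t.kplant}
            m, g, f = generate_diurnal(config, sp.name, tree)
            if met is None:
                met = m  # one weather station for the whole site
            gas_all.append(g)
            flux_all.append(f)
            structure = generate_tree_structure(config, sp.name, tree)
            meta_rows.append({
                "tree_id": structure["tree_id"], "species": sp.name,
                "sapwood_area_cm2": structure["sapwood_area_cm2"]})
            for dmm in structure["branch_diameters_mm"]:
                branch_rows.append({"tree_id": structure["tree_id"],
                                    "diameter_mm": float(dmm)})
            # midday gas exchange drives the water-potential drawdown
            hours = _day_hours(config, config.interval_minutes)
            noon_idx = int(np.argmin(np.abs(hours
                                            - config.solar_noon_hour)))
            d_noon = _d_profile(config, hours)[noon_idx]
            gs_noon = float(_gs_true(t, np.array([d_noon]))[0])
            for day in range(config.n_days):
                psi_all.append(generate_water_potentials(
                    config, sp.name, tree, gs_noon, float(d_noon), day))

    return Campaign(
        config=config, met=met,
        gas=pd.concat(gas_all, ignore_index=True),
        flux=pd.concat(flux_all, ignore_index=True),
        water_potentials=pd.DataFrame(psi_all),
        tree_meta=pd.DataFrame(meta_rows),
        tree_branches=pd.DataFrame(branch_rows),
        anatomy={k: pd.concat(v, ignore_index=True)
                 for k, v in anatomy.items()},
        truth=truth)


def truth_to_json(truth: dict) -> str:
    """Serialize the ground-truth sidecar deterministically."""
    return json.dumps(truth, indent=2, sort_keys=True)
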