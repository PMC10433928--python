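"""End-to-end pipeline driver.

Runs simulate -> fit-flux -> traits -> calibrate-gs -> multitrait and
writes every stage output plus a machine-readable JSON summary.  Stage
failures halt with the stage name and the offending tree id.  For a
fixed seed the whole run is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import flux_response, gs_model, io, multitrait, synthetic, traits

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline",
           "fit_flux_stage", "traits_stage", "calibrate_stage",
           "multitrait_stage"]


class PipelineError(RuntimeError):
    """Raised when a stage fails; names the stage and offending tree."""

    def __init__(self, stage: str, detail: str, tree_id: str = ""):
        self.stage = stage
        self.tree_id = tree_id
        suffix = f" (tree {tree_id})" if tree_id else ""
        super().__init__(f"stage {stage!r} failed{suffix}: {detail}")


@dataclass
class PipelineConfig:
    """Project-level configuration.

    Either ``simulation`` holds keyword overrides for the synthetic
    campaign, or ``input_dir`` points at a directory of real CSV tables
    following the interchange schemas.
    """

    output_dir: str = "pipeline_out"
    input_dir: str | None = None
    simulation: dict = field(default_factory=dict)
    seed: int = 0
    alpha: float = 0.05
    dawn_d_threshold: float = 0.1
    noon_hour: float = 13.0
    calibration_intercept: bool = True
    parabola_intercept: bool = True
    gsmax_formula: str = "diffusive"
    n_boot: int = 1000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _morning(df, met, cfg: PipelineConfig) -> pd.DataFrame:
    """Attach D to a tree series and keep the dawn-to-noon window."""
    merged = pd.merge(df, met[["timestamp", "D_kPa"]], on="timestamp",
                      how="inner")
    return flux_response.filter_morning(
        merged, threshold=cfg.dawn_d_threshold, noon_hour=cfg.noon_hour)


def fit_flux_stage(flux: pd.DataFrame, met: pd.DataFrame,
                   cfg: PipelineConfig) -> pd.DataFrame:
    """Per-tree Js-D response fits pooled over the measurement days."""
    rows = []
    for tree_id, tree_df in flux.groupby("tree_id", sort=True):
        try:
            morning = _morning(tree_df, met, cfg)
            d = morning["D_kPa"].to_numpy()
            js = morning["Js_cm_per_h"].to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                par = flux_response.fit_parabolic(
                    d, js, intercept=cfg.parabola_intercept)
                logf = flux_response.fit_log(d, js)
            best = flux_response.select_model(par, logf)
        except (ValueError, ZeroDivisionError) as exc:
            raise PipelineError("fit-flux", str(exc), str(tree_id))
        rows.append({
            "tree_id": tree_id, "n": par.n, "a": par.a, "b": par.b,
            "c": par.c, "r2_parabolic": par.r2, "D_Jsmax_kPa": par.d_jsmax,
            "Jsmax_cm_per_h": par.jsmax, "status": par.status,
            "Jsref_cm_per_h": logf.jsref, "mJs_cm_per_h_lnkPa": logf.m_js,
            "r2_log": logf.r2, "selected_model": best})
    return pd.DataFrame(rows)


def traits_stage(campaign_tables: dict, fits: pd.DataFrame,
                 cfg: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Species-level anatomy and per-tree functional traits.

    Returns ``(species_traits, tree_traits)``.
    """
    anatomy = campaign_tables["anatomy"]
    met = campaign_tables["met"]
    gas = campaign_tables["gas"]
    wp = campaign_tables["water_potentials"]
    tree_meta = campaign_tables["tree_meta"]
    tree_branches = campaign_tables["tree_branches"]

    formula = {"diffusive": traits.diffusive_gsmax}[cfg.gsmax_formula]

    # --- species-level anatomical traits
    sp_rows = {}
    for species, df in anatomy["vessels"].groupby("species", sort=True):
        ks_vals = [
            traits.hagen_poiseuille_ks(traits.VesselTransect(
                tdf["diameter_um"].to_numpy(),
                float(tdf["transect_area_mm2"].iloc[0])))
            for _, tdf in df.groupby("sample_id")]
        sp_rows.setdefault(species, {})["ks_kg_m_MPa_s"] = float(
            np.mean(ks_vals))
    for species, df in anatomy["stomata"].groupby("species", sort=True):
        anat = traits.StomatalAnatomy(
            float(df["density_mm2"].mean()), float(df["size_um2"].mean()),
            float(df["amax_um2"].mean()))
        sp_rows.setdefault(species, {})["theoretical_gsmax_mol_m2_s"] = (
            traits.theoretical_gsmax(anat, formula))
    for species, df in anatomy["veins"].groupby("species", sort=True):
        vd = [traits.vein_density(r.vein_length_mm, r.leaf_area_mm2)
              for r in df.itertuples()]
        sp_rows.setdefault(species, {})["vein_density_mm_mm2"] = float(
            np.mean(vd))
    allometries = {}
    for species, df in anatomy["branches"].groupby("species", sort=True):
        model = traits.allometry_fit(df["diameter_mm"].to_numpy(),
                                     df["leaf_area_cm2"].to_numpy())
        allometries[species] = model
        sp_rows.setdefault(species, {}).update(
            allom_c0=model.c0, allom_c1=model.c1, allom_r2=model.r2)
    species_traits = pd.DataFrame(
        [{"species": sp, **vals} for sp, vals in sorted(sp_rows.items())])

    # --- per-tree functional traits
    fits_ix = fits.set_index("tree_id")
    morning_gas = {}
    for tree_id, g in gas.groupby("tree_id", sort=True):
        morning_gas[tree_id] = _morning(g, met, cfg)

    # measured gsmax: mean over days of the tree's daily morning maximum
    tree_gsmax = {}
    daily_max = {}
    for tree_id, g in morning_gas.items():
        dm = g.groupby(pd.to_datetime(g["timestamp"]).dt.date)[
            "gs_mol_m2_s"].max()
        daily_max[tree_id] = dm
        tree_gsmax[tree_id] = float(dm.mean())
    species_of = dict(zip(tree_meta["tree_id"], tree_meta["species"]))
    # species-level measured gsmax: mean over the species' trees
    species_gsmax = {}
    for sp in set(species_of.values()):
        vals = [tree_gsmax[t] for t, s in species_of.items() if s == sp
                and t in tree_gsmax]
        species_gsmax[sp] = float(np.mean(vals)) if vals else np.nan

    rows = []
    for rec in tree_meta.itertuples():
        tree_id, species = rec.tree_id, rec.species
        try:
            model = allometries[species]
            diam = tree_branches.loc[
                tree_branches["tree_id"] == tree_id,
                "diameter_mm"].to_numpy()
            la, extrapolated = traits.allometry_predict(model, diam)
            hv = traits.huber_value(rec.sapwood_area_cm2, float(la.sum()))

            kp_rows = wp[wp["tree_id"] == tree_id]
            kp = float(np.mean([
                traits.kplant(r.gs_mol_m2_s, r.D_kPa, r.psi_pd_MPa,
                              r.psi_min_MPa)
                for r in kp_rows.itertuples()])) if len(kp_rows) else np.nan

            gsmax_sp = species_gsmax[species]
            d_jsmax = fits_ix.loc[tree_id, "D_Jsmax_kPa"]
            jsmax = fits_ix.loc[tree_id, "Jsmax_cm_per_h"]
            # gs at D_Jsmax from the tree's log-linear gs-D response
            g = morning_gas[tree_id]
            gfit = flux_response.fit_log(g["D_kPa"].to_numpy(),
                                         g["gs_mol_m2_s"].to_numpy())
            if np.isfinite(d_jsmax):
                gs_at = max(0.0, gfit.jsref
                            + gfit.m_js * np.log(d_jsmax))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    red = traits.gs_reduction(gs_at, gsmax_sp)
            else:
                red = np.nan
            ratio = (traits.jsmax_over_gsmax(jsmax, tree_gsmax[tree_id])
                     if np.isfinite(jsmax) else np.nan)
        except (ValueError, ZeroDivisionError, KeyError) as exc:
            raise PipelineError("traits", str(exc), str(tree_id))
        rows.append({
            "tree_id": tree_id, "species": species,
            "Hv_cm2_cm2": hv, "Hv_extrapolated": bool(extrapolated.any()),
            "Kplant_mol_m2_s_MPa": kp,
            "measured_gsmax_mol_m2_s": tree_gsmax[tree_id],
            "species_gsmax_mol_m2_s": gsmax_sp,
            "Jsmax_over_gsmax": ratio, "gs_reduction": red})
    return species_traits, pd.DataFrame(rows)


def calibrate_stage(gas: pd.DataFrame, flux: pd.DataFrame,
                    met: pd.DataFrame, cfg: PipelineConfig
                    ) -> pd.DataFrame:
    """Per-tree gs ~ Js/D calibrations on morning data."""
    rows = []
    for tree_id, g in gas.groupby("tree_id", sort=True):
        try:
            f = flux[flux["tree_id"] == tree_id]
            paired = gs_model.pair_gs_to_flux(
                g.drop(columns=["tree_id"]), f.drop(columns=["tree_id"]))
            morning = _morning(paired, met, cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = gs_model.calibrate(
                    morning["gs_mol_m2_s"], morning["Js_cm_per_h"],
                    morning["D_kPa"], str(tree_id),
                    intercept=cfg.calibration_intercept)
        except (ValueError, ZeroDivisionError) as exc:
            raise PipelineError("calibrate-gs", str(exc), str(tree_id))
        rows.append({"tree_id": tree_id, "slope": fit.slope,
                     "intercept": fit.intercept, "r2": fit.r2,
                     "n": fit.n, "pvalue": fit.pvalue,
                     "significant": fit.significant(cfg.alpha)})
    return pd.DataFrame(rows)


_TUKEY_VARS = ("D_Jsmax_kPa", "mJs_cm_per_h_lnkPa", "Hv_cm2_cm2",
               "Kplant_mol_m2_s_MPa", "Jsmax_over_gsmax", "gs_reduction",
               "measured_gsmax_mol_m2_s")


def multitrait_stage(fits: pd.DataFrame, tree_traits: pd.DataFrame,
                     species_traits: pd.DataFrame, calib: pd.DataFrame,
                     cfg: PipelineConfig) -> dict:
    """PCA, mJs-on-PC regression, R^2 model with LMG, Tukey letters."""
    df = (tree_traits
          .merge(fits[["tree_id", "mJs_cm_per_h_lnkPa", "D_Jsmax_kPa",
                       "Jsmax_cm_per_h"]], on="tree_id")
          .merge(calib[["tree_id", "slope", "r2", "pvalue"]],
                 on="tree_id")
          .merge(species_traits[["species", "theoretical_gsmax_mol_m2_s",
                                 "vein_density_mm_mm2",
                                 "ks_kg_m_MPa_s"]], on="species"))
    trait_cols = ["Hv_cm2_cm2", "Kplant_mol_m2_s_MPa",
                  "measured_gsmax_mol_m2_s", "Jsmax_over_gsmax",
                  "gs_reduction", "theoretical_gsmax_mol_m2_s",
                  "vein_density_mm_mm2", "ks_kg_m_MPa_s"]
    complete = df.dropna(subset=trait_cols + ["mJs_cm_per_h_lnkPa"])
    try:
        pca_res = multitrait.pca(complete[trait_cols])
        pc_reg = multitrait.regress_on_pcs(
            complete["mJs_cm_per_h_lnkPa"], pca_res, k=2)
        r2_model = multitrait.fit_r2_model(
            complete["r2"], complete["Hv_cm2_cm2"],
            complete["Kplant_mol_m2_s_MPa"], n_boot=cfg.n_boot,
            seed=cfg.seed)
    except ValueError as exc:
        raise PipelineError("multitrait", str(exc))

    tukey = {}
    for var in _TUKEY_VARS:
        sub = df.dropna(subset=[var])
        counts = sub.groupby("species")[var].count()
        if (counts >= 2).sum() >= 2:
            keep = sub[sub["species"].isin(
                counts[counts >= 2].index)]
            comp = multitrait.tukey_compare(
                keep[var], keep["species"], alpha=cfg.alpha)
            tukey[var] = comp
    return {"merged": df, "pca": pca_res, "pc_regression": pc_reg,
            "r2_model": r2_model, "tukey": tukey}


def _round_floats(obj, ndigits=12):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        if np.isnan(obj):
            return None
        return float(round(float(obj), ndigits))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    return obj


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage; write tables and a JSON summary to
    ``cfg.output_dir``; return the summary dict."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if cfg.input_dir is None:
        sim_kwargs = dict(cfg.simulation)
        sim_kwargs.setdefault("seed", cfg.seed)
        if "species" in sim_kwargs:
            sim_kwargs["species"] = tuple(
                synthetic.SpeciesPreset(**sp)
                for sp in sim_kwargs["species"])
        sim_cfg = synthetic.SimulationConfig(**sim_kwargs)
        campaign = synthetic.simulate_campaign(sim_cfg)
        campaign.write(outdir / "simulated")
        tables = {
            "met": campaign.met, "gas": campaign.gas,
            "flux": campaign.flux,
            "water_potentials": campaign.water_potentials,
            "tree_meta": campaign.tree_meta,
            "tree_branches": campaign.tree_branches,
            "anatomy": campaign.anatomy}
        truth = campaign.truth
    else:
        indir = Path(cfg.input_dir)
        if not indir.exists():
            raise PipelineError("load", f"input dir {indir} not found")
        def _load(name, schema):
            path = indir / f"{name}.csv"
            if not path.exists():
                raise PipelineError("load", f"missing table {path}")
            return io.read_table(path, schema)
        tables = {
            "met": _load("microclimate", "microclimate"),
            "gas": _load("gas_exchange", "gas_exchange"),
            "flux": _load("sapflux", "sapflux"),
            "water_potentials": _load("water_potentials",
                                      "water_potentials"),
            "tree_meta": _load("tree_meta", "tree_meta"),
            "tree_branches": _load("tree_branches", "tree_branches"),
            "anatomy": {k: _load(k, k)
                        for k in ("vessels", "stomata", "branches",
                                  "veins")}}
        truth = None

    fits = fit_flux_stage(tables["flux"], tables["met"], cfg)
    io.write_table(fits, outdir / "fits.csv")
    species_traits, tree_traits = traits_stage(tables, fits, cfg)
    io.write_table(species_traits, outdir / "species_traits.csv")
    io.write_table(tree_traits, outdir / "tree_traits.csv")
    calib = calibrate_stage(tables["gas"], tables["flux"], tables["met"],
                            cfg)
    io.write_table(calib, outdir / "calibrations.csv")

    hv_by_tree = dict(zip(tree_traits["tree_id"],
                          tree_traits["Hv_cm2_cm2"]))
    calib_fits = [gs_model.CalibrationFit(r.tree_id, r.slope, r.intercept,
                                          r.r2, int(r.n), r.pvalue)
                  for r in calib.itertuples()]
    try:
        slope_hv = gs_model.slope_vs_hv(calib_fits, hv_by_tree, cfg.alpha)
        slope_hv_dict = dataclasses.asdict(slope_hv)
    except ValueError as exc:
        logger.warning("slope_vs_hv skipped: %s", exc)
        slope_hv_dict = None

    mt = multitrait_stage(fits, tree_traits, species_traits, calib, cfg)
    io.write_table(
        pd.DataFrame(mt["pca"].loadings, index=mt["pca"].traits,
                     columns=[f"PC{i+1}"
                              for i in range(len(mt["pca"].traits))])
        .rename_axis("trait").reset_index(),
        outdir / "pca_loadings.csv")
    relimp = mt["r2_model"].relimp
    io.write_table(pd.DataFrame({
        "regressor": relimp.names, "lmg_share": relimp.shares,
        "ci_lower": relimp.ci_lower, "ci_upper": relimp.ci_upper}),
        outdir / "relative_importance.csv")
    letters_rows = [
        {"variable": var, "species": g, "letters": comp.letters[g]}
        for var, comp in mt["tukey"].items() for g in comp.groups]
    io.write_table(pd.DataFrame(letters_rows), outdir / "tukey_letters.csv")

    summary = {
        "seed": cfg.seed,
        "n_trees": int(len(tree_traits)),
        "fits": fits.drop(columns=["status", "selected_model"])
                    .set_index("tree_id").to_dict("index"),
        "model_selection": dict(zip(fits["tree_id"],
                                    fits["selected_model"])),
        "tree_traits": tree_traits.set_index("tree_id").drop(
            columns=["species", "Hv_extrapolated"]).to_dict("index"),
        "calibrations": calib.set_index("tree_id").to_dict("index"),
        "slope_vs_hv": slope_hv_dict,
        "pca_variance_fraction": mt["pca"].variance_fraction,
        "pc_regression": {
            "params": dict(zip(mt["pc_regression"].names,
                               mt["pc_regression"].params)),
            "pvalues": dict(zip(mt["pc_regression"].names,
                                mt["pc_regression"].pvalues)),
            "r2": mt["pc_regression"].r2},
        "r2_model": {
            "params": mt["r2_model"].params,
            "pvalues": mt["r2_model"].pvalues,
            "r2": mt["r2_model"].r2,
            "diagnostics": mt["r2_model"].diagnostics,
            "lmg_shares": dict(zip(relimp.names, relimp.shares)),
            "lmg_ci_lower": dict(zip(relimp.names, relimp.ci_lower)),
            "lmg_ci_upper": dict(zip(relimp.names, relimp.ci_upper))},
        "tukey_letters": {var: comp.letters
                          for var, comp in mt["tukey"].items()},
    }
    if truth is not None:
        summary["ground_truth"] = truth
    summary = _round_floats(summary)
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))
    return summary
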