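# hydrotrait

Hydraulic-trait-based analysis of how stomatal conductance regulates
tree sap flux as atmospheric drought (vapour pressure deficit, *D*)
increases.

Tree transpiration is commonly monitored as sap flux density *J*ₛ
(cm h⁻¹, volumetric flow per unit sapwood area), while its regulation
happens at the leaves through stomatal conductance *g*ₛ
(mol m⁻² s⁻¹). For a canopy tightly coupled to the atmosphere,
inverting the simplified Penman–Monteith equation links the two through
a single anatomical trait, the Huber value *H*ᵥ (sapwood area per unit
supplied leaf area, cm² cm⁻²):

    gs = C · Hv · Js / D,      C = λγ / (ρₐ·Cp)

with λ the latent heat of vaporization, γ the psychrometric constant,
ρₐ the air density and Cp the heat capacity of air. `hydrotrait`
implements this model together with the surrounding response and trait
pipeline used in whole-plant hydraulics:

- **Js–D response curves** per tree (parabola `Js = aD² + bD (+c)` with
  analytic vertex → the deficit *D*ⱼₛₘₐₓ at which flux peaks and the
  peak flux *J*ₛₘₐₓ; logarithmic `Js = Jsref + mJs·ln D` whose slope is
  the drought sensitivity), restricted to the dawn-to-midday window to
  avoid hysteresis.
- **Hydraulic traits**: theoretical maximum stomatal conductance from
  stomatal density and pore geometry, Hagen–Poiseuille specific
  conductivity from vessel diameters (`ks = πρ/(128ηA)·Σdᵢ⁴`),
  whole-plant conductance `Kplant = gs·D/(Ψpd − Ψmin)`, Huber value via
  log–log branch-diameter allometry, leaf vein density, the
  *J*ₛₘₐₓ/*g*ₛₘₐₓ ratio and the *g*ₛ reduction at *D*ⱼₛₘₐₓ.
- **Per-tree calibrations** of gs against Js/D, whose slope estimates
  C·*H*ᵥ, and the cross-tree regression of those slopes on *H*ᵥ.
- **Cross-species statistics**: PCA of the standardized trait matrix,
  regression of mJs on component scores, a two-predictor model of
  calibration quality (R² ~ *H*ᵥ + *K*plant) decomposed with the LMG
  (Shapley) relative-importance metric implemented from first
  principles with bootstrap confidence intervals, and Tukey-type
  multiple comparisons with compact letter displays.
- **A synthetic field campaign** with known ground truth (five species
  presets spanning *H*ᵥ ≈ 1.2–3.8 × 10⁻³ cm² cm⁻², three measurement
  days, 30-min sap-flow cadence), so every estimator in the pipeline
  has an exact parameter-recovery test.

## Worked example

```python
from hydrotrait import synthetic, pipeline

cfg = synthetic.default_config(seed=1)
campaign = synthetic.simulate_campaign(cfg)
pcfg = pipeline.PipelineConfig(seed=1)

fits = pipeline.fit_flux_stage(campaign.flux, campaign.met, pcfg)
calib = pipeline.calibrate_stage(campaign.gas, campaign.flux,
                                 campaign.met, pcfg)
print(fits[["tree_id", "D_Jsmax_kPa", "Jsmax_cm_per_h",
            "mJs_cm_per_h_lnkPa"]].head(4).round(2).to_string(index=False))
row = calib.iloc[0]
truth = campaign.truth["trees"][row.tree_id]
print(f"{row.tree_id}: calibration slope = {row.slope:.5f} "
      f"(C x Hv_true = {cfg.constant.js_to_gs * truth['hv']:.5f}), "
      f"R2 = {row.r2:.2f}, p = {row.pvalue:.2e}")
```

prints

```
 tree_id  D_Jsmax_kPa  Jsmax_cm_per_h  mJs_cm_per_h_lnkPa
almond_0         4.33            8.34                2.50
almond_1         4.05            8.35                2.41
almond_2         4.19            8.39                2.62
almond_3         4.20            8.43                2.65

almond_0: calibration slope = 0.06182 (C x Hv_true = 0.05868), R2 = 0.78, p = 1.16e-07
```

The four simulated almond trees peak near 4.2 kPa (their underlying
flux optimum is 4.85 kPa; the parabolic vertex is a slightly
conservative estimator near the top of the sampled D range), and the
first tree's gs-vs-Js/D calibration slope lands within ~5% of the
mechanistic prediction C·*H*ᵥ under the default observation noise.

The same chain is available from the shell:

```sh
hydrotrait simulate --out sim --seed 1
hydrotrait fit-flux --input sim/sapflux.csv --met sim/microclimate.csv --out fits.csv
hydrotrait calibrate-gs --gs sim/gas_exchange.csv --flux sim/sapflux.csv \
    --met sim/microclimate.csv --out calib.csv
hydrotrait run-all --out report --seed 1     # full pipeline + summary.json
```

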