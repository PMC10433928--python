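# Methods

## The model

Transpiration *E* of a canopy tightly coupled to the atmosphere is
stomatally limited, so inverting the simplified Penman–Monteith
equation gives the stomatal conductance as

    gs = (λγ / (ρₐ Cp)) · E / D

with λ the latent heat of vaporization (J kg⁻¹), γ the psychrometric
constant (kPa K⁻¹), ρₐ the air density (kg m⁻³), Cp the heat capacity
of air (J kg⁻¹ K⁻¹) and D the vapour pressure deficit (kPa).
Transpiration per unit leaf area follows from sap flux density
measured per unit sapwood area through the Huber value,
E = Js · Hv, yielding the trait-based model gs = C·Hv·Js/D.

`gs_model.mechanistic_constant(T, P)` evaluates the four constituents
from standard meteorological formulae at one reference state (default
25 °C, 101.325 kPa) and treats them as constant over a campaign: their
relative diurnal variation is a few percent, negligible against the
orders-of-magnitude dynamic range of Js and D. The returned object
carries both the physical constant C = λγ/(ρₐCp) and the full factor
`js_to_gs` (≈ 15.6 at the default state) that additionally folds in
liquid-water density (998.2 kg m⁻³), the cm h⁻¹ → m s⁻¹ conversion and
the molar volume of air, so that `gs[mol m⁻² s⁻¹] = js_to_gs · Hv ·
Js[cm h⁻¹] / D[kPa]` with no further unit handling. Every conversion
factor lives in `units.py` and is unit-tested; all boundary-layer and
aerodynamic terms are deliberately absent (coupled-canopy assumption).

Saturation vapour pressure uses the Tetens formula
`es = 0.6108·exp(17.27 T/(T+237.3))` kPa throughout; leaf-to-air D is
`es(Tleaf) − RH·es(Tair)`, falling back to air-to-air D where leaf
temperature is missing and flooring rare negative values at zero.

Whole-plant hydraulic conductance follows the drawdown convention
`Kplant = gs·D/(Ψpd − Ψmin)` with gs in mol m⁻² s⁻¹, D numerically in
kPa and the pre-dawn to midday water-potential difference in MPa, so
Kplant carries mol m⁻² s⁻¹ MPa⁻¹. The mixed kPa/MPa usage is a
documented reporting convention, not a physical identity; all
functions state it explicitly.

## Response-curve fitting

Per tree, morning samples (from the first D > 0.1 kPa of the day
through solar noon, default 13:00 — the rising limb, avoiding the
afternoon hysteresis between flux and D) pooled over the measurement
days are fit with

* the parabola Js = aD² + bD (+ c), vertex D\* = −b/2a giving
  D_Jsmax and the flux there giving Jsmax;
* the logarithmic response Js = Jsref + mJs·ln D.

The model with the higher R² is selected; ties go to the parabola.
R² is computed against the mean-of-Js baseline in both modes (and in
the origin-forced mode), which keeps the two forms comparable;
no-intercept R² conventions differ and this choice is therefore
explicit.

**Intercept default.** The parabolic fit defaults to *including* an
intercept even though the strict response form has none (Js → 0 as
D → 0 physically). The reason is a property of the vertex as an
estimator: when the underlying response is the log-linear stomatal
model (gs = gsref − m·ln D, hence Js ∝ (gsref − m ln D)·D), forcing
the parabola through the origin biases the fitted vertex 12–17% low
for optima in the upper half of a 0.1–4.5 kPa ramp, while the
intercept-allowed vertex stays within 10% of the true optimum across
the ramp. The origin-forced form remains available
(`intercept=False`) and recovers exact parabolas identically. Fits
with a ≥ 0 (no interior maximum) are flagged `no-vertex` rather than
returning silent NaNs.

## Trait calculators

* **Theoretical gsmax** — the anatomical upper bound on diffusive
  conductance. The default formula object is the canonical diffusion
  form `gsmax = d·n·amax / (v·(pd + (π/2)√(amax/π)))` with water-vapour
  diffusivity d and air molar volume v as configuration (defaults
  2.49 × 10⁻⁵ m² s⁻¹ and 0.0245 m³ mol⁻¹, 25 °C values), stomatal
  density n, mean maximum pore area amax, and pore depth pd derived
  from stomatal size S = length × width as half the guard-cell width
  under the usual length ≈ 2 × width proportion (pd = 0.5·√(S/2)).
  The formula is a swappable callable because algebraic arrangements
  of this bound vary across the literature; swapping it never touches
  the unit handling. Stomata are assumed abaxial-only (an
  amphistomatous flag exists).
* **Hagen–Poiseuille ks** = πρ/(128ηA)·Σdᵢ⁴ with water density and
  viscosity fixed at their 20 °C values (998.2 kg m⁻³,
  1.002 × 10⁻⁹ MPa s). No pit-membrane resistance correction is
  applied; ks is an anatomical upper bound.
* **Huber value** via branch allometry: OLS of ln(leaf area) on
  ln(diameter), back-transformed predictions, and an explicit
  extrapolation flag for diameters outside the fitted range
  (predictions are still returned, mirroring field practice for wide
  branches, but always flagged).
* **gs reduction** at D_Jsmax uses the tree's log-linear gs–D response
  evaluated at the fitted D_Jsmax, divided by the species-level
  measured gsmax (mean over trees of each tree's daily morning
  maxima); ratios above 1 are clipped to 1 with a warning (sampling
  noise). Jsmax/gsmax is a per-tree quotient whose extrema need not be
  simultaneous.

## Calibration and significance filter

The empirical calibration regresses gs on Js/D with an intercept by
default — field calibrations are empirical equations, and the
intercept absorbs offsets the strict proportional model cannot; a
no-intercept mode matches the strict form. Spot gs readings are paired
to the half-hourly flux record by nearest timestamp within ±15 min;
unmatched rows are dropped with a logged count. Slope p-values come
from the two-sided t distribution of the OLS estimate (α = 0.05), and
only trees with significant calibrations enter the cross-tree
regression of slope on Hv — under pure noise this filter admits ~5% of
trees, verified by simulation.

## Cross-species statistics

PCA standardizes each trait (ddof 1) and eigendecomposes the
correlation matrix; the sign convention (largest-magnitude loading
positive per component) makes output deterministic across linear
algebra backends. Constant traits are an error naming the trait.

The LMG relative-importance decomposition is implemented from first
principles: each regressor's share is its incremental R² averaged over
all p! orderings of model entry, evaluated by exact enumeration with a
2^p cache of subset R² values (p ≤ 8; the pipeline uses p = 2). The
shares telescope to the full-model R² by construction, and equal the
Shapley attribution — both identities are tested against independent
implementations. Confidence intervals use a case-resampling bootstrap
(default 1000 runs, percentile 95%); degenerate resamples (fewer than
p + 2 distinct rows) are redrawn and counted.

Tukey comparisons fit a one-way model, use Tukey–Kramer standard
errors for unequal group sizes and the studentized-range distribution
(scipy's numerically integrated implementation) for adjusted
p-values; at k = 2 this reduces exactly to the two-sample t-test.
Letters come from the insert-and-absorb algorithm with ties broken by
group order. An optional log/sqrt pre-transformation is recorded in
the output rather than hard-coded per trait.

The calibration-quality model (R² ~ Hv + Kplant, trees pooled across
species) reports Shapiro residual-normality, Breusch–Pagan
heteroscedasticity and design condition number alongside the LMG
shares.

## The synthetic campaign

The generator forward-simulates the design of a multi-species
sap-flow study: 5 species × 4 trees, 3 clear days, 30-min microclimate
and sap-flow cadence, hourly gas-exchange spot readings (≈ 21 morning
calibration samples per tree), D ramping 0.1 → 4.5 kPa along a
quarter-sine from dawn (06:00) to solar noon (13:00) and mirrored to
dusk, air temperature tied monotonically to D (16–38 °C) so that the
stored (Tleaf, RH, D) triple is exactly self-consistent under the
Tetens formula, with Tleaf = Tair (coupled canopy).

Ground truth per species: Huber value 3.83/2.50/1.20/1.80/1.50 × 10⁻³
cm² cm⁻², gs at 1 kPa 0.27/0.24/0.11/0.15/0.13 mol m⁻² s⁻¹, log-linear
sensitivity m set so the noise-free flux optimum
D\* = exp(gsref/m − 1) sits at 4.85/4.28/2.88/4.50/3.90 kPa, and
Kplant 3.94/5.04/1.25/2.50/2.00 mol m⁻² s⁻¹ MPa⁻¹ — values spanning
the ranges reported for Mediterranean tree crops (almond- and
olive-like species with large sapwood allocation and weak stomatal
limitation; citrus-like species with the opposite syndrome). Stomatal
conductance follows gs = max(0, gsref − m·ln D); sap flux inverts the
mechanistic model, Js = gs·D/(C·Hv); midday water potentials satisfy
the Kplant drawdown identity exactly.

Tree-to-tree variation applies one coordinated lognormal factor
(sd 0.16) to Hv, gsref and m jointly — within-species coupling of
sapwood allocation with stomatal capacity; scaling m with gsref keeps
D\* species-specific — and an independent factor (sd 0.17) to Kplant.
Both dispersions match the within-species coefficients of variation
implied by published per-species mean ± SE values for these crops.

Noise model: sap-flux error is Gaussian with sd 5% of the tree's
noise-free maximum (half-hourly heat-pulse repeatability); gas-exchange
spot error is absolute with sd 0.05·(2 × 10⁻³/Hv) mol m⁻² s⁻¹ — spot
readings sample two leaves of a heterogeneous crown, and the
leaf-to-crown mismatch shrinks with sapwood allocation per leaf area.
This makes calibration quality Hv-driven and reproduces the observed
spread of calibration R² (from ≈ 0.4 to ≈ 0.97 across species);
allometry leaf areas carry lognormal noise (sd 0.10 on the log scale).
All randomness flows from one seed through per-(species, tree, stage)
spawned generators, so campaigns are byte-reproducible and any
sub-table can be regenerated in isolation.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: radiation- or boundary-layer-limited
transpiration (D is the only driver), soil water deficit and its
interaction with atmospheric drought, afternoon hysteresis beyond the
morning window (afternoons mirror mornings exactly), heat-pulse
raw-signal artefacts, xylem cavitation feedbacks on Kplant, and any
decoupling between leaf and air temperature. Parameter-recovery
results therefore validate the estimators, not the field realism of
the forward model.

## Numerical choices and degenerate inputs

All OLS fits use `numpy.linalg.lstsq`; closed-form and
normal-equations oracles agree to ≤ 1e-10 relative in tests. Rank
deficiency (constant D, constant ln D, collinear regressors) is an
error, never a silent NaN. Empty morning windows name the offending
day. Vessel transects reject empty lists and non-positive areas.
Summary JSON rounds floats at 12 significant decimals (stable bytes,
well below every tolerance used).

Problem sizes in the shipped checks: campaigns of 20 trees × 3 days,
50-seed replication for the qualitative cross-species structure,
1000-rep null simulations for the family-wise-error and type-I
controls, 500-vessel transects and 1000-run bootstraps — sizes chosen
to keep every invariant measurable with comfortable Monte-Carlo margin
while the full suite runs in a couple of minutes.

## Known limitations

* The vertex of a parabola is a biased estimator of the underlying
  flux optimum when the optimum lies near the top of the sampled D
  range (≈ −8% at 4.3 kPa on a 4.5 kPa ramp even with the intercept);
  the reported D_Jsmax inherits this.
* The anatomical traits (theoretical gsmax, ks) are upper bounds;
  no pore-occlusion or pit-membrane corrections are applied.
* LMG shares of strongly collinear predictors split attribution and
  become seed-sensitive near ties; the bootstrap intervals quantify
  this.
* The Kplant unit convention (D in kPa against ΔΨ in MPa) follows
  field reporting practice and is not dimensionally reduced.
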