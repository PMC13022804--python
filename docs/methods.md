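# Methods

This note documents the models, parameter choices and numerical decisions
behind `riverghg`, and what the synthetic-data tests do and do not establish
about real river data.

## Gas chemistry

Percent saturation is the ratio of the dissolved concentration to the
concentration in equilibrium with the atmosphere, ×100. Equilibrium
concentrations use freshwater (zero-salinity) Henry's-law solubilities at
1 atm total pressure:

| Gas | Formulation | Value at 25 °C (mol L⁻¹ atm⁻¹) |
| --- | --- | --- |
| CO₂ | Weiss (1974) K₀ polynomial | 0.0340 |
| CH₄ | Wiesenburg–Guinasso (1979) Bunsen coefficient / 22.414 | 1.41 × 10⁻³ |
| N₂O | Weiss–Price (1980) K₀ polynomial | 0.0248 |
| O₂ | Benson–Krause equation (air-saturation mg L⁻¹, the USGS standard) | 8.26 mg L⁻¹ |

All are strictly decreasing in temperature on the supported [0, 40] °C range;
requests outside it raise. No salinity dependence, carbonate-system
speciation, fugacity correction or elevation-dependent pressure is applied —
the budget assumes 1 atm everywhere. Which exact solubility constants a given
upstream study used is rarely stated; across the common formulations this
choice moves the flux medians by roughly ±5 %, which is well inside the
propagated uncertainty.

The atmospheric boundary condition is a packaged table of NOAA global annual
mean mixing ratios, 2000–2022. Budget defaults use the 2002–2022 period means
computed from that table at run time (≈394 ppm CO₂, 1.82 ppm CH₄, 326 ppb
N₂O).

## Flux budget

Fick's-law diffusive flux F = k·C_sat·(sat/100 − 1) with defaults
k = 9.4 m d⁻¹ and a global ice-free river surface area of 616,000 km²; annual
upscaling multiplies by area and 365 days. Masses are element-basis (CO₂-C,
CH₄-C by 12.011 g C mol⁻¹; N₂O-N by 28.014 g N mol⁻¹, two N per molecule).
The reference global water temperature for C_sat defaults to 16 °C, a
representative discharge-weighted global river temperature; it is
configurable, and a per-catchment temperature mode is available through the
same function by passing catchment-level saturations and temperatures.

Uncertainty components are relative and combine in quadrature: per-gas model
uncertainty (7.2 % CO₂, 9.1 % CH₄, 6.6 % N₂O — MAE as a share of the observed
mean), 50 % on k, 28 % on surface area, and optionally the relative half-width
of a 1000-draw bootstrap percentile CI on the median saturation. At thousands
of catchments the bootstrap component is a fraction of a percent and is
numerically negligible next to the fixed components, so the propagated bounds
are reproducible from the three fixed components alone. The lower bound is
floored at zero (a supersaturated median cannot emit negative mass); the
default parameterisation never reaches the floor.

CO₂-equivalents convert element masses to molecule masses (×44.009/12.011,
×16.043/12.011, ×44.013/28.014) and weight CH₄ and N₂O by GWP₁₀₀ = 27.2
(non-fossil CH₄, AR6) and 273. The counterfactual "avoided emission" assumes
a linear ramp between the start- and end-year CO₂-eq rates; holding the start
rate constant avoids the triangle n·Δ/2 in total, Δ/2 per year.

## Synthetic scenario generator

The generator emulates the *structure* of a satellite-driven global
reconstruction — not geographic realism. Each catchment gets a region label
(8 continental regions with latitude bands), a stream order (0–10),
elevation, topographic diversity, and imposed linear trends drawn from
configurable distributions: warming (default 0.27 ± 0.15 °C decade⁻¹,
matching the global-change magnitudes the pipeline targets) and cropland /
urban expansion (% decade⁻¹). A latent air-temperature field (latitude /
elevation baseline + annual harmonic + iid daily synoptic noise + trend)
drives everything: water temperature couples at slope 0.9 (so the imposed
water-temperature trend is exact by construction), vegetation / snow indices
and PAR are deterministic functions of the latent climate plus observation
noise, and GHG saturations and nutrients follow log-linear response functions
of water temperature, land use, precipitation and indices with per-catchment
site effects and multiplicative log-normal noise. Dissolved oxygen is a
fraction (≈0.77 on average) of its temperature-dependent solubility declining
with anthropogenic land use, so warming plus expansion produce deoxygenation
mechanistically. A 365-day calendar (no Feb 29) keeps the seasonal harmonic's
annual mean identical across years, so noiseless imposed slopes are recovered
by OLS to machine precision.

Default response coefficients and noise levels were chosen once so that, on
default scenarios, (a) saturations are strongly right-skewed with medians far
below means, (b) a random forest trained on the remote-sensing predictors
alone reaches moderate-to-high held-out skill (R² ≈ 0.5–0.9 for the GHGs) —
the unexplainable share being the site effects and observation noise — and
(c) warming and land-use effects are recoverable downstream. What the
generator does **not** emulate: spatial autocorrelation, hydrological
routing, flow-dependent gas transfer, diel cycles, sampling bias toward
accessible sites, and non-stationary response functions. Passing tests
therefore demonstrate that the pipeline's machinery is correct and unbiased
under known ground truth, not that its outputs on real data are accurate.

## Learning protocol

One random 70/30 train/test row split (ignoring site/date structure), 10-fold
cross-validation on the training set to tune `mtry` (`max_features`) over 10
evenly spaced integers from 2 to the number of predictors, minimizing MAE,
with a fixed seed (default 142). Right-skewed responses are fitted on the
natural-log scale — everything except DO (mg L⁻¹), pH and water temperature —
and back-transformed by plain exponential without a smearing correction,
a known low-bias source for means (documented, not corrected, since the
evaluation targets medians and trends). Test R² is reported on the model
(possibly log) scale; MAE and its percent-of-mean on the natural scale;
per-site temporal skill uses the 2009 Kling–Gupta efficiency
(KGE = 1 − √((r−1)² + (α−1)² + (β−1)²), α the SD ratio), computed for sites
with ≥2 held-out observations; a coefficient-of-variation variant (KGE-2012)
is available. Annual reconstruction applies daily-trained models to
annual-mean predictors; this assumes approximate linearity of the learned
response over the intra-annual predictor range. Tree ensembles additionally
attenuate linear trends (leaf averaging, no extrapolation): on synthetic
scenarios the reconstructed global warming trend is significant and correctly
signed but ~15–20 % smaller in magnitude than the imposed truth. Tests assert
magnitude agreement within 30 % rather than exact recovery.

In tests the forest protocol is scaled down (60–150 trees, mtry grid of 3–4,
3–5 folds, a few thousand training rows); these sizes are the package's
testing choice and leave the tuning logic identical.

## Trends, pressures, attribution

Trends are plain OLS of annual means on year, two-sided slope p-values, no
autocorrelation-robust errors and no multiple-testing correction across
regions/variables (flagged here; consumers needing family-wise control should
apply it downstream). A perfectly constant series returns slope 0 with p = 1
by contract. Decadal rate ≡ 10 × slope exactly. Land-use trends are windowed
to 2002–2019, the span of the land-use record; regional tables blank
non-significant cells (p ≥ 0.1) and mark marginal ones. Whether regional rates
derive from the region-mean series or from means of catchment slopes is an
open representational choice; the region-mean series is the default, the
alternative a mode switch.

The pressure classification median-splits per-catchment water-temperature and
anthropogenic land-use (cropland + urban) slopes, ties to "high"; it is
invariant under monotone affine transforms of either slope set. The 0–1
pressure index min-max-normalizes water temperature and anthropogenic
land-use fraction over the full pool of catchment-year values (per-year
normalization available as a switch) and averages them. Binned response
summaries use 20 equal-width bins with gaps retained; "exponential" fits are
log-linear OLS for determinism and closed-form testability. Group contrasts
delegate pairwise significance to Tukey's HSD; the latitude-random-effect
mixed model of the original design is deliberately not re-derived.

Attribution fits one elastic net per catchment (mixing parameter 0.5 by
default, configurable in [0, 1]; sensitivity to this choice is mild because
the drivers are standardized within catchment) on the annual series, penalty
chosen by cross-validated-error minimization over a log-spaced path with
floor ratio 1e-4 (the glmnet `lambda.min` convention), 5-fold CV — 10 folds
would leave ~2-point folds at ~20 annual observations. Land-use columns are
frozen at their 2019 value beyond the land-use record. The reported r² is
in-sample by default (a CV option exists); the estimator choice is stated
because penalized in-sample r² is optimistic. The `lambda.min` rule carries a
small systematic shrinkage toward zero (≈1 % of each coefficient at the noise
levels tested, scaling with noise); with many catchments this bias exceeds
the tiny across-catchment SE, so recovery tests assert mean standardized
deviation within 2 SE plus <10 % relative error per coefficient rather than a
simultaneous per-coefficient 2-SE band.

## Numerical and degenerate-input conventions

Saturation requires C_sat > 0; its inverse is exact to 1e-12 relative.
Constant bootstrap samples return a zero half-width. Constant responses in
the elastic net return a zero coefficient vector flagged via r² = 0. DON is
floored at zero with a flag where DIN > TN; DOC:TN is NaN-flagged for
TN ≤ 0. Empty sparse-field campaigns are returned empty with an
`empty_campaign` flag rather than raising. All randomness flows from explicit
integer seeds through `numpy.random.default_rng`; reruns are bit-identical on
the same platform.

## Known limitations

- The flux budget is diffusive only: no ebullition or plant-mediated CH₄
  pathways, no reach-scale hydraulic k, no seasonal surface-area dynamics.
- The reference-temperature mode treats the globe as one parcel at 16 °C;
  per-catchment temperature aggregation changes CH₄/N₂O medians by a few
  percent.
- Whether a single global temperature or averaged per-catchment temperatures
  is the better reading of "modeled global water temperatures" is ambiguous;
  both modes are provided.
- The synthetic generator's predictor distributions are plausible, not
  calibrated to any satellite product.
- Retransformation bias of log-scale fits is not corrected.
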