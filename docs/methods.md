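# Methods

`benthoflux` infers benthic mineralization and solute exchange at the
sediment–water interface (SWI) of shallow coastal sediments from the three
classical measurement chains, and places the result in a community and carbon
budget context. This note documents the models, conventions, defaults and
limitations; everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`.

## Sediment properties

Porosity is gravimetric. A wet subsample of mass `m_wet` dried at 105 °C
leaves `m_d` (sediment plus precipitated sea salt); the evaporated water is
`m_w = m_wet − m_d`. With salinity `S` as a mass fraction, water density
`ρ_w` (default 1.0 g cm⁻³, the evaporated water is fresh) and grain density
`ρ_s` (default 2.66 g cm⁻³, terrigenous material):

    φ = (m_w/ρ_w) / ( m_w/ρ_w + (m_d − S·m_w)/ρ_s )

The salt term removes residual sea salt from the grain mass, so φ increases
(slightly) with S. Field metadata usually reports salinity in PSU; the I/O
layer converts PSU → mass fraction (÷1000). Total inorganic carbon is
TC − TOC and is refused (not clipped) when TOC > TC. Chloroplastic pigment
equivalents CPE = Chl *a* + phaeophytin; the Chl *a*/Phaeo ratio indexes the
freshness of the organic material. Location summaries average **per-sample
ratios**, not ratios of location means — for patchy data the two differ.

## Transport coefficients

Free-solution diffusion coefficients D(T, S) for O₂, DIC (as HCO₃⁻), PO₄,
NH₄, NO₂, NO₃ and SO₄ come from an embedded 0/10/20 °C freshwater table
(compiled from the standard seawater tabulations: Li & Gregory 1974;
Boudreau 1997; Schulz & Zabel 2006), piecewise-linear in temperature with end
extrapolation, times a linear salinity viscosity correction
`1 − 0.048·S/35`. Accuracy is a few percent, which dominates neither the
counting nor the analytical uncertainty of any flux here. The table can be
exported to CSV (`transport.export_coefficient_table`) for audit. Sediment
diffusivity uses the tortuosity relation `Ds = D/θ²`, `θ² = 1 − ln(φ²)`.

## Chamber incubations (total fluxes)

A cylindrical chamber of inner diameter d encloses area `A = π(d/2)²` and
water volume `V = A × mean(height readings)`. The total flux is the rate of
concentration change scaled by V/A. With more than two samplings the rate is
an OLS slope with a two-sided t-test; slopes with p > α (default 0.05) are
reported with the `nonsignificant_slope` flag. With exactly two samplings the
finite difference is used, and a concentration change below the analyte's
detection limit flags the flux `below_detection` (the DIC limit defaults to
0.05 μM, the value stated for the incubation methodology; nutrient limits are
converted from the analyzers' 2 ppb element limits). Nitrate is derived
per time point as [NO₃+NO₂] − [NO₂]; negative derived values within
analytical noise are kept and flagged, never clipped.

Sign convention (package-wide): **positive = efflux** (sediment → water).
Oxygen uptake is therefore a negative flux; `FluxResult.uptake` exposes the
positive "total oxygen uptake" (TOU) magnitude used in reporting. Carbon
equivalents use the Redfield ratio C:O₂ = 106:138; the respiration quotient
is RQ = |DIC flux|/TOU. Light/dark chambers are compared with a Levene test
followed by Student's or Welch's t-test; non-rejection (p > α) licenses
pooling.

## Oxygen microprofiles (diffusive uptake, penetration depth)

The profile model: a well-mixed plateau, a diffusive boundary layer (DBL) in
which transport is purely molecular, and a consumption zone below the SWI.
The diffusive oxygen uptake applies Fick's first law at the interface:

    DOU = φ · Ds · |dO₂/dz| at z = 0

This is the flux per unit bed area, the same `−φ·Ds·dC/dz` form used for the
pore-water fluxes; the porosity factor is part of the package's convention
(microsensor profiles measure pore-water concentration, and only φ of a bed
cross-section is pore). Applied to a gradient partly inside the DBL — where
the free coefficient D > φ·Ds governs — the estimate errs low, so DOU is a
mild underestimate whenever the fit window touches the DBL.

Estimation:

1. **Smoothing** — centred running mean, default 3 points (0.3 mm support at
   the 100 μm sensor step), shrunken symmetric windows at the ends.
2. **First alteration** — the overlying-water plateau is the longest initial
   run whose OLS slope is not significant at α; the alteration is the first
   point deviating from the plateau mean by more than k (default 3) raw-sample
   plateau SDs, with the same sign sustained over 5 consecutive smoothed
   points. The persistence requirement holds the false-start rate on
   pure-noise plateaus below 1% (measured ≈0.5%); without it, correlated
   wiggles in the smoothed series trip a point-wise k = 3 rule an order of
   magnitude more often.
3. **Gradient** — OLS on the *raw* samples over a window starting at
   max(first alteration, SWI) and spanning 0.5 mm by default (hard cap 1 mm).
   Starting at the SWI rather than inside the DBL avoids mixing the two
   transport regimes; fitting raw samples avoids the smoothed kink at the
   interface. The span is a bias–variance choice: for a zero-order-consumption
   parabola the OLS slope underestimates the interface gradient by roughly
   (span/2)/OPD, so 0.5 mm keeps the bias near 3–4% for penetration depths of
   5–8 mm while still using ≥5 points.
4. **OPD** — oxygen penetration depth, defined operationally as the depth
   where the smoothed profile makes a sustained drop below the anoxia
   threshold (default 1 μmol L⁻¹, a typical electrochemical sensor floor),
   refined by inverting a local linear fit around the crossing. The
   refinement brings the median error well under the sensor spacing scale.

## Pore-water profiles (diffusive fluxes)

Rhizon samples at 1 cm intervals with the bottom-water reference at −0.5 cm.
The diffusive flux over a per-analyte depth interval (default −0.5 to 2.5 cm;
near-surface gradients dominate exchange, and intervals are configuration,
e.g. a deeper window for the nitrite influx leg) is

    flux(downward) = −φ̄ · Ds · dC/dz

with the OLS gradient over the interval's points (finite difference when only
two). The reported `FluxResult.value` is converted to the package's
positive-efflux convention (= −the downward Fickian value, exposed as
`fickian_downward`), so a solute accumulating with depth yields a positive
efflux, consistent with the chamber sign round-trip. A perfectly flat profile
(the sulfate case) yields exactly zero, flagged `nonsignificant_slope`.

## Community metrics

Prokaryote carbon: cells cm⁻³ × mean cell volume (μm³) × 3.0×10⁻¹³ g C μm⁻³,
integrated over a default 5 cm (the sampled depth) for areal stocks.
Macrofauna carbon: 50% of ash-free dry weight (dry − ash). The deep-burrowing
bivalve *Laternula elliptica*, undersampled by grabs, is quantified from a
photo survey: a linear siphon-width → AFDW conversion gives individual
carbon; biomass = mean individual carbon × density; location means are added
to every grab replicate (the gear-combination rule). Shannon diversity
H′ = −Σ pᵢ ln pᵢ on density shares. The community bioturbation potential:

    BPc = Σᵢ (Bᵢ/Aᵢ) · Aᵢ · Mᵢ · Rᵢ      (default, "as_printed")

with mobility Mᵢ ∈ 1–4 and reworking Rᵢ ∈ 1–5; the literature formulation
with √(Bᵢ/Aᵢ) is available as the `sqrt` variant and the variant used is
recorded in outputs.

## Carbon budget

Demand is the C-TOU; supply is a (min, max) band of pelagic primary
production in mmol C m⁻² d⁻¹ (default band 19.7–21.6, i.e. 236–259 mg C at a
carbon molar mass of 12.0 g mol⁻¹ — 12.0, not 12.011, reproduces the
conventional 1-decimal conversions and is configurable). The state
(supply meets demand / deficit) is evaluated against both band ends, and
DOU/TOU gives the microbially mediated share of mineralization.

## Synthetic data generator

The generator emulates the study conditions with exact truth records; site
presets `faro_like`, `creek_like`, `islad_like` are anchored to measured
study-site values (porosities 0.56/0.51/0.76; TOU 33/43/18 mmol O₂ m⁻² d⁻¹;
DIC effluxes from the respiration quotients 0.55/0.53/0.65; DOU = the
observed DOU/TOU shares × TOU; penetration depths 7.5/6.5/5.5 mm inside the
observed 3–8 mm envelope; diffusive/total shares inside the observed
0.3–13%; macrofauna stocks and *L. elliptica* shares 39/42/69%).

* **Incubations** — linear drawdown/buildup at the imposed flux; the measured
  concentration is the mean of technical replicates (duplicate Winkler for
  O₂, triplicates otherwise) with multiplicative noise at the analytical
  RSDs (O₂ 0.5%, DIC 0.5%, NH₄ 1.5%, PO₄ 1.0%, NO₂ 0.8%, NO₃+NO₂ 2.5%).
  Backgrounds are realistic ambient values (O₂ 300 μM, DIC 2050 μM — the
  Antarctic coastal summer surface value — NO₃ 30 μM, etc.).
* **Microprofiles** — plateau, linear DBL (default 0.5 mm) with slope
  DOU/D, and a zero-order-consumption parabola with interface slope
  DOU/(φ·Ds) reaching zero at the preset OPD; the interface concentration is
  derived (C_swi = slope·OPD/2, ≈230–260 μM O₂ bottom water for the presets).
  Additive sensor noise at 1% of bottom-water O₂, floored at −3σ as real
  electrochemical sensors are near zero. Truth records both the parabola zero
  and the threshold crossing.
* **Pore water** — exponential relaxation over a decay length λ (15 cm for
  NH₄ and DIC, consistent with the deep suboxic zone that the flat ~27 mM
  sulfate profiles indicate; shorter for PO₄ and the rapidly consumed NO₃),
  with the bottom-water point on the gradient's linear extension where that
  stays positive and at the water-column value otherwise; nitrite has a
  subsurface peak (efflux above, influx below). Note the consequence: for
  strongly curved profiles (PO₄, NO₃, NO₂) the interval-OLS gradient is a
  biased estimate of the true surface gradient — that is a property of the
  field method itself, and only the near-linear NH₄/DIC cases carry a tight
  (10%) recovery guarantee.
* **Community** — lognormally patchy biomass (σ = 1) with one dominant
  deposit feeder and the large bivalve scaled to its preset share exactly;
  trait scores drawn from their ordinal scales; truth computed by the same
  metric definitions on the emitted table.
* **Layers** — gravimetric masses inverted from target porosities with a
  downward porosity decline and lognormal pigment decay.

Everything is deterministic under a fixed seed, to the byte, in every emitted
file.

What the generator does **not** emulate: bioirrigation and fauna-mediated
advection (the reason total fluxes exceed diffusive ones in nature is imposed
here, not mechanistic), transient diagenesis, tidal forcing, inter-replicate
variance structure beyond independent noise, and instrument drift. Passing
recovery tests therefore demonstrates estimator correctness under the assumed
measurement model, not robustness to processes the model omits.

## Verification scale and expected errors

The recovery experiments (also run by `scripts/acceptance.py`) use two-point
incubations at 10,000 Monte-Carlo replicates per analyte, 1,000 microprofiles
and 40 pore-water cores; these sizes keep the median-error estimates' own
Monte-Carlo noise an order of magnitude below the documented bounds while the
whole script runs in well under a minute. Expected behaviour: chamber median
errors ≤ the per-analyte analytical uncertainties (5.4–7.4%; DIC is the
binding case at ≈5.2% because its 0.5% RSD acts on a ~2 mM background);
median DOU within 5% of the imposed flux (≈3.5%, the window-centroid
curvature bias); median OPD error ≈0.15 mm; NH₄/DIC pore-water fluxes within
10% (≈6.5%, the exponential-curvature bias).

## Known limitations

* The DOU porosity convention (φ·Ds) is a modelling choice; field papers are
  not unanimous, and omitting φ would scale DOU by 1/φ (≈1.3–2×).
* Diffusive fluxes for strongly curved pore-water profiles underestimate the
  surface gradient by construction of the linear-regression method.
* The light/dark pooling check at n = 3 per group has little power; pooling
  is a non-rejection decision, not evidence of equality.
* The prokaryote areal stock depends linearly on the assumed integration
  depth (default 5 cm), which propagates into the macrofauna stock fraction.
* The budget compares rates measured at different times and scales; the
  package reports the comparison and does not adjudicate the ecological
  claim of autotrophy.
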