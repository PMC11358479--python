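# Methods

This note documents the model, the numerical choices, and what the
synthetic tests do and do not establish.

## Model structure and assumptions

The package treats human dispersal as the propagation of a population
density ρ(x, y, t) (persons per 100 km²) on a regular longitude–latitude
grid, driven entirely by a habitat-suitability surface ("human existence
potential", HEP). The core assumptions:

* Suitability is separable into an environmental layer Φ_E (climate only),
  an accessibility layer Φ_Ac (terrain/water modifiers) and an
  availability layer Φ_Av (population pressure). Culture, technology and
  adaptation enter only implicitly, through the fitted niche and the hard
  phase switch between the two fitted suitability stacks.
* The population responds to climate through the carrying capacity
  ρ_c = ρ_c,max Φ_Ac and through the growth rate r = r_max Φ_Av / ρ_c,max;
  interactions with other populations are not modelled.
* Climate variability between the stadial and interstadial end members is
  one-dimensional: the accessible-HEP field at any time is a linear blend
  of the GS and GI end members weighted by the normalised δ¹⁸O proxy,
  held piecewise constant on the proxy's 20-yr step (nearest step; no
  sub-step interpolation).

## Niche model

Φ_E = expit(½PᵀAP + B·P + C) on four standardized predictors. Fitting is
penalised maximum likelihood by damped Newton/IRLS: gradient-norm
tolerance 1e-8 (sup norm), at most 200 iterations, ridge 1e-6 on A and B
(never on the intercept C) to keep quasi-separable configurations
well-posed. Standard errors come from the inverse curvature at the
optimum; with ridge 0 the fit reproduces an unpenalised GLM (verified in
the tests against an independent GLM implementation).

Presence/absence construction labels spatial blocks (default one 0.5°
cell; larger blocks aggregate cells by block means and one record per
block). The a-priori habitability envelope — annual mean temperature in
[−2, 16] °C and wettest-month precipitation in [30, 250] mm — defines
absences among site-free blocks. The remaining blocks are pseudo-absences
with three labelling options; the default is the most stringent (label 1
with probability N_p/(N_p + N_pa)), which biases Φ_E low. This is a
deliberate conservatism: the fitted surface then under-states rather than
over-states habitability, and the ensemble spread quantifies the cost.

The downstream suitability is the **mean of the member Φ_E fields**, not
the field of mean coefficients: the mean of expits stays in [0, 1],
whereas coefficient averaging has no such guarantee.

Prediction-time predictors outside the training range are extrapolated by
the quadratic without clamping (stadial climates are deliberately out of
the training distribution); excursions beyond ±5 training s.d. are logged.

## HEP layers

* Modifiers are rudimentary by design: g_wat is the land indicator; g_ele
  is 1 below 1 500 m with a linear ramp to 0 at 2 500 m; g_std is 1 below
  300 m sub-grid s.d. ramping to 0 at 600 m. All breakpoints are
  configurable; extra named unit-interval modifiers multiply in.
* The availability transform uses the **Weibull probability density** in
  x = ρ/ρ_c with scale ε and shape η > 1, normalised by its closed-form
  maximum at the mode x* = ε((η−1)/η)^(1/η), so Φ_Av ∈ [0, ρ_c] and is
  unimodal: zero at ρ = 0 (isolation), maximal at x*, vanishing under
  overcrowding. A divergent exponential variant of this expression admits
  no interior maximum and contradicts the documented peak at ρ ≈ 0.2 ρ_c
  (ε = 0.4, η = 1.6), so the standard density form is used. Simulations
  default to η = 2.5; η = 1.6 reproduces the illustrative peak-at-0.2
  case.
* Where the carrying capacity is exactly zero the population decays
  exponentially at r_max, the culture's maximal demographic rate. This
  matters: because r ∝ Φ_Av and Φ_Av vanishes double-exponentially for
  ρ ≫ ρ_c, the logistic term alone cannot depopulate a cell whose capacity
  merely *drops* — overcrowded cells freeze rather than die back. Stadial
  population collapses therefore require genuinely uninhabitable cells.
  The pipeline achieves this faithfully to the niche framework by applying
  the same a-priori habitability envelope used in training as an extra
  accessibility modifier at prediction time (an indicator g_x), so cells
  whose blended climate leaves the envelope carry ρ_c = 0.

## Solver numerics

* Internal units: km, yr, persons per 100 km²; Earth radius 6 371 km.
* Spherical metric: Δx = R Δλ cos φ per row, Δy = R Δφ; cell areas
  R²Δλ(sin φ_top − sin φ_bot) (their sum telescopes exactly to the
  spherical box area).
* Operator splitting per 10-day step, transport then growth.
* Transport is flux-form finite volume on cell faces: first-order upwind
  advection (face velocity = mean of adjacent cell velocities) plus
  centered diffusion (face D = arithmetic mean), with zero flux across
  coastlines and domain edges. This conserves total persons to float
  rounding and keeps ρ ≥ 0 under the CFL bounds
  max|v|Δt/min(Δx,Δy) < 1 and D Δt/min(Δx,Δy)² < 0.25, which are checked
  at construction (diffusive, with D_max) and at every step (advective,
  naming the violating cell).
* Growth uses the exact logistic map per cell over the step —
  unconditionally stable and dt-insensitive; a growth-only run reproduces
  the closed-form logistic trajectory to 1e-12 relative.
* The drift equation is advanced by exponential Euler
  v ← v e^(−γΔt) + (α/γ)(1 − e^(−γΔt))∇Φ_Av, exact for forcing frozen over
  the step and bounded by |α∇Φ_Av|/γ.
* Diffusivity D = κ·(κ_l√(ΔxΔy))·(κ_σ|v|), clipped to [10, 100] km²/yr;
  clipping is how the documented parameter range is reconciled with the
  velocity-scaled closure.
* Snapshots are taken at the first step crossing each 10-yr boundary (the
  10-day step does not divide 10 yr exactly); recorded times are the true
  step times. Time is integrated forward in elapsed years and reported as
  ka BP.

Default parameters: ρ_c,max = 5 P/100 km², ε = 0.4, η = 2.5, α = 20
(drift scaling, treated as an opaque calibration constant in the internal
unit system), γ = 0.1 yr⁻¹, D ∈ [10, 100] km² yr⁻¹ with κ ≈ κ_l ≈ 1 and
κ_σ ≈ 0.1, r_max = 0.01 yr⁻¹, Δt = 10 days, outputs every 10 yr, arrival
threshold 0.4 P/100 km², occupation level 1 P/100 km². The default run
window is 45–25 ka (start configurable), seeded with 5 000 persons in a
150-km Gaussian; phase switch P1→P2 at 38 ka (hard switch, no cross-phase
blending).

## Ensembles and diagnostics

The perturbed-parameter ensemble varies ρ_c,max, α and the diffusivity
range (as a common scale factor on both clip bounds) over a full factorial
of 5 evenly spaced levels within ±50% of the base values (125 members).
Members are deterministic and order-invariant; a failed member is recorded
and excluded from summaries with a warning. Arrival-time statistics use
the population (divide-by-n) standard deviation over the members that
reached a cell; flux maps are stored per year and reported per decade
(factor 10 exactly); sites map to cells by half-open binning — no
sub-cell interpolation at a 0.5° working resolution.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* the method needs: four bioclim
predictors with latitudinal trends plus seeded smooth Gaussian noise
(spectrally smoothed white noise), a stadial offset deep enough that the
−2 °C bound crosses the domain interior, Bernoulli site sampling from a
known truth niche model, a periodic (square or sine) proxy series on the
20-yr step, and simple ridge topography with optional ocean margins.
Default study conditions: a 40×30-cell 0.5° domain (0–20°E, 34–49°N),
interstadial southern-edge temperature 15.5 °C with a 0.8 °C/deg lapse,
stadial offset −12 °C (a Heinrich-like excursion placing roughly the
northern half of the domain outside the envelope), 120 sites, square-wave
forcing with a 1 000-yr period, and a 5 000-person seed at (6°E, 44°N).

It does **not** emulate real geography, the observed ice-core waveform,
dating uncertainty, spatially correlated site-discovery bias, or
culture-dependent accessibility. Passing tests therefore demonstrate that
the implementation realises the stated model and recovers known truths
under the model's own assumptions — not that the model is an adequate
description of any particular archaeological record.

## Design choices made where the design was open

* Discretisation (upwind/centered finite volume, splitting order
  transport-then-growth, exponential-Euler drift) chosen for positivity,
  exact conservation and dt-robustness.
* r = r_max Φ_Av/ρ_c,max: the availability layer carries density units, so
  it is normalised by the capacity ceiling to make r_max the attainable
  maximum growth rate.
* Uninhabitable decay at rate r_max (see HEP layers above).
* The isotope weight is held at the nearest 20-yr step rather than
  interpolated (the proxy is itself a step series).
* Ensemble perturbation design (±50%, 5 levels, full factorial) follows
  from the 125-member convention.
* NetCDF I/O uses the NETCDF3-classic backend; all rasters also round-trip
  through plain CSV.

## Known limitations

* First-order upwind advection is diffusive; sharp fronts are smeared by
  O(Δx) numerical diffusion (front-speed checks bound the consequence at
  the 10% level on corridor tests).
* Diffusivity is isotropic; directional dispersal emerges only through the
  drift term.
* No age structure, group interactions, or interaction with indigenous
  populations; no sea crossings.
* Arrival times are quantised to the 10-yr snapshot interval.
* Quadratic-logistic extrapolation far outside the training climate is
  uncontrolled by construction; the a-priori envelope modifier is the
  guard rail.
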