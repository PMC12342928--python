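# Methods

This note documents the models implemented in `oceanch4`, the defaults and
numerical choices behind them, what the synthetic scenarios emulate, and
what the tests do and do not establish about real cruise data.

## Water-mass decomposition (OMP)

Each sample is treated as a linear mixture of 2–7 predefined endmember
water masses conserved in potential temperature, salinity, dissolved
oxygen, phosphate, nitrate and silicate.  The property-conservation system
plus a mass-conservation row is solved per sample for non-negative mixing
fractions by Lawson–Hanson non-negative least squares.

Numerical choices:

* **Standardization.**  The six properties have incommensurate units, so
  each property row is divided by the *population* standard deviation
  (divisor *n*) of that property across the endmember values, then
  multiplied by a user weight (default 1 for all properties).  The
  population convention is fixed and load-bearing: changing it rescales
  the objective and can move near-degenerate solutions.
* **Mass conservation as a soft constraint.**  The Σx = 1 row enters the
  least-squares stack with a weight of 100× a unit property weight
  (configurable).  It is soft deliberately: the mass residual R_M is a
  diagnostic of endmember adequacy, and forcing it to zero would push that
  error into the property residuals.  Increasing the mass weight
  monotonically tightens |R_M| (tested).
* **Degenerate inputs.**  A property with zero spread across endmembers
  carries no mixing information and is excluded with a warning; samples
  with missing properties are flagged as failed rows, never imputed.
  Dominant-mass ties break by endmember order with a flag.
* **Oxygen and nutrients** are quasi-conservative at best; treating them as
  conservative is the standard OMP assumption and the main structural
  approximation of the method.

The solver is cross-checked against an exhaustive 0.01-step simplex grid
search of the same objective: the NNLS objective must dominate every grid
candidate, and the grid optimum must not beat the NNLS solution rounded to
the grid (objective agreement within grid resolution).  The fraction
vectors themselves can differ more than one grid step along nearly flat
directions of the objective; the objective comparison is the meaningful
oracle.

## Tracer kinetics

First-order rate constants come from the tracer turnover fraction divided
by incubation time; the MOx rate is k times the ambient methane
concentration measured in separate vials.  Choices:

* **Killed-control correction on the fraction scale** (not the rate
  scale): fractions are what scintillation counting measures, and the
  incubation time is shared.  Corrected fractions below zero clip to 0
  with a flag — k is physically non-negative.  The correction is
  switchable (on by default) since some workflows use killed controls only
  qualitatively.
* **Incubation time** defaults to 2 days (48-hour dark incubations) but is
  a per-record field.
* **Counting noise** in the generator is Gaussian with sd = √DPM, the
  Poisson approximation appropriate for count rates ≥ 10⁵ DPM.

## Air–sea gas exchange

The equilibrator chain (water-vapor pressure, headspace pCO₂, warming
correction) follows the standard empirical forms given in the README.
Parameterizations not fixed by those forms are isolated in
`gas_constants.py` with their sources, swappable without code changes:
Schmidt-number quartics in seawater (Wanninkhof 2014; Sc(CO₂, 20 °C) =
668), CH₄ solubility for equilibrium concentration (Wiesenburg & Guinasso
1979, nmol l⁻¹ coefficients), CO₂ K_H (Weiss 1974).

Unit pipeline: fluxes are computed natively in µmol m⁻² h⁻¹
(k [cm h⁻¹] × 0.01 × Δ[µmol m⁻³]) and converted exactly to mmol m⁻² d⁻¹
(×0.024) and mmol m⁻² y⁻¹ (×8.766, 365.25-day year).  Positive flux is
sea→air.  Wind speed is used instantaneously per record; no averaging
scheme is applied.  Atmospheric CH₄ enters as a dry mole fraction in ppb
and is converted through the solubility fit; a measured equilibrium
concentration can be supplied instead by bypassing that conversion.
Out-of-range inputs (T_eq outside 270–320 K, |SST − T_eq| ≥ 10 °C, SST
outside −2–40 °C) raise rather than extrapolate silently.

## Dilution analysis and driver attribution

The conservative mixing line interpolates CH₄ linearly between two
(salinity, CH₄) endmembers; by default the endmembers are the salinity
extremes of the input table, matching the transect-extreme framing.
Residuals are observed − predicted, so negative means methane deficit
relative to pure mixing.

Variance attribution uses the LMG decomposition — sequential R² increments
averaged over all predictor orderings (the Shapley value of R²) — because
it is the standard order-independent choice when per-predictor "% of
variability" is wanted; shares are reported as percent of *total*
variance, summing to 100·R².  Exact enumeration over subsets is
exponential in the number of predictors and intended for the handful of
hydrographic drivers used here (≤ ~8).  p-values carry no
multiple-testing correction.

## Amendment incubations

Net accumulation is (treatment final − initial) − (control final −
initial) on replicate means, with standard errors propagated in
quadrature.  Control correction is time-matched subtraction of control
means.  Lag detection uses a sustained-exceedance rule — the earliest time
at which the control-corrected mean exceeds `threshold_sd` × pooled
replicate sd and stays above it at every later sampled time — rather than
breakpoint regression, which is unstable at the sparse (≈6-point) time
resolution of typical microcosm experiments.  A consequence worth noting:
with a true lag of L days the detected lag is the first *sampling time*
with signal, i.e. the first time point strictly after L.  Raising the
threshold never shortens the detected lag (tested).

## Methane loss budget

The budget has exactly two loss terms: depth-integrated MOx and sea–air
flux.  Integration is trapezoidal over the bottle depths with the profile
extended to the surface at the shallowest value (flagged) and cut at the
integration depth by linear interpolation; the default integration depth
is 300 m (upper-water-column framing), configurable.  Since
nmol l⁻¹ = µmol m⁻³, the integral is in µmol m⁻² d⁻¹ directly.  When the
sea is a CH₄ sink the flux is floored at 0 in the removal total (removal
sums losses), with a flag.  The MOx share is scale-invariant in its
inputs.

## Synthetic scenarios: what they emulate, and what they do not

The default two-endmember scenario contrasts a warm, saline, nutrient-poor
"Kuroshio" endmember (22 °C, S 34.8, CH₄ 5.15 nmol l⁻¹) with a cold,
fresh, nutrient-rich "Oyashio" endmember (5 °C, S 33.2, CH₄
6.11 nmol l⁻¹); a three-endmember variant adds an intermediate-water
endmember to exercise the full system shape.  These values are plausible
for the Northwest Pacific upper water column but are placeholders —
endmember definitions are configuration, and users with a calibrated
endmember table should supply it.  The underway scenario spans 35–41 °N
with SST 16.8–30.2 °C, salinity 33.2–35.1, in situ pCO₂ 338–360 µatm
(sink of ≈55 µatm against the atmosphere), dissolved CH₄ 5.15–6.11
nmol l⁻¹ and winds 7.31 ± 1.38 m s⁻¹.  The budget scenario constructs 12
stations whose true MOx shares are deterministic normal quantiles with
mean exactly 43.7 % and spread 0.20, with 5 % multiplicative noise on both
loss terms.

Simulated noise is independent Gaussian per property at instrument scale
(e.g. 0.05 °C, 0.01 salinity, 2 µmol l⁻¹ oxygen).  Real sections violate
several of these assumptions: property errors are correlated (sensor
drift), endmember properties themselves vary seasonally, nutrient
non-conservation is systematic rather than random, and underway fields
carry autocorrelated instrument noise that the generator omits entirely
(its underway records are noise-free by design so flux round trips are
exact).  Passing tests therefore establish the correctness of the
arithmetic and the internal consistency of the chain — not that the OMP
error bars or the budget spread transfer to any particular real transect.

## Problem sizes

The test suite and acceptance script use 20-station × 8-depth sections,
200-sample grid-search comparisons, 10³ tracer-bias simulations,
200-record transects and 12-station budget regions.  These sizes put
Monte-Carlo error well below the tolerances asserted while keeping the
whole suite under a minute on one core.

## Known limitations

* No time-dependent OMP, nonlinear mixing, or conversion of in situ to
  potential temperature (inputs are assumed already converted).
* No bubble-mediated flux, wind-product ingestion, or flux-averaging
  schemes.
* The budget has no advection or diffusion terms.
* The LMG decomposition is exact but exponential in predictor count.
* The CLI pipeline assigns the transect-mean sea–air flux to every station
  when no per-station flux table is supplied; supply `fluxes_path` for
  station-resolved budgets.
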