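# Methods

## Isotope conversions

All isotope arithmetic runs through three exactly interconvertible
currencies: δ¹⁵N (‰ vs atmospheric N₂), atom percent ¹⁵N, and the raw
¹⁵N/¹⁴N ratio.  The reference ratio of air N₂ is fixed at
R_air = 0.0036765 and overridable in every function; round trips are exact
to better than 10⁻⁹ relative over the full tracer range.  Instrument-side
corrections (drift, blanks, elemental-standard calibration) are assumed to
have been applied upstream: the package consumes finished δ¹⁵N values.

## Rate estimation and censoring

The volumetric N₂-fixation rate for one treatment bottle is the two-pool
isotope mass balance

    rate = (at%PON_sample − at%PON_control) / (at%N₂ − at%PON_control)
           × (PON / t)

with PON converted from µg N L⁻¹ to nmol N L⁻¹ using an atomic mass of
14.0067 g mol⁻¹.  The estimator is linear in the PON concentration and
invariant to jointly scaling filter mass and filtered volume.  No
temperature correction is applied: on-deck incubation temperatures are
taken to track in-situ conditions closely enough that the correction would
be smaller than bottle-to-bottle scatter.

Censoring is deliberately conservative.  A bottle is below the limit of
detection when its treatment δ¹⁵N fails to exceed the control by 4 ‰, when
a negative δ¹⁵N co-occurs with a negative computed rate, or when the
computed rate is negative; censored bottles report rate 0, never a
negative value.  The 4 ‰ floor corresponds to several times the batch
standard reproducibility of the IRMS measurement (≤ 0.5 ‰), so the
false-positive probability for a truly inactive bottle is negligible —
the suite verifies < 5 % empirically at σ = 0.2 ‰.  The implied minimum
detectable rate is strictly positive, falls with label strength, and
rises with PON concentration (fixed new N diluted into more biomass).

Duplicate treatments at one station/depth are summarised by the mean of
the retained (non-censored) rates with SE = sd/√n.  The mixed case — one
duplicate retained, one censored — is not covered by a stated convention;
the package averages the retained bottles and attaches a
`partially-censored` flag, preserving data while exposing the asymmetry.
A missing control falls back to a configurable natural-abundance baseline
(default 0 ‰) with a `default-control` flag.

N-loss experiments are reduced to OLS slopes of ²⁹N₂ and ³⁰N₂
concentration against time (≥ 3 points; negative slopes censored to 0).
Translating isotopologue production into anammox vs denitrification
removal rates requires isotope-pairing conventions that depend on the
amendment design; the package intentionally stops at production slopes and
lets the caller supply a pairing convention, taking the budget's removal
term from configuration instead.

## Profile features

Profiles are discrete Niskin/CTD casts (5–25 m spacing), metres positive
downward.  Interpolation is linear in depth for all analytes except PAR,
which is log-linear because light decays exponentially; on a pure
exponential profile the extracted euphotic depth (1 % surface irradiance)
equals ln(100)/k exactly.  The thermocline is the midpoint of the sampling
interval with maximum |ΔT/Δz| (ties to the shallowest; profiles with max
gradient below 0.01 °C m⁻¹ are treated as isothermal), matching discrete
sampling rather than a fitted functional form.  Oxygen boundaries are the
first linear-interpolated crossings of 10 µM (oxygen-deficient) and 1 µM
(anoxic).  The primary chlorophyll maximum is the global maximum above the
anoxic boundary; a deep anoxic maximum is reported only when a local peak
below the boundary stands ≥ 20 % above the chlorophyll floor between the
boundary and the peak (deep maxima are otherwise identified visually;
20 % is this package's explicit prominence default).  Below-detection
nutrient values are stored at the detection limit with a censored flag and
enter ratio and gradient computations as 0, flagged — no substitution
rule being stated for the source data, zero-substitution is the most
conservative choice for N-deficit classification.  N:P classification
counts samples with molar DIN:SRP (DIN = NO₃⁻ + NO₂⁻ + NH₄⁺ where
measured) below the Redfield ratio of 16; samples with censored SRP but
positive DIN are excluded as undefined.

## Fluxes

Depth integration is trapezoidal with interval boundaries obtained by
linear interpolation when bracketed and constant extension (flagged) when
not; censored rates integrate as 0.  The integral is additive over
contiguous intervals and agrees with a fine-grid quadrature oracle to
10⁻⁹ relative on piecewise-linear profiles.  Default intervals: 0–50 m
(euphotic), 125–175 m (anoxic), 0–175 m (total).

Diffusive fluxes use Fick's law with a scalar K_z defaulting to
10⁻⁵ m² s⁻¹, the lake-wide thermocline-average turbulent diffusivity; a
buoyancy-frequency-based K_z can be supplied per station but no functional
form is imposed.  Gradients are OLS fits over ±15 m around the interface —
wide enough to span two to three sampling intervals, narrow enough to stay
inside the nitracline.  Fluxes into the euphotic zone are positive when
concentration increases downward.  At upwelling stations the total upward
nitrate flux adds c·v, with c the nitrate concentration at the interface
and v the configured upwelling velocity (defaults 0.05 and 0.1 m d⁻¹ at
stations 8 and 9).  In the pipeline driver the euphotic nitrate interface
is the thermocline (falling back to the euphotic depth), nitrate supply
into the anoxic zone is reported as the magnitude of the diffusive flux
across the anoxic boundary, and the ammonium interface is placed at the
depth of steepest ammonium increase below that boundary.

## Budget

Basin means are arithmetic station averages with SE = sd/√n, reported in
mmol N m⁻² d⁻¹ at two decimals (full precision retained internally).
Stations 1–6 form the north/central basin and 7–9 the south; membership is
configuration.  External inputs default to daily downscaled literature
loads: deposition 0.13 mmol N m⁻² d⁻¹ for both basins, rivers 0.02 (north)
and 0.003 (south).  (The source literature also quotes rounded combined
deposition+river inputs of 160 and 140 µmol m⁻² d⁻¹; the per-term table
values, which sum to 150 and 133, are used here.)  Total new production is
the sum of euphotic fixation, upward nitrate flux, deposition and rivers;
SEs of derived sums propagate in quadrature, no propagation rule being
stated for the source table.  Diagnostics divide anoxic-zone fixation and
euphotic-zone fixation by the fixed-N removal rate, reported as
percentages.

## Correlation

Cross-station tests use Spearman rank correlation with a one-sided
alternative fixed a priori.  For n ≤ 9 the p-value is exact: all n!
permutations of one rank vector are enumerated (average ranks on ties,
≥-with-tolerance counting), which is feasible because 9! = 362 880.  For
larger n a one-sided t approximation with n − 2 degrees of freedom is
used.  ρ² is reported alongside ρ, and significance is flagged at both the
95 % and 80 % confidence levels, the two thresholds used for these
transect comparisons.  No multiple-testing correction is applied.

## Synthetic data

Regime templates parameterise the two end members: stratified
(thermocline 55 m, euphotic depth 46 m, oxygen-deficient boundary 115 m,
surface chlorophyll peak plus a deep anoxic peak at 150 m) and upwelling
(thermocline 20 m, euphotic depth 30 m, boundary 135 m, single productive
peak at 25 m, no deep peak).  Nitrate rises sigmoidally below ~50 m
(shallower under upwelling) to a maximum of 8.5 µM near 100 m and is drawn
down below ~160 m; ammonium rises below ~155 m; PAR decays exponentially.
Noise defaults: lognormal σ = 0.05 on concentrations, Gaussian 0.05 °C on
temperature, Gaussian σ = 0.25 ‰ on δ¹⁵N (consistent with IRMS standard
reproducibility better than 0.5 ‰).  Detection limits (NO₃⁻ 0.20, SRP
0.22, NH₄⁺ 0.34, NO₂⁻ 0.03 µM) censor generated values exactly as the
readers expect.

Incubation bottles are generated by inverting the mass balance: the
imposed true rate fixes the treatment at%PON, which is converted back to
δ¹⁵N and perturbed with IRMS noise; with zero noise the estimator recovers
the truth exactly, making the inverse a self-check rather than a shared
code path (the forward estimator never calls the inverse).  Labels default
to 6.3 at% (4.7 at% available as the alternative campaign value).  The
default expedition imposes a 5× euphotic fixation contrast between
stratified stations 1–6 (peak 10 nmol L⁻¹ d⁻¹ at 20 m) and upwelling
stations 7–9 (peak 2 nmol L⁻¹ d⁻¹), with lognormal σ = 0.1 between-station
amplitude scatter — realistic station-scale variability that keeps the
realized basin contrast near the injected value.  Anoxic-zone rate peaks
(0.5 / 0.1 nmol L⁻¹ d⁻¹ at 145 m) sit near the 4 ‰ detection floor by
construction, so deep estimates are frequently censored, as in real anoxic
incubations.  A single integer seed spawns one independent RNG stream per
data product; output is reproducible byte for byte.

What the generator does **not** emulate: bubble-equilibration kinetics of
¹⁵N₂ dissolution (the label at% is treated as measured per bottle),
trace-O₂ inhibition in anoxic bottles, internal-wave nutrient injection,
horizontal advection, and any mechanistic lake physics.  Passing tests
therefore demonstrate correctness of the estimators and plumbing under the
stated noise model, not fidelity of any particular field dataset.

## Problem sizes and numerical choices

Monte-Carlo checks use 1 000 replicates for rate-recovery calibration,
2 000–10 000 for detection-limit false positives, and 1 500 null
simulations (n = 7) for permutation-test calibration — sizes chosen so
Monte-Carlo SEs are well below the effects being tested.  Ties in ranks
use average ranks; permutation counting uses a 10⁻¹² tolerance; OLS
everywhere is scipy's `linregress`.  Degenerate inputs (empty intervals,
constant series, all-censored depths, unknown stations, non-positive
ratios) raise `ValueError`/`KeyError` with named fields, or return
explicitly flagged absent values where absence is scientifically
meaningful (isothermal profiles, fully oxic columns).

## Known limitations

* The anammox/denitrification partition of N removal is out of scope; the
  budget's removal term must be supplied.
* K_z is a scalar; spatially resolved turbulence requires per-station
  overrides.
* The gradient window (±15 m) and ACM prominence (20 %) are heuristics
  matched to 5–25 m sampling; denser casts may warrant narrower windows.
* Basin SEs reflect station-to-station scatter only; bottle-level SEs are
  reported but not propagated into basin means.
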