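# lakenfix

Tracer-to-budget analysis of biological nitrogen fixation in stratified and
upwelling lake basins.

Field surveys of N₂ fixation in large lakes and oceans combine three kinds of
measurement: ¹⁵N₂ tracer incubations that yield volumetric fixation rates,
hydrographic depth profiles that yield nutrient fluxes and water-column
structure, and counts of the filamentous cyanobacteria that do most of the
fixing.  `lakenfix` turns those raw observables into basin-scale nitrogen
budgets, for biogeochemists who need censored, replicated rate estimates and
defensible flux arithmetic rather than spreadsheet one-offs.  The package was
built around a north–south transect of Lake Tanganyika — a deep meromictic
rift lake whose permanently stratified northern basin and wind-driven
upwelling southern basin form natural end members — but every stage is
generic.

## The model

**Rates.**  Each incubation set is one unamended control bottle plus duplicate
treatments amended with ¹⁵N-labelled N₂.  The bulk fixation rate follows the
isotope mass balance

```
rate = (at%PON_sample − at%PON_control) / (at%N₂ − at%PON_control)
       × (PON concentration / incubation time)        [nmol N L⁻¹ d⁻¹]
```

with atom-percent values converted from EA-IRMS δ¹⁵N via
R = R_air·(δ/1000 + 1), at% = 100·R/(1+R).  Enrichments below the detection
limit (treatment δ¹⁵N < control δ¹⁵N + 4 ‰, or negative δ/rates) are censored
to zero.  N-loss experiments are summarised by OLS slopes of ²⁹N₂ and ³⁰N₂
concentration versus time.

**Fluxes.**  Volumetric rates are integrated trapezoidally over the euphotic
(0–50 m), anoxic (125–175 m) and total (0–175 m) intervals.  Turbulent
diffusive nutrient fluxes follow Fick's law, J = K_z·∂C/∂z, with the gradient
fitted by OLS over a ±15 m window around the interface and
K_z = 10⁻⁵ m² s⁻¹ by default; upwelling stations add an advective term
Q = J + c·v.

**Budget.**  Station fluxes are averaged into basins (stations 1–6
north/central, 7–9 south), combined with literature atmospheric and riverine
inputs, and reported as a two-compartment source/sink table with total new
production and two diagnostics: anoxic-zone fixation as a percentage of
fixed-N removal, and euphotic-zone fixation export as a percentage of
removal.  Cross-station relationships use a one-sided Spearman test with an
exact permutation null (n ≤ 9).

A synthetic-data module generates complete expeditions from stratified and
upwelling regime templates with known imposed rate fields, so the whole chain
is testable without field data.

## Worked example

```python
import numpy as np
from lakenfix.synthetic import generate_expedition
from lakenfix.pipeline import run_pipeline

exp = generate_expedition(seed=1)            # 9 stations, truth stored
res = run_pipeline(exp.incubations, exp.profiles,
                   timeseries=exp.timeseries, colonies=exp.colonies)
print(res["table"])
```

```
Nitrogen fluxes (mmol N m-2 d-1)
                        north_center            south
Euphotic zone
  n_fixation            0.27 ± 0.01 (n=6)       0.05 ± 0.00 (n=3)
  no3_flux              0.20 ± 0.00 (n=6)       0.35 ± 0.09 (n=3)
  deposition            0.13                    0.13
  rivers                0.02                    0.00
  total_new_production  0.62                    0.53
Anoxic zone
  n_fixation            0.01 ± 0.00 (n=6)       0.00 ± 0.00 (n=3)
  no3_flux              0.07 ± 0.01 (n=6)       0.15 ± 0.01 (n=3)
  nh4_flux              0.05 ± 0.00 (n=6)       0.04 ± 0.00 (n=3)
  n_removal             -                       -
```

The stratified basin fixes ~5× more N₂ in its euphotic zone than the
upwelling basin (0.27 vs 0.05 mmol N m⁻² d⁻¹ here, against an imposed truth
contrast of 5.05 for this seed), while the upwelling basin receives the
larger upward nitrate flux — the trade-off the pipeline is designed to
quantify.  `res["rates"]`, `res["features"]`, `res["fluxes"]` and
`res["correlations"]` hold the per-stage tables, each with censoring and
quality flags propagated.

The same chain is available from a shell:

```
lakenfix --seed 1 simulate --outdir data/
lakenfix run-all --indir data/ --outdir out/
```

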