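# rangeland

Monthly coupled simulation of herbaceous forage growth and ruminant
grazer energy balance for semi-arid rangelands, aimed at rangeland
ecologists and managers who want to ask: *how many cattle can this site
carry, what grazing history explains the biomass I measured, and how
much forage surplus is left for wild grazers under changing rainfall?*

## What it computes

The simulator advances a one-hectare patch at a monthly timestep.
A reduced grassland production stage grows live shoot biomass from a
texture-derived soil-water bucket and a unimodal temperature response,
senesces it into standing dead, and applies three grazing feedbacks
(production penalty, root:shoot shift, shoot-nitrogen boost).  A
GRAZPLAN-family ruminant stage selects a diet from the live and
standing-dead pools — intake limited by relative availability
`1 − exp(−B/b_sat)` and relative ingestibility
`1 − q·(d_ref − digestibility)` — and scores each month by **diet
sufficiency**

```
diet_sufficiency = (ME_intake − ME_req) / ME_req
```

positive when the herd can gain weight, negative when it loses, exactly
−1 when grazing is halted.  A residual-biomass management threshold
(default 300 kg/ha) truncates offtake so grazing never strips a site
bare.

On top of the simulator:

- **Back-calculate management** (`RangelandModel.fit`): iteratively
  adds/removes grazing events and then tunes their intensity until the
  simulated standing biomass matches a single field measurement; fit
  quality is reported as the change in mean squared error of prediction
  (ΔMSEP) and the mean bias (negative = overestimation).
- **Precipitation scenarios**: the precipitation concentration index
  `PCI = 100·Σp²/(Σp)²` (100/12 for uniform rain, 100 for one wet
  month), total-rainfall scaling, PCI redistribution at fixed total,
  and a factorial 6 × 6 scenario grid (20%–120% of empirical total ×
  20%–120% of empirical PCI).
- **Viability analysis**: the maximum stocking density with at most one
  diet-insufficient month in a 24-month run (bisection on the density
  grid), and the **viable wild grazer density** — maximum viable minus
  reported cattle density — compared across drought (40% rainfall), wet
  (160%), and wildlife-/livestock-dominated management extremes
  (0.07 / 0.43 cattle/ha).

A synthetic-site generator (`make_site`) emulates an East-African
bimodal-rainfall ranch so everything is testable without field data.

## Worked example

```python
import rangeland as rl

site = rl.make_site(rl.SyntheticSiteSpec(seed=0))   # 600 mm bimodal site
model = rl.RangelandModel.from_site(site)

# calibrate a grazing history to one biomass measurement
res = model.fit(rl.BiomassTarget(2003, 11, 1200.0))
print(res.summary())

v = model.max_viable_density(rl.ViabilityConfig(density_hi=1.0))
print("max viable density:", v.density, "cattle/ha")
```

prints

```
Back-calculated grazing management
==================================
Target biomass                1200.0 kg/ha at (2003, 11)
Simulated (default)           2549.1 kg/ha
Simulated (calibrated)        1189.0 kg/ha
Converged                       True in 17 iterations
Grazing events in schedule         10
dMSEP                      1819985.8 kg^2/ha^2
Mean bias                      10.97 kg/ha
Mean offtake (12 mo)           144.8 kg/ha/month (8.1% of standing)
max viable density: 0.38 cattle/ha
```

Read it as: an ungrazed run predicts 2549 kg/ha standing at the
measurement date; to reconcile that with the observed 1200 kg/ha the
routine inferred ten months of grazing removing ~145 kg/ha/month (about
8% of standing biomass), leaving an 11 kg/ha under-prediction (mean
bias positive = slight underestimate).  The same site supports at most
0.38 cattle/ha before the herd sees more than one energy-deficient
month in two years.

A command-line interface mirrors the library:
`rangeland simulate|backcalc|scenarios|viability|wildlife|fixtures`
(see `rangeland --help`).

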