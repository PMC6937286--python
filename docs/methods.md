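# Methods

## Model structure

The package simulates a one-hectare rangeland patch at a monthly
timestep as two coupled stages.

**Forage production** is a deliberately reduced grassland growth model,
not a full soil-organic-matter ecosystem model: monthly production is

```
production = rue × effective_moisture × temp_scalar × graze_penalty
```

with `temp_scalar = exp(−((T − temp_opt)/temp_width)²)` and
`graze_penalty = max(0, 1 − α·g)` where `g` is last month's realized
grazing intensity (fraction of standing biomass removed).  Production
is split between shoots and roots by a root:shoot ratio
`r = root_shoot_target·(1 + β·g)`; a fixed fraction of live biomass
senesces into a standing-dead pool each month, and the dead pool decays.
Shoot nitrogen is a mixing model — old tissue relaxes toward
`n_live_min` at `n_decline_rate` per month while new growth enters at
`n_live_max` — raised by `γ·g` (compensatory quality response of grazed
swards) and clipped to bounds.  Crude protein is 6.25 × nitrogen.
Live digestibility declines linearly from `digest_live_max` at
`n_live_max` to `digest_dead` at `n_live_min`, so exhausted live tissue
approaches standing-dead quality.

**Soil water** is a single bucket whose plant-available capacity per
notional 30-cm root zone is texture-ordered:
`capacity = 100·(0.35·clay + 0.25·silt + 0.10·sand)` mm.  Plants
transpire a fixed share of the month's rain (`moisture_uptake_rain`)
plus a share of stored water (`moisture_uptake_store`); the remainder
refills the bucket and excess drains.  This form was chosen so three
properties hold exactly: zero input gives zero effective moisture,
saturating rain leaves the bucket at capacity, and
rain = effective moisture + drainage + storage change (closure to
1e-6 mm, verified over randomized months).

**The ruminant stage** uses the GRAZPLAN family of functional forms
with all coefficients exposed in `IntakeParams`: potential intake
`I_max = i_scale·SRW^0.75·condition`, where condition is weight over a
logistic normal-weight-for-age curve (anchored at 7% of mature weight
at birth), capped at 1.2; per-pool intake
`I_max·RA(B)·RQ(d)` with `RA = 1 − exp(−B/1000 kg/ha)` and
`RQ = clip(1 − 1.7·(0.8 − d), 0, 1)`, normalized only when the sum
would exceed `I_max` (so more digestible pools always get at least
their biomass-proportional share); dietary energy density
`M/D = 17.2·d − 1.71` MJ/kg DM floored at zero; maintenance
`ME_req = 0.55·W^0.75` MJ/day, multiplied by 1.15 during gestation
(9 months from the average conception month, repeating every calving
interval) and 1.4 during lactation.  Diet sufficiency is
`(ME_intake − ME_req)/ME_req` on the herd-weighted budget; the
crude-protein content of the selected diet is reported but does not
gate sufficiency, which is an energy measure.

**Coupling order** within a month is fixed: grow → select diets →
truncate offtake at the residual-biomass threshold (proportionally
across pools and classes, so diet composition is preserved under
restriction) → evaluate energy balance on realized intake → record →
feed the realized grazing intensity into next month's growth.  With
zero intake the sufficiency is exactly −1; 0/0 cannot occur because
`ME_req > 0` always.  The whole loop is deterministic; all randomness
lives in the synthetic-site generator.

**Spin-up** repeats a 12-month climatology until the annual peak live
biomass changes by less than 0.1% between years (max 100 years, flagged
and warned on non-convergence).  Two checks back this: equilibria
reached from initial biomasses differing by 5000 kg/ha agree to 2%, and
the equilibrated state is a fixed point of the annual map to 0.5%.

## Back-calculation

Given one observed standing biomass, the routine simulates the site
under the current schedule and compares at the measurement date.  Too
much simulated biomass → add grazing events in ungrazed months within
the window (default 24 months), nearest to the measurement first; when
every window month is grazed, raise intensity uniformly in steps of
0.05 until the target is bracketed, then bisect the uniform intensity.
Too little biomass → mirror (remove farthest-first, lower intensity).
Convergence is `|sim − target| ≤ max(10 kg/ha, 1% of target)` within
40 iterations; failure returns the last schedule flagged.  Design
choices that were genuinely open: event addition nearest-first
(recent grazing affects measured biomass most), uniform rather than
per-event intensity modification, and the spin-up forcing uses the
candidate schedule's month-of-year mean intensities so the equilibrated
state is consistent with the history being proposed.  Fit metrics are
ΔMSEP (mean over targets of the squared-error reduction from default to
calibrated schedule; positive = improvement) and mean bias (observed −
predicted; negative = overestimation).

## Scenarios

PCI redistribution uses a power transform `pᵢ′ ∝ pᵢ^γ` rescaled to the
original total, with γ found by Brent root search (γ > 1 concentrates,
γ < 1 flattens).  It was chosen for smoothness, exact total
preservation and monotonicity of PCI in γ.  Limits are handled
explicitly: targets below the 12-month floor 100/12 clamp to the floor
with a warning (so the full 6 × 6 grid always exists); targets below
the floor implied by zero-rain months, or above the ceiling implied by
ties among the wettest months, raise with a diagnostic.  PCI class
boundaries are fixed as: < 11 uniform, [11, 16) moderate, [16, 20]
irregular, > 20 strongly irregular.

## Viability

Maximum viable density is the largest density on the search grid
(default resolution 0.01 animals/ha in [0, 2]) with at most one
diet-insufficient month over 24 months, found by bisection on grid
indices — exactly equivalent to exhaustive grid search under
monotonicity of `months_insufficient` in density, which the search
verifies on every density it simulates and refuses to exploit if
violated.  The tolerated number of insufficient months is configurable
because "viable" is a management judgement, not a biological constant.
Each site is spun up once ungrazed and all candidate densities start
from that common equilibrium.  The extreme-scenario table fixes
rainfall at 40% / 160% of baseline and management at 0.07 / 0.43
cattle/ha; because the wild-grazer index is linear in reported density
with slope −1, the management extremes differ in viable wild density by
exactly 0.36 animals/ha at fixed climate.

## Parameter defaults and calibration of the synthetic site

The synthetic site emulates a semi-arid East-African bimodal-rainfall
ranch: 600 mm/yr split between long rains (April) and short rains
(November) by a two-Gaussian month-of-year mixture, 22 °C mean
temperature with 3 °C seasonal swing, sandy-loam or clay-loam texture
presets, a zebu-type herd (breeding cows SRW 350 kg with heifers and
steers), and a 300 kg/ha residual-biomass rule.  Noise, when enabled,
is lognormal per month; the default is noise-free so annual totals are
exact.

Free defaults were set once so the site sits in the regime such
rangelands actually occupy, and then frozen:

- `rue = 5.0` kg DM/ha per mm effective moisture.  Combined with
  `moisture_uptake_rain = 0.9` and the temperature scalar this realizes
  a rain-use efficiency near 4 kg DM/ha/mm — mid-range for semi-arid
  grasslands — and a peak standing crop of ≈2.3 t/ha at 600 mm.
  Substantially smaller values leave the site unable to support any
  cattle at the stocking densities reported for such regions
  (0.07–1.33 animals/ha), which would make the viability analysis
  degenerate.
- `i_scale = 0.14` kg DM/day per kg^0.75: a potential-intake ceiling of
  ≈3.5% of body weight, the upper end of cattle dry-matter intake.
  This is the ceiling under ideal forage; realized intake on seasonal
  forage is far lower.
- `root_shoot_target = 0.5` (two-thirds of production to shoots),
  `senescence 0.15/mo`, `dead decay 0.10/mo`, `root turnover 0.10/mo`.
- Grazing feedbacks `α = 0.8, β = 0.2, γ = 0.1`; digestibility bounds
  0.65 (lush live) / 0.45 (standing dead); shoot N 0.020–0.005 g N/g.
- Days per month 30.44 for converting daily intake to monthly offtake.

With these defaults the default site's maximum viable density is
0.38 cattle/ha at baseline rainfall, falling to zero under a 60%
rainfall reduction and rising to ≈0.9 under a 60% increase — the herd
is more vulnerable at higher densities and drier climates, and both
monotonicities are asserted in the test suite.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the study system — bimodal
seasonality, realistic magnitudes of rainfall, biomass, intake and
stocking — but not real weather sequences, spatial heterogeneity,
multi-species herds, browse, fire, or inter-annual rainfall
variability (scenario years repeat identically, so spin-up and
experiment see the same climatology).  Tests passing on synthetic sites
therefore demonstrate the internal consistency, conservation laws,
monotonicities and recovery behaviour of the machinery, not predictive
skill against field measurements, which requires site data the package
does not ship.

## Numerical choices and limitations

Tolerances: mass/water closure 1e-6; spin-up 0.1% on annual peak;
PCI root-finding to machine precision with a 1e-3 acceptance band;
calibration max(10 kg/ha, 1%).  Degenerate inputs are handled
explicitly: all-zero precipitation years make PCI undefined (error),
bare ground yields a zero-intake diet (not an error), an unreachable
biomass target (above the ungrazed trajectory) flags non-convergence
since no upward lever exists.  The herd is static — no weight dynamics,
demography, milk yield or supplementation; a hungry herd is represented
only by negative diet sufficiency.  One forage type only; woody
vegetation and browsing herbivores are out of scope.  Problem sizes in
the shipped tests (24-month horizons, 20-site calibration batches,
0.01-density grids) complete in seconds and are the sizes the analysis
routines are intended for.
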