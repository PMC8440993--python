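# Methods

`divegas` estimates N₂, O₂ and CO₂ partial pressures (tensions) in the blood
and major body compartments of diving sea turtles — loggerhead (*Caretta
caretta*), leatherback (*Dermochelys coriacea*) and green (*Chelonia mydas*) —
over arbitrary time-depth profiles, and derives end-dive supersaturation
metrics that index the risk of gas-embolism (GE) formation. It belongs to the
family of perfusion-limited compartmental gas-exchange models developed for
marine mammals and penguins, adapted to chelonian anatomy (faveolar lungs,
reptilian blood O₂ carriage, turtle compartment sizes).

## Model structure

Gas moves around the circulatory loop

```
lung gas ⇄ arterial blood ⇄ {brain, fat/bone, central circulation, muscle} ⇄ mixed venous blood ⇄ lung
```

driven purely by partial-pressure gradients. Each compartment is a homogeneous
tissue exchanging with its blood supply in a perfusion-limited way: the blood
leaving a compartment carries the compartment's tension, so each tension
relaxes toward arterial with rate

k = Q̇ᵢ · S_blood / (Vᵢ · S_tissue)   (s⁻¹),

where Q̇ᵢ is the compartment's blood flow, Vᵢ its volume and S the Ostwald
solubilities. The four compartments are sized from a generic-turtle body
composition (blood 7.0%, brain 0.06%, fat/bone 30%, central circulation 9%,
muscle as the 53.94% remainder of body mass; obese and emaciated variants move
fat to 40%/20%). Blood is split 33% arterial / 67% venous.

### Numerical scheme

The integrator advances at dt = 1 s (configurable; the depth series is
regularized to 1 Hz). Each step moves a blood "package" ΔV = Q̇·dt around the
loop with piecewise-constant coefficients:

1. the package leaves the venous reservoir at its tension;
2. at the lung the unshunted fraction equilibrates with the faveolar gas
   (Hill-curve content for O₂, linear solubilities for N₂/CO₂), debiting or
   crediting the lung gas store;
3. the package mixes into the arterial reservoir, which feeds the tissues;
4. tissue tensions update by the analytic exponential of the perfusion
   equation within the step (unconditionally stable); O₂ is consumed and CO₂
   produced at the phase metabolic rate, drawing on dissolved plus, in muscle,
   myoglobin-bound stores;
5. the compartment effluents merge into the venous reservoir.

Every ml (STPD) leaving one store is credited to another, so **total N₂ is
conserved exactly (to floating-point rounding) during submerged phases** —
this is a structural property of the package scheme, not a tuned tolerance.
The system is open only at the surface, where breathing is instantaneous: the
moment depth reads 0, lung composition and arterial blood snap to the surface
boundary condition (PN₂/PO₂/PCO₂/PH₂O = 0.741/0.164/0.033/0.062 ATA, summing
to 1 ATA), while tissue recovery proceeds by the same perfusion equations at
surface cardiac output and metabolic rate.

Two sampling points are distinguished from the reservoirs behind them:
*arterial* tension is the lung effluent, (1−shunt)·P_fav + shunt·P_venous —
what an arterial sample reads — and *mixed venous* tension is the
instantaneous flow-weighted confluence of compartment effluents — what a
pulmonary-artery sample reads. The reservoir tensions (`*_arterial_pool`,
`*_venous_pool`) evolve more slowly and carry the blood's share of the gas
inventory.

### Lung mechanics

Total lung capacity (TLC) divides into a maximum faveolar volume and a
conducting-airway dead space (7% of TLC for all species). Under pressure the
total gas volume follows Boyle's law while the airways, being stiffer, shrink
toward a residual fraction:

VD(P) = VD₀ · (f_min + (1 − f_min) · (1 + (P−1)/|Kp|)^(−n)),

with the cited airway-compliance constants Kp = −6.44, n = 0.74 and a residual
fraction f_min = 0.20. The faveoli hold the remainder, VfA = max(0, V_tot −
VD); when the airways claim all the gas the lung has collapsed (VfA = 0) and
exchange stops entirely. The cited faveolar compliance constants
(a = 1.04, b = 0.20, c = 1.21) are carried on the geometry for reference; the
realization treats the faveolar space as freely compliant, which is what makes
airway stiffness the collapse mechanism.

The pulmonary shunt follows a derecruitment picture — compressed faveolar
units empty completely rather than all units shrinking uniformly — so the
shunted fraction is the share of the pressure-scaled faveolar gas that the
airways have claimed:

shunt = s₀ + (1 − s₀) · (1 − VfA / VfA_ref)^γ,  VfA_ref = V_tot · VfA₀/(VfA₀+VD₀),

with γ = 1 and baseline s₀ = 0. Because turtles can also open a right-to-left
intracardiac shunt whose regulation is not understood, this pulmonary shunt is
an *effective* (pulmonary + cardiac) exchange impairment, calibrated once
against the published depth anchors for a half-inflated green-turtle lung:
exchange largely open at ≤30 m (shunt ≈ 0.36 at 30 m), largely closed from
90 m down (≈ 0.85), collapse just past 90 m (114 m). f_min and γ are the two
calibration constants; both live in `LungShape` and are logged with every run.
An earlier candidate family, shunt = (1 − VfA/VfA_max)^γ, cannot satisfy both
anchors without making N₂ uptake *decrease* beyond ~110 m at full lung
inflation, contradicting the observed deepening of end-dive PN₂; the
derecruitment normalization keeps uptake monotone in depth well past 160 m.

### Circulation and metabolism

Control surface cardiac output is 7 ml·min⁻¹·kg⁻¹ for every animal (the value
the allometric relation sQ̇tot = (Q̇_ref/M_ref)·(M/M_ref)^(−0.25) returns at the
1.2 kg reference; the allometric form itself is available as
`surface_sqtot()` and drives the forced-dive scenario's 3.42). While diving
the total falls to 5% and the distribution shifts from 60/34/4/2 to
92.8/5.0/2.0/0.2 % (central/muscle/brain/fat-bone). Metabolic rate is 4.23 ml
O₂·min⁻¹·kg⁻¹ of compartment tissue at the surface and 5% of that (0.21)
while submerged; CO₂ is produced at RQ (default 1.0) times the O₂ actually
consumed. O₂ is carried by hemoglobin (Hill exponent 2.7, species P50 of
25/40/47 mmHg) plus a dissolved term; muscle adds hyperbolic myoglobin
carriage (Mb P50 fixed at 2.75 mmHg — a literature-typical value, exposed in
config, since no chelonian measurement is available).

A structural property of these published values deserves note: the surface
metabolic rate (4.23) exceeds the O₂ transport capacity of the surface
cardiac output (7 ml·min⁻¹·kg⁻¹ × ≈0.12 ml O₂·ml⁻¹ ≈ 0.84 ml
O₂·min⁻¹·kg⁻¹). Any strictly perfusion-limited model must therefore pin the
poorly perfused, high-mass compartments (muscle, fat/bone) at PO₂ = 0 at the
surface steady state, with consumption limited to delivery (flagged as
`o2_exhausted_*` events). N₂ — the gas that matters for embolism, with no
metabolic source or sink — is unaffected and sits at 0.741 ATA everywhere at
the surface. The packaged initial condition is the exact fixed point of the
discrete step map, so an all-surface simulation is stationary to machine
precision.

### Gas constants

Solubilities are not reported for sea turtles; literature-standard Ostwald
coefficients are the defaults (N₂: 0.0144 blood/lean, 0.067 fat; O₂ dissolved
0.0236; CO₂ effective 0.47 ml·ml⁻¹·ATA⁻¹ — a single effective CO₂ solubility
stands in for the full dissociation curve). Hemoglobin concentrations are
read as g·ml⁻¹ (e.g. 0.156 g/ml = 15.6 g/dl). Water vapor is held at
0.062 ATA at all depths; faveolar dry-gas pressures share P_amb − PH₂O in
proportion to the lung store. All of these live in `GasConstants` and are
overridable.

## Dive records

Tag records (4 or 10 s sampling) are linearly interpolated to 1 Hz, then 2 m
are subtracted and the result clipped at 0, so that every breathing event
reads depth 0 (tethered tags and 1 m resolution otherwise leave surfacings at
small positive depths). A dive is any maximal run of samples with depth > 0 —
deliberately not a threshold definition, because GE risk changes fastest near
the surface. Dives bin as shallow (< 30 m), medium (30–90 m, boundaries
inclusive) and deep (> 90 m). Dives cut by a record boundary are kept but
flagged truncated and excluded from end-dive metrics.

## End-dive metrics and experiments

The GE-risk index is the mixed-venous PN₂ averaged over the final 5 s of each
dive (shorter dives use all samples and are flagged), aggregated as mean and
maximum per depth bin. Variants change exactly one knob of a control
configuration: body condition (obese/emaciated), surface cardiac output
(10 / 2.5 ml·min⁻¹·kg⁻¹), or the diving fraction (10% "dive-low" / 3.3%
"dive-high" — the published labels rank variants by heart-rate direction, so
*dive-high* is the reduced-flow, reduced-PN₂ variant; the numeric fraction is
always stored alongside the label). Comparisons are percent change,
100·(variant − control)/control. Supersaturation is reported both referenced
to the surface N₂ tension (PN₂/0.741 — the convention under which the
published species maxima 9.40/6.17/5.03 ATA give M-ratios 12.7/8.3/6.8) and
to ambient pressure ((PN₂ − P_amb)/P_amb).

## Synthetic dive bouts

No tag data are redistributable, so seeded synthetic bouts emulate them. A
bout recipe holds, per depth bin, the proportion of dives and the mean ± SD of
dive duration and maximum depth; recipes mirroring each published animal
(Dc1–Dc6, Cc1–Cc3, Cm1–Cm4) ship in `data/bout_specs.yaml`. Durations and
depths are truncated-normal draws (duration floor 10 s; depth truncated to
the bin's interval so realized proportions match the recipe). Dives are
trapezoidal — descent, 40% bottom time, ascent — with a 10 s pause at 15 m on
ascent for dives deeper than 20 m, mimicking the ascent pause observed in all
three species. Surface intervals default to 120 ± 60 s. Bottom-time fraction,
pause and surface-interval parameters are declared defaults, not values
recoverable from published summaries. What the generator does *not* emulate:
dive-shape taxonomy (U/V/W), behavioral sequencing (bout structure,
day/night), seasonality, and surface-interval/dive-duration correlation —
so passing tests demonstrate the model's response to realistic depth/duration
statistics, not to realistic behavioral sequences.

## Problem sizes and determinism

Simulations run at ≈10⁵ 1 Hz samples per second of compute. The packaged
analyses use: 1 h surface and sealed-dive runs for the fixed-point and
conservation checks; a 640-dive, ≈5-day synthetic leatherback bout
(≈200 dives per depth bin) for the depth and cardiac-output structure of
end-dive PN₂; and 500-dive bouts for generator fidelity. All randomness flows
from a single seed through `numpy.random.default_rng`; a given
(recipe, seed) pair reproduces a bout byte-identically.

## Known limitations

- **Absolute tension magnitudes are conservative.** Desk-scale synthetic
  bouts (days, not weeks) and the lumped arterial/venous reservoirs yield
  end-dive mixed-venous PN₂ of ~0.8–0.9 ATA, well below the multi-ATA maxima
  attainable over weeks of real, deep, repetitive diving. Depth ordering and
  variant directions are the reproducible content; single-number magnitudes
  are not.
- Temperature is absent: solubilities, P50 and metabolic rate are fixed at
  warm-water values, though turtles are at least partly ectothermic.
- The intracardiac shunt is folded into the calibrated pulmonary shunt; no
  independent cardiac-shunt control exists.
- CO₂ uses one effective solubility, not a dissociation curve; with the
  transport-limited surface metabolism above, surface tissue PCO₂ fixed
  points are elevated (~0.2–0.3 ATA) — a consequence of the published
  parameter set, not a target quantity.
- Bubble formation, growth and DCS probability are out of scope; the model
  stops at supersaturation.
- Under full shunt the arterial sample reads the venous return, so in the
  forced-dive scenario arterial PN₂ sags after collapse rather than holding a
  plateau; it recovers when exchange reopens on ascent.
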