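# Methods

## Model

`dietsim` implements a static, deterministic, discrete-time microsimulation
of population dietary change. The base case is the observed single-day
intake of a surveyed population: intake lines (person, 8-digit food code,
grams) joined to a food-composition table (per-100 g nutrient values) and
population expansion weights. Every reported quantity is a
population-weighted per-capita mean,

    mean(x) = Σ_p w_p x_p / Σ_p w_p ,

with non-consumers kept in the denominator. Energy (kJ) is computed from the
macronutrients with fixed conversion factors (kJ/g): protein 16.736,
carbohydrate 16.736, fat 37.656, dietary fibre 8.368, alcohol 29.288.
Because published composition values are rounded, the stored energy of a
profile and the value recomputed from its macronutrients differ by a small
closure gap (< 0.5 % in practice); gram-scaling transforms scale the stored
energy, compositional transforms update it by the recomputed delta, and the
recomputed value is authoritative after a scenario transform.

Foods classify into four labels — core food, core beverage, discretionary
food, discretionary beverage — from the discretionary flag and beverage
flag. Two conventions from national survey practice are honoured:

* milk (plain or flavoured) is consumed as a liquid but behaves as a food
  for substitution purposes (protein, calcium, satiety), so milk-family
  items classify as food by default (configurable);
* sports products and meal replacements are discretionary choices but are
  excluded from the "discretionary beverages" reporting column; they carry
  their own flag.

## Scenario families

All transforms are deterministic, order-independent across persons, and run
either per person (`PopulationDataset`) or on a per-capita class-column
table (`AggregateTable`, "aggregate mode").

**Moderation** scales the grams of every targeted discretionary intake line
by `1 − reduction_fraction`; since composition is per-100 g and scales
linearly, an item's nutrients and energy fall by the same fraction. Optional
energy compensation adds back `compensation_fraction` of the *food*-derived
energy deficit (beverage deficits are never compensated — reduced liquid
intake is not behaviourally compensated). Compensation is applied per
person: each person's deficit is distributed over their own pool lines
(default pool: core foods plus the moderated discretionary foods), pro-rata
to base-case pool energy, so added grams follow observed eating patterns. A
person with a deficit but no pool intake is an error. The population-level
primitive `compensate_energy` distributes a scalar deficit over the whole
population pool in the same pro-rata way.

**Substitution** removes `reduction_fraction` of each discretionary line's
grams and adds `ratio(subgroup) × grams_removed` grams of replacement.
Replacement ratios (grams added per gram removed) are explicit inputs, a
scalar or a per-subgroup map; the bundled default is the overall population
value 1.29. `compute_replacement_ratio` estimates a ratio from data as the
quotient of weighted median consumption-line grams (target pool over source
group) — at the consumption-line level, typical discretionary portions
(~100 g) against typical core portions (~130 g) make the 1.29 default
concrete; orientation is configurable because published descriptions of
such ratios are ambiguous. Replacement grams are distributed over the pool
pro-rata to the person's own base-case pool gram shares, falling back to
population shares for persons who consume no pool item. Pools: all core
foods (including milk), or fresh/frozen/canned fruit and vegetables only
(excluding dried fruit, potatoes, legumes); discretionary beverages —
alcoholic ones included — are replaced only by water and fruit/vegetable
juices. No further energy compensation is applied, on the grounds that the
ratios already reflect observed eating patterns.

**Reformulation** changes product composition, not consumption: per
targeted item, (i) `sfa_replace_fraction` of SFA moves into MUFA+PUFA at
the item's own unsaturated split (50:50 when both are zero), total fat
unchanged; (ii) added sugars fall by `added_sugar_reduction`, with free
sugars, total sugars and carbohydrate reduced by the same grams; (iii)
sodium falls by `sodium_reduction`; (iv) alcohol falls by
`alcohol_reduction`; (v) the product loses the removed sugar + alcohol +
sodium (mg→g) mass, unless `sweetener_energy_replacement` restores the
sugar's mass and energy (modelling an energy-equivalent sweetener; the
default models non-nutritive replacement or none); (vi) energy is updated
by the carbohydrate and alcohol conversion factors. Person-level
compositions are re-expressed per 100 g of the reformulated product and
intake grams scale by the mass-retention factor, so deliveries follow the
new recipe exactly. Protein, fibre, total fat and all micronutrients are
invariant by construction.

Sensitivity presets: moderation compensation 0/0.25/0.75; reformulation
lower {25 % SFA, 10 % sugars, 10 % sodium, 25 % alcohol}, primary
{50, 25, 20, 25 %}, upper {75, 40, 40, 50 %}. The upper added-sugar bound
is applied uniformly at 40 %; a per-subgroup override hook exists because
some published bounds go to 100 % for specific product groups. Substitution
has no parameter bounds; its "suite" is the two replacement pools.

## Aggregate mode

Published per-capita tables report parallel columns (total, core,
discretionary, discretionary foods, discretionary beverages) that are *not*
additive: sports products sit inside the discretionary-choices column but
outside the food and beverage columns. Aggregate mode therefore works in
deltas — each transform computes a per-column delta from that column's own
values and the total receives the full delta — rather than assuming the
columns sum. For linear transforms (moderation without compensation,
reformulation) aggregate mode equals person-level mode exactly, which is
tested by brute force; the only exception is the MUFA/PUFA split, which
uses item-level ratios person-wise and the column ratio aggregate-wise
(their sum is identical). Compensation and substitution agree on energy and
mass but distribute nutrients slightly differently, because the aggregate
core column cannot exclude core beverages from the pool (the core
food/beverage split is not published) and aggregate beverage substitution
uses zero-nutrient water as the replacement profile.

Derived metrics: %E is `grams × kJ/g ÷ total energy × 100` (SFA uses the
fat factor, sugar fractions the carbohydrate factor — standard convention);
in class columns the denominator is *total* intake energy, matching
published table layouts. Nutrient density is amount per 1000 kJ as a ratio
of population means; with this estimator the bundled table gives core
choices 469.1 g/1000 kJ. Percent change is `(modelled − base)/base × 100`,
undefined (reported missing) at zero base.

## Synthetic population

Restricted survey microdata is emulated, not parsed. The generator draws,
per person, a Bernoulli consumption indicator and a lognormal portion for
each of 20 food archetypes spanning all four classes (bread, grains, milk,
cheese, apple, vegetables, beef, water, juice, tea/coffee; cake, pie,
chocolate, crisps; cola, fruit drink, thickshake, beer, wine, sports
drink), plus gamma population weights normalised to mean 1
(shape 8 — coefficient of variation ≈ 0.35, a plausible spread for survey
expansion weights). Compositions are written per 100 g with comfortable
invariant headroom; stored energy is exactly the macronutrient-computed
value.

Calibration then makes the dataset reproduce published per-capita class
means (core, discretionary foods, discretionary beverages): one gram factor
per class pins mean intake weight exactly; per-nutrient composition factors
pin protein, fat, carbohydrate, fibre, alcohol, SFA, added sugars, sodium
and all 17 micronutrients. MUFA/PUFA follow the fat factor and total/free
sugars the carbohydrate factor (their class targets are either unpublished
or over-determined by the sugar-chain invariants); a per-food repair step
clips any invariant violation and counts the clips in the generator
manifest. Energy follows the calibrated macronutrients, landing within the
usual closure gap of the published value (≈ 0.3 % at the total level).
Portion medians and consumer fractions were fixed once so that
pre-calibration means sit near the targets (keeping calibration factors
mild) and so that the discretionary:core line-median gram ratio fluctuates
around the 1.29 replacement-ratio default (band 1.04–1.54 across seeds).
Default size: 500 persons, matching the per-capita precision needed by the
property suites; tests use 50–300 persons.

What passing tests on synthetic data do **not** show: robustness to
demographic intake gradients, day-of-week effects, usual-intake variance or
misreporting — none of which the generator models, and the last of which
the modelling approach deliberately leaves uncorrected (misreporting is not
uniform across food groups, so a blanket factor would bias scenario
contrasts).

## Numerical choices and degenerate inputs

* Internal arithmetic is full double precision; rounding to 1 dp happens
  only in the reporting layer.
* The fatty-acid closure `sfa + mufa + pufa ≤ total_fat` carries a
  configurable 2 % tolerance for trans fats and database rounding.
* Zero-gram intake lines are legal and inert; zero-energy pool items
  (water) receive no compensation energy; a reformulated product that loses
  all its mass degenerates to an empty composition.
* Weighted medians take the smallest value whose cumulative weight reaches
  half the total (lower weighted median) — deterministic under ties.
* Moderation composes: applying fraction f twice equals 1 − (1−f)² once.

## Known limitations

* Aggregate mode inherits every rounding artifact of its printed inputs;
  cells derived from a printed column can differ from
  individual-level results by a few tenths of a percent (e.g. an SFA bound
  computed from the discretionary-choices column includes the printed 0.2 g
  beverage SFA that is ≈ 0 at full precision).
* Replacement-ratio estimation is one defensible estimator among several;
  the ratios that matter for substitution results are therefore explicit
  configuration, not derived values.
* Single-day recalls only; no usual-intake adjustment, no variance or CI
  estimation for survey means.
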