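# Methods

This note documents the model implemented in `bmslca`: its structure,
parameters, calibration, numerical choices and limitations. It states no
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Functional unit and system boundary

All footprints are expressed per **1 kg of BMS powder with an energy
density of 21.7 kJ/g**, in kg CO₂-equivalents under GWP₁₀₀. The
production system runs from raw-milk and vegetable-oil production through
dairy processing, packaging and transport to the factory gate
(`CFP_Prod`); the consumption system adds retail transport, baby-bottle
manufacture and in-home sterilisation and preparation (`CFP_Cons`); the
breastfeeding system covers production, distribution and cooking of the
extra maternal food equivalent to 1 kg of powder (`CFP_BF`). Biogenic
carbon uptake is excluded. Because the functional unit is the kilogram of
powder rather than the fed infant, BMS wasted after preparation reduces
the amount of breastmilk that is equivalent to a kilogram of powder and
therefore reduces `CFP_BF`, not `CFP_Cons`.

## Recipe model

The recipe is a point on the simplex of dry-solids fractions over four
ingredients: skim-milk solids, whey protein concentrate, lactose and
vegetable oil (vitamins and minerals, ~2% of powder mass, are excluded
from the mass balance and handled as an optional production add-on).
Nutrient bookkeeping uses energy coefficients of 37 kJ/g for fat and
17 kJ/g for protein and carbohydrate. The packaged ingredient
compositions are calibrated so that the baseline recipe (0.15 / 0.10 /
0.50 / 0.25) reproduces the reference profile — 0.60 g protein, 2.69 g
carbohydrate, 1.19 g fat and 0.08 g ash per 100 kJ at 21.7 kJ/g with 65%
of protein from whey — exactly at printed precision; a consistent
solution exists and is frozen in `data/ingredients.csv`.

Compliance is checked against the permitted infant-formula ranges
(protein 0.45–0.70, carbohydrate 2.30–3.30, fat 1.05–1.40 g/100 kJ, whey
≥ 50% of protein). The recipe sampler draws uniformly on the simplex
(normalised exponentials) and rejects non-compliant candidates; the
sampling scheme is a design choice — the simplest defensible null over
recipes — and its acceptance rate is tested against a dense-grid
enumeration of the feasible volume (step 0.005). Per-recipe footprints
are normalised to the functional unit by rescaling the final footprint by
21.7/E(recipe) (default) or, behind a flag, by rescaling the ingredient
masses entering the process chain; the two differ only through the
per-kilogram stages (packaging, bottles, home energy).

## Dairy mass balance and allocation

The process tree implements the wet-mix/spray-dry route: raw milk is
skimmed (cream co-product); skim milk feeds both the BMS wet mix and
cheese-making (curd co-product); cheese whey is separated into whey
protein concentrate and lactose powder. The tree is solved backwards from
the recipe's ingredient demands: the cheese-milk quantity is set by the
binding whey requirement over all tracked components (protein,
carbohydrate, fat, ash, other, total dry matter), and any whey solids
beyond the demand become a surplus co-product stream. Demands that the
whey cannot supply at any scale (e.g. whey-protein-dominated recipes with
no lactose pull) raise an explicit infeasibility error naming the binding
component. Wet- and dry-matter conservation hold at every step to 1e-6.

Shared burdens (raw milk, and process energy not attributable to a single
product) are partitioned at each step by one of four bases — dry mass
(default), fat+protein, energy content (37/17/17 kJ/g), or economic value
(price × dry mass) — and compose multiplicatively along the tree,
following standard dairy-LCA practice. Process energy attributable to a
single product (whey drying, the BMS spray-dryer) is assigned in full.

**Calibration.** The supplement-level physical constants (milk and cream
composition, skim solids content, cheese split fractions, step energies,
co-product prices) are not printed; they are calibrated once, by
`scripts/calibrate_defaults.py`, so that with the baseline recipe the tree
draws 13.7 kg of raw milk per kg BMS with 6.55 kg (prints as 6.6 at two
significant figures) allocated to the BMS under dry-mass allocation, with
2.9 MJ electricity and 9.6 MJ heat allocated — values consistent with
every published raw-milk and processing stage at printed precision. The
calibrated milk composition is leaner than typical whole milk (the
allocated-share target forces a small cream stream); it is flagged
calibrated and should not be read as a farm-level dairy composition.
Economic prices are calibrated so the economic-allocation variant lowers
the China consumption footprint by ~36% relative to dry mass. The
fat+protein variant gives ~33% as published; the energy-content variant
gives ~6% against the published 12% — with skim-milk cheese the whey
stream is necessarily more energy-dense per kilogram of dry matter than
curd, which bounds how little burden can reach the BMS chain; the
qualitative ordering fat+protein < energy < dry mass is preserved and
tested.

## Country scenarios

Each country configuration holds: the raw-milk emission factor per kg
energy-corrected milk (printed values: NZ 1.09, US 0.73, Brazil 1.28,
France 0.99, after a milk/meat allocation of 88–94% at farm level, taken
as an input); electricity and natural-gas heat factors; a four-oil blend
with per-oil factors embedding the economic allocation of press residues;
the 70/30 tin-can/bag-in-box packaging mix with material masses
calibrated to the common 0.26 kg CO₂e packaging stage; 100-km refrigerated
road legs for raw milk and whey and a non-refrigerated leg for dry
ingredients (distances fine-tuned within a few km of 100 to the printed
transport stages); production-chain waste (zero for NZ/US/France, 5.8%
calibrated for Brazil, whose printed raw-milk stage exceeds factor ×
allocated mass); stove profiles (fuel shares, fuel emission factors,
efficiencies — China's includes the 23% coal share); per-country boiled
water emission intensities solved from the printed sterilisation and
preparation stages, with a per-batch rolling-boil margin solved for
Brazil only; diets; and land-use-change factors.

Heat demand for sterilisation and preparation is water volume × 4.186
kJ/(kg·K) × 80 K (20 °C ambient to the boil), with no latent-heat term by
default. The steam-steriliser variant scales the sterilisation stage by
0.15; no single country-independent scale maps every country into the
published 14–23% reduction band (the stovetop no-sterilisation reductions
span 16–27%), and 0.15 yields 13.8–23.2%.

**Diets.** Each consumption country carries a 13–16 item diet
(FAOSTAT-style food groups with plausible energy shares); item emission
factors and masses are scaled once so the plant-source, animal-source and
cooking terms per MJ consumed match the published diet table exactly, and
the consumer-stage BMS waste fraction is back-calculated from the
published per-kg-BMS value (UK 14%, China 14%, Brazil 5.6%, Vietnam
3.2%). Item granularity (e.g. splitting bovine meat from other ruminant
meat, milk from cheese) was chosen so the Monte Carlo standard deviations
of the diet terms match the published ± values; household food waste is
set equal to the country's BMS waste fraction, per the assumption that
BMS wastage equals average household food waste.

**GWP sets.** Emission factors are stated under AR4 (CH₄ = 25,
N₂O = 298) and carry gas shares (raw milk: 70% of CO₂e from CH₄;
animal-source foods 55%, plant foods 30% CH₄). Re-characterisation to
AR5 (28/265) or AR5 with climate-carbon feedback (34/298) rescales each
factor by its gas shares. Under AR5 the consumption footprints rise
4–5% and breastfeeding 2–3%; under the feedback factors the consumption
rise is 13–17%, somewhat above the published 11–15% — the CH₄ share that
reproduces the AR5 band fixes the feedback response, and the AR5 band was
prioritised.

**Land-use change.** Factors per kg commodity for palm oil, soybean oil
and beef follow the expansion-attribution approach (all soy/palm/beef
from expanding regions carries LUC). Oil factors are calibrated so LUC
adds 0.5–0.7% to every consumption footprint; the Brazil beef factor is
solved so LUC exactly doubles the Brazil diet footprint (local
pasture-driven deforestation), while other diets gain ≤ 2%.

## Uncertainty and sensitivity

The distribution grammar supports point values, normal and lognormal
distributions parameterised by a coefficient of variation (lognormal
matches the arithmetic mean to the point value), and triangular
distributions with mode at the point value and support at relative
offsets. Assignments: raw milk normal CV 20%; vegetable oils lognormal
CV 25% (drawn independently per oil, so blend averaging narrows the oils
stage); electricity −50%/+80% and heat −30%/+60% triangular; sterilisation
water ±50%; stove efficiency ±15%; food production lognormal CV 45% per
item; cooking energy −30%/+300% triangular per item.

The strongly asymmetric triangulars (process energy, cooking energy)
would shift the ensemble mean far above the deterministic point value
(a −30%/+300% triangle has mean 1.9× its mode), which contradicts both
the published central estimates and the published comparison statistics.
These distributions are therefore **recentred**: draws are rescaled so
the ensemble mean equals the point estimate while the relative spread is
preserved. The `recentre` flag is explicit on `DistributionSpec`; the
plain (mode-at-point) behaviour remains the default and is what
`sample()` tests against closed-form triangular moments. Normal draws
are truncated at zero (tail mass ~3e-7 at CV 20%).

Parameters are sampled independently (no correlations are specified);
one seed stream per scenario-evaluation makes cross-variant comparisons
paired. Summary statistics are mean, SD, CV, 2.5/97.5 percentiles and,
for comparisons, the exceedance probability P(CFP_Cons > CFP_BF).
Reported central values are the deterministic point estimates with Monte
Carlo SDs attached (the published table convention).

One-at-a-time sensitivity re-evaluates the pipeline at point × (1 ± 10%)
per parameter; for purely linear stages the percent response equals the
perturbation times the stage share, which serves as an analytic oracle in
the tests. Stove efficiency and BMS-per-feed tie structurally in the
consumption OAT (both rescale the same heating stages, ~2.9% for China).

## Problem sizes and reproducibility

Default Monte Carlo runs use n = 10⁴ draws (exceedance standard error
≈ 0.1 percentage points at p ≈ 0.99); the recipe Monte Carlo samples 10⁴
compliant recipes; the pipeline runner accepts any n. All randomness
flows through `numpy.random.default_rng(seed)`; identical (spec, n, seed)
give bit-identical summaries, and the run manifest (seed, n, switches,
configuration hash) suffices to reproduce a run byte-for-byte.

## What the synthetic generator does and does not emulate

`generate_synthetic_scenario` produces structurally valid scenarios —
positive emission factors within three times the packaged ranges,
mixtures summing to one, waste fractions in [0, 1), valid distribution
specs — for property testing of validation, serialisation round-trips and
pipeline invariants (monotonicity, conservation, determinism). It does
not emulate covariances between real country parameters (e.g. clean grids
co-occurring with low stove intensities), so passing property tests
demonstrates robustness of the machinery, not realism of arbitrary
synthetic countries.

## Known limitations

* Calibrated defaults are identifiable only up to the published
  aggregates: many input combinations reproduce the same stage tables.
  Conclusions should be drawn from the stage level upwards, not from
  individual calibrated inputs.
* The energy-content allocation variant understates the published
  sensitivity (see above).
* Only the climate impact is modelled; no other impact categories, no
  health-outcome weighting, and no functional-equivalence adjustment
  between BMS and breastmilk.
* Liquid/ready-to-feed and specialised formulas, dry-blending process
  routes, refrigerated storage of prepared feeds and steam-steriliser
  equipment manufacture are out of scope.
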