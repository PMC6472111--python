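# bmslca

Carbon-footprint model of powdered breastmilk substitutes (BMS, "infant
formula") compared with breastfeeding.

Feeding an infant formula has a climate cost: raw milk production, dairy
processing, packaging, transport, and boiling water at home to prepare and
sterilise bottles. Breastfeeding has one too: a breastfeeding mother needs
roughly 500 kcal of extra food per day. `bmslca` implements a
cradle-to-bottle life-cycle model that quantifies both sides on a common
functional unit — **1 kg of BMS powder at 21.7 kJ/g** — for four production
countries (New Zealand, United States, Brazil, France) and four consumption
countries (United Kingdom, China, Brazil, Vietnam), with Monte Carlo
uncertainty propagation and one-at-a-time sensitivity analysis. It is aimed
at LCA practitioners and researchers in food-system environmental
assessment.

## The model

Three footprints, all in kg CO₂e (GWP₁₀₀) per kg BMS powder:

* **CFP_Prod** — producing and packaging 1 kg BMS to the factory gate:

  CFP_Prod = m_milk·EF_milk·W + m_oil·(Σᵢ sᵢ·EFᵢ + transport) +
  (E_el·EF_el + E_heat·EF_heat) + packaging + transport,

  where *m_milk* is the raw-milk mass **allocated** to the BMS across the
  dairy co-product chain (skimming → cheese-making → whey separation into
  whey protein concentrate and lactose), *W* a chain-waste multiplier
  Π 1/(1−wᵢ), and the allocation basis is dry mass by default
  (fat+protein, energy content and economic value are alternatives). The
  baseline recipe (15% skim-milk solids, 10% whey protein concentrate,
  50% lactose, 25% vegetable oil) draws 13.7 kg raw milk per kg powder,
  of which 6.6 kg is allocated to the BMS under dry-mass allocation.

* **CFP_Cons** — cradle to bottle: CFP_Prod plus retail transport, bottle
  manufacture, and in-home sterilisation (boiling 54 bottles per kg in
  nine 5 L batches) and preparation (54 × 0.13 L of boiled water),
  converted to fuel emissions through each country's stove and fuel mix.

* **CFP_BF** — the breastfeeding equivalent: 385 MJ of extra maternal food
  per 21 kg of powder (≈ 18 MJ/kg), valued at the national average diet
  including household food waste and cooking energy (1.3 MJ heat per kg
  food), and reduced by the fraction of prepared BMS that is wasted.

Uncertainty follows a distribution grammar (normal/lognormal by
coefficient of variation, triangular by relative offsets) propagated by
Monte Carlo with independent parameters; sensitivity is one-at-a-time
±10% perturbation.

## Worked example

```bash
$ bmslca production --country "New Zealand"
        raw_milk: 7.1 kg CO2e/kg BMS
  vegetable_oils: 0.52 kg CO2e/kg BMS
      processing: 0.72 kg CO2e/kg BMS
       packaging: 0.26 kg CO2e/kg BMS
       transport: 0.57 kg CO2e/kg BMS
           total: 9.2 kg CO2e/kg BMS
```

Producing a kilogram of powder in New Zealand emits 9.2 kg CO₂e, 77% of it
from raw milk. Consuming that kilogram in China adds sterilisation,
preparation, transport and bottles:

```bash
$ bmslca compare --country China
CFP_Cons: 14 kg CO2e/kg BMS
CFP_BF:   6.5 kg CO2e/kg BMS
difference (Cons - BF): 7.3
ratio (BF / Cons):      0.47
```

Breastfeeding the equivalent of that kilogram costs 6.5 kg CO₂e — less
than half. The same comparison through the Monte Carlo engine
(`bmslca mc --country China --n 10000`) reports the exceedance
probability P(CFP_Cons > CFP_BF) ≈ 1.00 and per-stage standard
deviations; `bmslca run --out results/` executes all three stages for
every configured country and writes the full result tables, the
difference chart and the BMS-waste sweep as CSV, text and PNG files plus
a reproducibility manifest.

The same API is available from Python:

```python
from bmslca import default_scenarios, cfp_production, cfp_consumption, cfp_breastfeeding

sc = default_scenarios()
prod = cfp_production(sc["France"])                 # StageBreakdown, 8.4 total
cons = cfp_consumption(sc["United Kingdom"], prod)  # 11 total
bf = cfp_breastfeeding(sc["United Kingdom"])        # 6.9 per kg BMS
```

## Scenario configuration

One YAML file per country under `src/bmslca/data/countries/` holds every
country-specific input (emission factors with gas shares and uncertainty
distributions, oil blends, packaging, transport legs, stove profiles,
diets, waste fractions, land-use-change factors), units stated in-field.
Values that were fitted against published aggregate results rather than
taken from a printed table are flagged `calibrated: true`;
`scripts/calibrate_defaults.py` regenerates them from the printed targets.
`bmslca validate` checks any configuration directory against the scenario
invariants.

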