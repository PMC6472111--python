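name: China
role: consumption
raw_milk_ef:
  value: 0.0
  unit: kg ECM raw milk
  gas_shares:
    co2: 1.0
    ch4: 0.0
    n2o: 0.0
milk_density: 1.035
milk_meat_allocation: 0.9
electricity_ef:
  value: 0.0
  unit: MJ electricity
  gas_shares:
    co2: 1.0
    ch4: 0.0
    n2o: 0.0
heat_ef:
  value: 0.0
  unit: MJ heat
  gas_shares:
    co2: 1.0
    ch4: 0.0
    n2o: 0.0
packaging_mix:
  tin_can: 0.7
  bag_in_box: 0.3
packaging_efs:
  steel:
    value: 3.52
    unit: kg packaging material
    gas_shares:
      co2: 1.0
      ch4: 0.0
      n2o: 0.0
  paperboard:
    value: 0.7
    unit: kg packaging material
    gas_shares:
      co2: 1.0
      ch4: 0.0
      n2o: 0.0
  plastic:
    value: 1.72
    unit: kg packaging material
    gas_shares:
      co2: 1.0
      ch4: 0.0
      n2o: 0.0
packaging_masses:
  tin_can:
    steel: 0.1
  bag_in_box:
    paperboard: 0.045
    plastic: 0.008
production_pairing: New Zealand
retail_transport:
- mode: sea
  distance_km: 9500.0
  ef_per_tkm: 0.011
  refrigerated: false
  cargo: bms
- mode: road
  distance_km: 800.0
  ef_per_tkm: 0.1
  refrigerated: false
  cargo: bms
stove_profile:
- fuel: coal
  share: 0.23
  ef_per_mj_fuel: 0.11
  efficiency: 0.25
  gas_shares:
    co2: 0.97
    ch4: 0.03
- fuel: natural gas
  share: 0.34
  ef_per_mj_fuel: 0.065
  efficiency: 0.45
  gas_shares:
    co2: 0.97
    ch4: 0.03
- fuel: electricity
  share: 0.43
  ef_per_mj_fuel: 0.17474806201550386
  efficiency: 0.75
  gas_shares:
    co2: 1.0
diet:
  items:
  - name: rice
    category: plant
    energy_share: 0.3
    ef_per_mj: 0.08969022376560953
    household_waste: 0.14153642967202296
    mass_per_mj: 0.19045746018766269
    gas_shares:
      co2: 0.5
      ch4: 0.3
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: wheat
    category: plant
    energy_share: 0.18
    ef_per_mj: 0.04484511188280477
    household_waste: 0.14153642967202296
    mass_per_mj: 0.2176656687859002
    gas_shares:
      co2: 0.5
      ch4: 0.3
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: vegetable oils
    category: plant
    energy_share: 0.1
    ef_per_mj: 0.056056389853505965
    household_waste: 0.14153642967202296
    mass_per_mj: 0.07346216321524132
    gas_shares:
      co2: 0.5
      ch4: 0.3
      n2o: 0.2
    luc_commodity: soybean_oil
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: vegetables
    category: plant
    energy_share: 0.08
    ef_per_mj: 0.5045075086815537
    household_waste: 0.14153642967202296
    mass_per_mj: 1.9045746018766265
    gas_shares:
      co2: 0.5
      ch4: 0.3
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: sugar
    category: plant
    energy_share: 0.02
    ef_per_mj: 0.11211277970701193
    household_waste: 0.14153642967202296
    mass_per_mj: 0.17005130373898453
    gas_shares:
      co2: 0.5
      ch4: 0.3
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: fruit
    category: plant
    energy_share: 0.04
    ef_per_mj: 0.3923947289745417
    household_waste: 0.14153642967202296
    mass_per_mj: 1.3604104299118762
    gas_shares:
      co2: 0.5
      ch4: 0.3
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: soybeans
    category: plant
    energy_share: 0.04
    ef_per_mj: 0.08969022376560953
    household_waste: 0.14153642967202296
    mass_per_mj: 0.2448738773841377
    gas_shares:
      co2: 0.5
      ch4: 0.3
      n2o: 0.2
    luc_commodity: soy
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: other plant foods
    category: plant
    energy_share: 0.04
    ef_per_mj: 0.06726766782420715
    household_waste: 0.14153642967202296
    mass_per_mj: 0.5441641719647505
    gas_shares:
      co2: 0.5
      ch4: 0.3
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: pork
    category: animal
    energy_share: 0.09
    ef_per_mj: 0.4549194016506365
    household_waste: 0.14153642967202296
    mass_per_mj: 0.2176656687859002
    gas_shares:
      co2: 0.25
      ch4: 0.55
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: dairy
    category: animal
    energy_share: 0.02
    ef_per_mj: 0.5560126020174446
    household_waste: 0.14153642967202296
    mass_per_mj: 0.9522873009383133
    gas_shares:
      co2: 0.25
      ch4: 0.55
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: poultry
    category: animal
    energy_share: 0.03
    ef_per_mj: 0.35382620128382836
    household_waste: 0.14153642967202296
    mass_per_mj: 0.35370671177708785
    gas_shares:
      co2: 0.25
      ch4: 0.55
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: eggs
    category: animal
    energy_share: 0.03
    ef_per_mj: 0.2527330009170203
    household_waste: 0.14153642967202296
    mass_per_mj: 0.40812312897356284
    gas_shares:
      co2: 0.25
      ch4: 0.55
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: fish
    category: animal
    energy_share: 0.02
    ef_per_mj: 0.5054660018340406
    household_waste: 0.14153642967202296
    mass_per_mj: 0.6802052149559381
    gas_shares:
      co2: 0.25
      ch4: 0.55
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: beef
    category: animal
    energy_share: 0.01
    ef_per_mj: 5.054660018340406
    household_waste: 0.14153642967202296
    mass_per_mj: 0.32649850317885026
    gas_shares:
      co2: 0.25
      ch4: 0.55
      n2o: 0.2
    luc_commodity: beef
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
luc_factors:
  beef: 1.0
  soy: 0.2
  soybean_oil: 0.2
  palm_oil: 0.651
bottle_ef: 0.175
bms_waste_fraction: 0.14153642967202296
sterilisation_boil_margin: 0.0
steam_sterilisation_scale: 0.15
calibrated:
  stove_profile: true
  diet: true
  bms_waste_fraction: true
  sterilisation_boil_margin: false
  retail_transport: true
  luc_factors: true
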