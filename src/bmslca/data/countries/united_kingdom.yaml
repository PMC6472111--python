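name: United Kingdom
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
production_pairing: France
retail_transport:
- mode: road
  distance_km: 1400.0
  ef_per_tkm: 0.1
  refrigerated: false
  cargo: bms
stove_profile:
- fuel: natural gas
  share: 0.61
  ef_per_mj_fuel: 0.065
  efficiency: 0.4
  gas_shares:
    co2: 0.97
    ch4: 0.03
- fuel: electricity
  share: 0.39
  ef_per_mj_fuel: 0.12692307692307697
  efficiency: 0.8
  gas_shares:
    co2: 1.0
diet:
  items:
  - name: wheat
    category: plant
    energy_share: 0.24
    ef_per_mj: 0.02996160250450422
    household_waste: 0.13954358398802835
    mass_per_mj: 0.20877043561353575
    gas_shares:
      co2: 0.5
      ch4: 0.3
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: rice
    category: plant
    energy_share: 0.02
    ef_per_mj: 0.07989760667867793
    household_waste: 0.13954358398802835
    mass_per_mj: 0.18267413116184378
    gas_shares:
      co2: 0.5
      ch4: 0.3
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: potatoes
    category: plant
    energy_share: 0.05
    ef_per_mj: 0.04993600417417371
    household_waste: 0.13954358398802835
    mass_per_mj: 0.782889133550759
    gas_shares:
      co2: 0.5
      ch4: 0.3
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: sugar
    category: plant
    energy_share: 0.12
    ef_per_mj: 0.09987200834834742
    household_waste: 0.13954358398802835
    mass_per_mj: 0.1631019028230748
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
    ef_per_mj: 0.04993600417417371
    household_waste: 0.13954358398802835
    mass_per_mj: 0.07046002201956832
    gas_shares:
      co2: 0.5
      ch4: 0.3
      n2o: 0.2
    luc_commodity: palm_oil
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: vegetables
    category: plant
    energy_share: 0.04
    ef_per_mj: 0.44942403756756333
    household_waste: 0.13954358398802835
    mass_per_mj: 1.8267413116184377
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
    ef_per_mj: 0.3994880333933897
    household_waste: 0.13954358398802835
    mass_per_mj: 1.3048152225845984
    gas_shares:
      co2: 0.5
      ch4: 0.3
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: other plant foods
    category: plant
    energy_share: 0.03
    ef_per_mj: 0.05992320500900844
    household_waste: 0.13954358398802835
    mass_per_mj: 0.5219260890338394
    gas_shares:
      co2: 0.5
      ch4: 0.3
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: milk
    category: animal
    energy_share: 0.1
    ef_per_mj: 0.40531287132700944
    household_waste: 0.13954358398802835
    mass_per_mj: 1.1743337003261385
    gas_shares:
      co2: 0.25
      ch4: 0.55
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: cheese and butter
    category: animal
    energy_share: 0.06
    ef_per_mj: 0.40531287132700944
    household_waste: 0.13954358398802835
    mass_per_mj: 0.4697334801304554
    gas_shares:
      co2: 0.25
      ch4: 0.55
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: beef
    category: animal
    energy_share: 0.02
    ef_per_mj: 3.6846624666091765
    household_waste: 0.13954358398802835
    mass_per_mj: 0.3131556534203036
    gas_shares:
      co2: 0.25
      ch4: 0.55
      n2o: 0.2
    luc_commodity: beef
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: lamb and mutton
    category: animal
    energy_share: 0.01
    ef_per_mj: 3.6846624666091765
    household_waste: 0.13954358398802835
    mass_per_mj: 0.3131556534203036
    gas_shares:
      co2: 0.25
      ch4: 0.55
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: pork
    category: animal
    energy_share: 0.05
    ef_per_mj: 0.3316196219948259
    household_waste: 0.13954358398802835
    mass_per_mj: 0.20877043561353575
    gas_shares:
      co2: 0.25
      ch4: 0.55
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: poultry
    category: animal
    energy_share: 0.06
    ef_per_mj: 0.25792637266264234
    household_waste: 0.13954358398802835
    mass_per_mj: 0.3392519578719956
    gas_shares:
      co2: 0.25
      ch4: 0.55
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: eggs
    category: animal
    energy_share: 0.02
    ef_per_mj: 0.18423312333045883
    household_waste: 0.13954358398802835
    mass_per_mj: 0.3914445667753795
    gas_shares:
      co2: 0.25
      ch4: 0.55
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: fish
    category: animal
    energy_share: 0.04
    ef_per_mj: 0.36846624666091765
    household_waste: 0.13954358398802835
    mass_per_mj: 0.6524076112922992
    gas_shares:
      co2: 0.25
      ch4: 0.55
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
luc_factors:
  beef: 0.5
  palm_oil: 0.4
  soybean_oil: 0.2
bottle_ef: 0.175
bms_waste_fraction: 0.13954358398802835
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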