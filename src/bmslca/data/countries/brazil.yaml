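name: Brazil
role: both
raw_milk_ef:
  value: 1.28
  unit: kg ECM raw milk
  gas_shares:
    co2: 0.22
    ch4: 0.7
    n2o: 0.08
  distribution:
    family: normal_cv
    cv: 20.0
milk_density: 1.035
milk_meat_allocation: 0.88
electricity_ef:
  value: 0.017240594626136814
  unit: MJ electricity
  gas_shares:
    co2: 1.0
heat_ef:
  value: 0.0625
  unit: MJ heat
  gas_shares:
    co2: 0.97
    ch4: 0.03
oil_blend:
  palm: 0.51
  soybean: 0.43
  sunflower: 0.06
oil_efs:
  palm:
    value: 2.5000000000000004
    unit: kg product
    gas_shares:
      co2: 0.6
      ch4: 0.02
      n2o: 0.38
    distribution:
      family: lognormal_cv
      cv: 25.0
  soybean:
    value: 1.8000000000000005
    unit: kg product
    gas_shares:
      co2: 0.6
      ch4: 0.02
      n2o: 0.38
    distribution:
      family: lognormal_cv
      cv: 25.0
  sunflower:
    value: 1.3000000000000003
    unit: kg product
    gas_shares:
      co2: 0.6
      ch4: 0.02
      n2o: 0.38
    distribution:
      family: lognormal_cv
      cv: 25.0
oil_transport:
- mode: sea
  distance_km: 3000.0
  ef_per_tkm: 0.011
  refrigerated: false
  cargo: oils
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
transport_legs:
- mode: road_refrigerated
  distance_km: 104.0
  ef_per_tkm: 0.225
  refrigerated: true
  cargo: raw_milk
- mode: road_refrigerated
  distance_km: 104.0
  ef_per_tkm: 0.225
  refrigerated: true
  cargo: whey
- mode: road
  distance_km: 100.0
  ef_per_tkm: 0.1
  refrigerated: false
  cargo: dry_ingredients
chain_waste:
- 0.0576877296073417
production_pairing: Brazil
retail_transport:
- mode: road
  distance_km: 800.0
  ef_per_tkm: 0.1
  refrigerated: false
  cargo: bms
stove_profile:
- fuel: lpg
  share: 0.75
  ef_per_mj_fuel: 0.075
  efficiency: 0.42
  gas_shares:
    co2: 0.97
    ch4: 0.03
- fuel: wood
  share: 0.05
  ef_per_mj_fuel: 0.005
  efficiency: 0.15
  gas_shares:
    ch4: 0.8
    n2o: 0.2
- fuel: electricity
  share: 0.2
  ef_per_mj_fuel: 0.01921904761904758
  efficiency: 0.8
  gas_shares:
    co2: 1.0
diet:
  items:
  - name: rice
    category: plant
    energy_share: 0.1
    ef_per_mj: 0.09068515383377448
    household_waste: 0.0555947936636062
    mass_per_mj: 0.22355711922979785
    gas_shares:
      co2: 0.5
      ch4: 0.3
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: wheat
    category: plant
    energy_share: 0.1
    ef_per_mj: 0.04534257691688724
    household_waste: 0.0555947936636062
    mass_per_mj: 0.2554938505483404
    gas_shares:
      co2: 0.5
      ch4: 0.3
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: sugar
    category: plant
    energy_share: 0.14
    ef_per_mj: 0.11335644229221811
    household_waste: 0.0555947936636062
    mass_per_mj: 0.1996045707408909
    gas_shares:
      co2: 0.5
      ch4: 0.3
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: vegetable oils
    category: plant
    energy_share: 0.09
    ef_per_mj: 0.056678221146109056
    household_waste: 0.0555947936636062
    mass_per_mj: 0.08622917456006488
    gas_shares:
      co2: 0.5
      ch4: 0.3
      n2o: 0.2
    luc_commodity: soybean_oil
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: beans
    category: plant
    energy_share: 0.05
    ef_per_mj: 0.09068515383377448
    household_waste: 0.0555947936636062
    mass_per_mj: 0.2874305818668829
    gas_shares:
      co2: 0.5
      ch4: 0.3
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: vegetables
    category: plant
    energy_share: 0.03
    ef_per_mj: 0.5101039903149815
    household_waste: 0.0555947936636062
    mass_per_mj: 2.235571192297978
    gas_shares:
      co2: 0.5
      ch4: 0.3
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: fruit
    category: plant
    energy_share: 0.05
    ef_per_mj: 0.39674754802276335
    household_waste: 0.0555947936636062
    mass_per_mj: 1.5968365659271273
    gas_shares:
      co2: 0.5
      ch4: 0.3
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: other plant foods
    category: plant
    energy_share: 0.04
    ef_per_mj: 0.06801386537533086
    household_waste: 0.0555947936636062
    mass_per_mj: 0.638734626370851
    gas_shares:
      co2: 0.5
      ch4: 0.3
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: beef
    category: animal
    energy_share: 0.05
    ef_per_mj: 1.5482521715999673
    household_waste: 0.0555947936636062
    mass_per_mj: 0.38324077582251054
    gas_shares:
      co2: 0.25
      ch4: 0.55
      n2o: 0.2
    luc_commodity: beef
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: other ruminant meat
    category: animal
    energy_share: 0.03
    ef_per_mj: 1.5482521715999673
    household_waste: 0.0555947936636062
    mass_per_mj: 0.38324077582251054
    gas_shares:
      co2: 0.25
      ch4: 0.55
      n2o: 0.2
    luc_commodity: beef
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: milk
    category: animal
    energy_share: 0.1
    ef_per_mj: 0.5418882600599885
    household_waste: 0.0555947936636062
    mass_per_mj: 1.4371529093344146
    gas_shares:
      co2: 0.25
      ch4: 0.55
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: cheese and butter
    category: animal
    energy_share: 0.05
    ef_per_mj: 0.5418882600599885
    household_waste: 0.0555947936636062
    mass_per_mj: 0.5748611637337658
    gas_shares:
      co2: 0.25
      ch4: 0.55
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: pork
    category: animal
    energy_share: 0.06
    ef_per_mj: 0.34835673860999267
    household_waste: 0.0555947936636062
    mass_per_mj: 0.2554938505483404
    gas_shares:
      co2: 0.25
      ch4: 0.55
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: poultry
    category: animal
    energy_share: 0.08
    ef_per_mj: 0.27094413002999423
    household_waste: 0.0555947936636062
    mass_per_mj: 0.4151775071410531
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
    ef_per_mj: 0.1935315214499959
    household_waste: 0.0555947936636062
    mass_per_mj: 0.47905096977813816
    gas_shares:
      co2: 0.25
      ch4: 0.55
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: fish
    category: animal
    energy_share: 0.01
    ef_per_mj: 0.3870630428999918
    household_waste: 0.0555947936636062
    mass_per_mj: 0.7984182829635637
    gas_shares:
      co2: 0.25
      ch4: 0.55
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
luc_factors:
  palm_oil: 0.478
  soybean_oil: 0.2
  beef: 14.643140265228428
bottle_ef: 0.175
bms_waste_fraction: 0.0555947936636062
sterilisation_boil_margin: 0.06665729661285269
steam_sterilisation_scale: 0.15
calibrated:
  electricity_ef: true
  oil_efs: true
  packaging_masses: true
  transport_distances: true
  chain_waste: true
  luc_factors: true
  stove_profile: true
  diet: true
  bms_waste_fraction: true
  sterilisation_boil_margin: true
  retail_transport: true
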