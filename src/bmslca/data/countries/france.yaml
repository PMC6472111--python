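name: France
role: production
raw_milk_ef:
  value: 0.99
  unit: kg ECM raw milk
  gas_shares:
    co2: 0.22
    ch4: 0.7
    n2o: 0.08
  distribution:
    family: normal_cv
    cv: 20.0
milk_density: 1.035
milk_meat_allocation: 0.92
electricity_ef:
  value: 0.006895769716220647
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
  palm: 0.25
  soybean: 0.155
  rapeseed: 0.375
  sunflower: 0.22
oil_efs:
  palm:
    value: 2.499286733238231
    unit: kg product
    gas_shares:
      co2: 0.6
      ch4: 0.02
      n2o: 0.38
    distribution:
      family: lognormal_cv
      cv: 25.0
  soybean:
    value: 1.7994864479315265
    unit: kg product
    gas_shares:
      co2: 0.6
      ch4: 0.02
      n2o: 0.38
    distribution:
      family: lognormal_cv
      cv: 25.0
  rapeseed:
    value: 1.4995720399429389
    unit: kg product
    gas_shares:
      co2: 0.6
      ch4: 0.02
      n2o: 0.38
    distribution:
      family: lognormal_cv
      cv: 25.0
  sunflower:
    value: 1.2996291012838803
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
  distance_km: 8000.0
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
  distance_km: 102.0
  ef_per_tkm: 0.225
  refrigerated: true
  cargo: raw_milk
- mode: road_refrigerated
  distance_km: 102.0
  ef_per_tkm: 0.225
  refrigerated: true
  cargo: whey
- mode: road
  distance_km: 100.0
  ef_per_tkm: 0.1
  refrigerated: false
  cargo: dry_ingredients
luc_factors:
  palm_oil: 0.956
  soybean_oil: 0.2
bottle_ef: 0.0
bms_waste_fraction: 0.0
sterilisation_boil_margin: 0.0
steam_sterilisation_scale: 0.15
calibrated:
  electricity_ef: true
  oil_efs: true
  packaging_masses: true
  transport_distances: true
  chain_waste: false
  luc_factors: true
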