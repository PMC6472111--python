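name: New Zealand
role: production
raw_milk_ef:
  value: 1.09
  unit: kg ECM raw milk
  gas_shares:
    co2: 0.22
    ch4: 0.7
    n2o: 0.08
  distribution:
    family: normal_cv
    cv: 20.0
milk_density: 1.035
milk_meat_allocation: 0.91
electricity_ef:
  value: 0.041378519415941166
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
  palm: 0.43
  soybean: 0.25
  rapeseed: 0.2
  sunflower: 0.12
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
  rapeseed:
    value: 1.5000000000000004
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
  distance_km: 9000.0
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
luc_factors:
  palm_oil: 0.651
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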