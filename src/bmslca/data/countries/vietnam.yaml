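name: Vietnam
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
- mode: sea
  distance_km: 15000.0
  ef_per_tkm: 0.011
  refrigerated: false
  cargo: bms
- mode: road
  distance_km: 800.0
  ef_per_tkm: 0.1
  refrigerated: false
  cargo: bms
stove_profile:
- fuel: lpg
  share: 0.45
  ef_per_mj_fuel: 0.075
  efficiency: 0.42
  gas_shares:
    co2: 0.97
    ch4: 0.03
- fuel: wood
  share: 0.25
  ef_per_mj_fuel: 0.005
  efficiency: 0.15
  gas_shares:
    ch4: 0.8
    n2o: 0.2
- fuel: electricity
  share: 0.3
  ef_per_mj_fuel: 0.07577380952380951
  efficiency: 0.75
  gas_shares:
    co2: 1.0
diet:
  items:
  - name: rice
    category: plant
    energy_share: 0.45
    ef_per_mj: 0.10539986329460015
    household_waste: 0.03212576896787411
    mass_per_mj: 0.20490161928161485
    gas_shares:
      co2: 0.5
      ch4: 0.3
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: wheat
    category: plant
    energy_share: 0.04
    ef_per_mj: 0.05269993164730007
    household_waste: 0.03212576896787411
    mass_per_mj: 0.2341732791789884
    gas_shares:
      co2: 0.5
      ch4: 0.3
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: vegetable oils
    category: plant
    energy_share: 0.06
    ef_per_mj: 0.06587491455912509
    household_waste: 0.03212576896787411
    mass_per_mj: 0.07903348172290858
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
    energy_share: 0.07
    ef_per_mj: 0.5928742310321258
    household_waste: 0.03212576896787411
    mass_per_mj: 2.0490161928161483
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
    ef_per_mj: 0.46112440191387555
    household_waste: 0.03212576896787411
    mass_per_mj: 1.4635829948686774
    gas_shares:
      co2: 0.5
      ch4: 0.3
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: sugar
    category: plant
    energy_share: 0.03
    ef_per_mj: 0.13174982911825017
    household_waste: 0.03212576896787411
    mass_per_mj: 0.18294787435858467
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
    ef_per_mj: 0.0790498974709501
    household_waste: 0.03212576896787411
    mass_per_mj: 0.585433197947471
    gas_shares:
      co2: 0.5
      ch4: 0.3
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: pork
    category: animal
    energy_share: 0.12
    ef_per_mj: 0.2761220144750742
    household_waste: 0.03212576896787411
    mass_per_mj: 0.2341732791789884
    gas_shares:
      co2: 0.25
      ch4: 0.55
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: poultry
    category: animal
    energy_share: 0.04
    ef_per_mj: 0.21476156681394656
    household_waste: 0.03212576896787411
    mass_per_mj: 0.38053157866585613
    gas_shares:
      co2: 0.25
      ch4: 0.55
      n2o: 0.2
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
  - name: fish
    category: animal
    energy_share: 0.05
    ef_per_mj: 0.30680223830563796
    household_waste: 0.03212576896787411
    mass_per_mj: 0.7317914974343387
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
    ef_per_mj: 0.15340111915281898
    household_waste: 0.03212576896787411
    mass_per_mj: 0.4390748984606032
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
    ef_per_mj: 0.3374824621362018
    household_waste: 0.03212576896787411
    mass_per_mj: 1.0245080964080742
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
    ef_per_mj: 3.0680223830563795
    household_waste: 0.03212576896787411
    mass_per_mj: 0.35125991876848256
    gas_shares:
      co2: 0.25
      ch4: 0.55
      n2o: 0.2
    luc_commodity: beef
    ef_distribution:
      family: lognormal_cv
      cv: 45.0
luc_factors:
  beef: 0.3
  palm_oil: 0.5
  soybean_oil: 0.2
bottle_ef: 0.175
bms_waste_fraction: 0.03212576896787411
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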