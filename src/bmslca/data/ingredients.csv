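# Dry-ingredient composition table, g per g dry ingredient.
# Energy densities follow from 37 kJ/g fat and 17 kJ/g protein and carbohydrate.
# Values are calibrated so the baseline recipe (15/10/50/25 % of solids)
# reproduces the reference profile: 0.60 g protein, 2.69 g carbohydrate,
# 1.19 g fat, 0.08 g ash per 100 kJ at 21.7 kJ/g, with 65% of protein from whey.
name,protein,fat,carbohydrate,ash,whey_share_of_protein,calibrated
skimmed milk solids,0.3797,0.0100,0.4849,0.0800,0.20,true
whey protein concentrate,0.7324,0.0673,0.1200,0.0436,1.00,true
lactose,0.0000,0.0000,0.9980,0.0020,0.00,true
vegetable oil,0.0000,1.0000,0.0000,0.0000,0.00,false
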