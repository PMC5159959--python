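# The 14 dietary risk factors of the GBD 2013 comparative risk assessment:
# eight food types, five nutrients, and fibre. Direction "harmful_low" means
# the risk is a diet LOW in the item (shortfall below the optimum is harmful);
# "harmful_high" means a diet HIGH in the item (excess above the optimum is
# harmful). Sodium acts through systolic blood pressure and sugar-sweetened
# beverages through body-mass index (two-stage mediated effects).
risks:
  - {name: fruits,                      direction: harmful_low,  unit: g/day,               category: food}
  - {name: vegetables,                  direction: harmful_low,  unit: g/day,               category: food}
  - {name: whole grains,                direction: harmful_low,  unit: g/day,               category: food}
  - {name: nuts and seeds,              direction: harmful_low,  unit: g/day,               category: food}
  - {name: milk,                        direction: harmful_low,  unit: g/day,               category: food}
  - {name: red meat,                    direction: harmful_high, unit: g/day,               category: food}
  - {name: processed meat,              direction: harmful_high, unit: g/day,               category: food}
  - {name: sugar-sweetened beverages,   direction: harmful_high, unit: g/day,               category: food, mediator: bmi}
  - {name: fibre,                       direction: harmful_low,  unit: g/day,               category: fibre}
  - {name: calcium,                     direction: harmful_low,  unit: g/day,               category: nutrient}
  - {name: seafood omega-3 fatty acids, direction: harmful_low,  unit: mg/day,              category: nutrient}
  - {name: polyunsaturated fatty acids, direction: harmful_low,  unit: percent energy/day,  category: nutrient}
  - {name: trans fatty acids,           direction: harmful_high, unit: percent energy/day,  category: nutrient}
  - {name: sodium,                      direction: harmful_high, unit: g/day urinary,       category: nutrient, mediator: sbp}
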