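# HEI-2010 component scoring standards.
# basis: amount per 1000 kcal unless noted; "ratio" = (MUFA+PUFA)/SFA;
# "pct_energy" = percent of total energy.
# Adequacy components score max_points at density >= standard_for_max,
# prorated linearly down to standard_for_min (0 unless stated).
# Moderation components score max_points at density <= standard_for_max and
# 0 at density >= standard_for_min, linear between.
components:
  total_fruit:
    max_points: 5
    direction: adequacy
    basis: per_1000_kcal
    amount: total_fruit_cup
    standard_for_max: 0.8
  whole_fruit:
    max_points: 5
    direction: adequacy
    basis: per_1000_kcal
    amount: whole_fruit_cup
    standard_for_max: 0.4
  total_vegetables:
    max_points: 5
    direction: adequacy
    basis: per_1000_kcal
    amount: total_veg_cup
    standard_for_max: 1.1
  greens_and_beans:
    max_points: 5
    direction: adequacy
    basis: per_1000_kcal
    amount: greens_beans_cup
    standard_for_max: 0.2
  whole_grains:
    max_points: 10
    direction: adequacy
    basis: per_1000_kcal
    amount: whole_grain_oz
    standard_for_max: 1.5
  dairy:
    max_points: 10
    direction: adequacy
    basis: per_1000_kcal
    amount: dairy_cup
    standard_for_max: 1.3
  total_protein_foods:
    max_points: 5
    direction: adequacy
    basis: per_1000_kcal
    amount: protein_foods_oz
    standard_for_max: 2.5
  seafood_plant_proteins:
    max_points: 5
    direction: adequacy
    basis: per_1000_kcal
    amount: seafood_plant_protein_oz
    standard_for_max: 0.8
  fatty_acids:
    max_points: 10
    direction: adequacy
    basis: ratio
    standard_for_max: 2.5
    standard_for_min: 1.2
  refined_grains:
    max_points: 10
    direction: moderation
    basis: per_1000_kcal
    amount: refined_grain_oz
    standard_for_max: 1.8
    standard_for_min: 4.3
  sodium:
    max_points: 10
    direction: moderation
    basis: per_1000_kcal_g
    amount: sodium_mg
    standard_for_max: 1.1
    standard_for_min: 2.0
  empty_calories:
    max_points: 20
    direction: moderation
    basis: pct_energy
    standard_for_max: 19.0
    standard_for_min: 50.0
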