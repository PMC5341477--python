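# Snack food-category density profiles (per 100 kcal) for the synthetic
# recall generator.  SYNTHETIC fixture: share_pct is the published share of
# solid-food snack calories by category (all-solid-snacks model); nutrient
# and food-pattern densities are plausible category-typical values assembled
# from standard food-composition tables, chosen so the synthetic snack
# supply is rich in added sugars, solid fats, refined grains and sodium, as
# observed US snacks are.  whole_grain_fraction is the share of the
# category's grain oz-eq that is whole grain.
category,share_pct,whole_grain_fraction,total_fat_g,sfa_g,mufa_g,pufa_g,ala_mg,protein_g,carbohydrate_g,fiber_g,sodium_mg,potassium_mg,magnesium_mg,added_sugars_tsp,solid_fats_g,oils_g,whole_grain_oz,refined_grain_oz,total_fruit_cup,whole_fruit_cup,total_veg_cup,greens_beans_cup,dairy_cup,protein_foods_oz,seafood_plant_protein_oz
cookies_brownies,11.2,0.035,4.7,1.5,1.8,1.0,30,1.2,14.0,0.4,80,30,5,2.0,4.0,0.5,0.02,0.55,0,0,0,0,0.02,0.02,0
ice_cream_frozen_dairy,9.1,0,5.3,3.3,1.4,0.25,15,1.7,11.5,0.2,40,90,7,2.4,5.2,0.05,0,0,0,0,0,0,0.33,0,0
cakes_pies,7.2,0.02,4.3,1.3,1.8,1.0,40,1.2,14.5,0.35,95,35,5,2.3,3.4,0.8,0.01,0.5,0.02,0,0,0,0,0,0
candy_chocolate,5.9,0,5.8,3.4,1.8,0.3,10,1.4,11.5,0.7,20,75,12,2.4,5.6,0,0,0,0,0,0,0,0.05,0,0
tortilla_corn_chips,4.9,0.4,5.0,0.7,1.5,2.5,100,1.4,13.0,1.0,105,45,15,0,0.3,4.6,0.25,0.35,0,0,0,0,0,0,0
candy_not_chocolate,4.1,0,0.5,0.3,0.1,0.05,0,0.1,24.0,0,10,5,1,5.5,0.4,0,0,0,0,0,0,0,0,0,0
crackers,3.9,0.14,4.0,1.0,1.7,1.1,50,1.7,14.0,0.6,160,35,7,0.3,1.2,2.6,0.1,0.6,0,0,0,0,0,0,0
potato_chips,3.6,0,6.3,0.8,1.7,3.4,150,1.2,9.5,0.8,95,235,12,0,0.2,6.1,0,0,0,0,0.12,0,0,0,0
doughnuts_pastries,3.6,0,5.3,1.7,2.2,1.1,40,1.5,12.5,0.4,95,30,5,1.5,4.5,0.5,0,0.55,0,0,0,0,0,0,0
popcorn,3.5,1.0,3.8,0.7,1.0,1.8,50,2.2,15.0,2.6,130,60,25,0,0.8,2.5,0.65,0,0,0,0,0,0,0,0
cheese,3.3,0,8.3,4.9,2.2,0.3,30,6.2,0.9,0,170,25,7,0,8.1,0,0,0,0,0,0,0,0.25,0,0
yeast_breads,2.6,0.14,1.3,0.3,0.5,0.4,20,3.3,18.5,0.9,180,40,9,0.3,0.3,0.8,0.15,0.9,0,0,0,0,0,0,0
apples,2.0,0,0.3,0.05,0.01,0.1,20,0.5,26.0,4.6,2,205,10,0,0,0,0,0,1.3,1.3,0,0,0,0,0
pretzels_snack_mix,1.9,0.12,2.5,0.5,1.0,0.8,30,2.6,19.0,0.9,330,50,9,0,0.4,1.9,0.1,0.75,0,0,0,0,0,0,0
bananas,1.8,0,0.35,0.1,0.03,0.08,30,1.2,25.5,2.9,1,400,30,0,0,0,0,0,1.0,1.0,0,0,0,0,0
pizza,1.7,0.04,3.9,1.7,1.3,0.7,30,4.3,12.0,0.9,250,70,9,0,2.9,0.8,0.02,0.5,0,0,0.05,0,0.15,0.15,0
rte_cereal_higher_sugar,1.5,0.4,1.0,0.2,0.35,0.35,15,1.8,22.0,1.5,135,60,15,2.3,0.1,0.5,0.3,0.45,0,0,0,0,0,0,0
cereal_bars,1.4,0.45,2.8,0.9,1.2,0.6,30,1.6,17.5,1.3,70,65,15,1.8,0.8,1.5,0.25,0.31,0.03,0,0,0,0,0,0
yogurt_lowfat,1.3,0,1.3,0.85,0.35,0.04,10,5.3,16.0,0,70,235,16,1.2,1.1,0,0,0,0,0,0,0,0.45,0,0
biscuits_muffins,1.3,0.05,4.0,1.1,1.6,1.1,40,1.8,14.0,0.5,180,40,6,1.0,2.1,1.6,0.03,0.55,0,0,0,0,0,0,0
cold_cuts,1.1,0,7.0,2.5,3.2,0.8,40,7.0,1.5,0,500,100,8,0,6.5,0,0,0,0,0,0,0,0,1.3,0
other_fruits,1.1,0,0.3,0.05,0.05,0.1,25,0.8,25.0,2.8,5,250,14,0,0,0,0,0,1.15,1.1,0,0,0,0,0
burritos_tacos,0.9,0.04,4.4,1.9,1.6,0.6,25,4.0,11.5,1.1,230,90,12,0,3.2,0.7,0.02,0.45,0,0,0.06,0,0.1,0.3,0
other,21.0,0.08,3.6,1.2,1.4,0.8,50,2.5,14.0,0.8,150,90,10,1.0,2.0,1.2,0.03,0.35,0.05,0.03,0.05,0.005,0.06,0.2,0.01
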