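# Tree-nut items for the consumption-frequency-weighted composite.
# SYNTHETIC fixture: weighted_frequency values (thousands of survey-weighted
# consumption events) are synthetic, chosen so that normalization over all
# items reproduces the published composite weights for the seven most
# frequently consumed items and an almond share of ~45%.  Nutrient and
# food-pattern values per 100 kcal are transcribed from standard USDA-style
# food-composition tables.  Users may supply their own file via
# composite.load_nut_items(path).
item_id,label,is_almond,weighted_frequency,energy_density_kcal_per_g,total_fat_g,sfa_g,mufa_g,pufa_g,ala_mg,protein_g,carbohydrate_g,fiber_g,sodium_mg,potassium_mg,magnesium_mg,added_sugars_tsp,solid_fats_g,oils_g,whole_grain_oz,refined_grain_oz,total_fruit_cup,whole_fruit_cup,total_veg_cup,greens_beans_cup,dairy_cup,protein_foods_oz,seafood_plant_protein_oz
almonds_nfs,"almonds, not formally specified",True,268,5.75,8.68,0.66,5.50,2.14,0.5,3.69,3.76,2.17,40,127,47,0,0,8.5,0,0,0,0,0,0,0,1.22,1.22
walnuts,"walnuts",False,208,6.51,10.00,0.94,1.37,7.25,1395,2.33,2.10,1.03,0.3,67.7,24.3,0,0,9.8,0,0,0,0,0,0,0,1.09,1.09
pecans,"pecans",False,88,6.91,10.42,0.90,5.90,3.13,143,1.33,2.01,1.39,0.1,59.3,17.5,0,0,10.2,0,0,0,0,0,0,0,1.02,1.02
almonds_dry_roasted,"almonds, dry roasted (salted)",True,86,5.75,8.68,0.66,5.50,2.14,0.5,3.69,3.76,2.17,58,127,47,0,0,8.5,0,0,0,0,0,0,0,1.22,1.22
cashews,"cashews",False,76,5.74,8.08,1.60,4.76,1.36,11,2.67,5.70,0.57,55,98,45,0,0,7.9,0,0,0,0,0,0,0,1.23,1.23
almonds_dry_roasted_unsalted,"almonds, dry roasted without salt",True,71,5.75,8.68,0.66,5.50,2.14,0.5,3.69,3.76,2.17,0.2,127,47,0,0,8.5,0,0,0,0,0,0,0,1.22,1.22
pistachios,"pistachio nuts",False,69,5.62,8.15,1.00,4.23,2.51,46,3.74,4.98,1.83,71,179,19.4,0,0,8.0,0,0,0,0,0,0,0,1.24,1.24
cashews_dry_roasted,"cashews, dry roasted (salted)",False,55,5.74,8.08,1.60,4.76,1.36,11,2.67,5.70,0.57,55,98,45,0,0,7.9,0,0,0,0,0,0,0,1.23,1.23
cashews_dry_roasted_unsalted,"cashews, dry roasted without salt",False,54,5.74,8.08,1.60,4.76,1.36,11,2.67,5.70,0.57,0.3,98,45,0,0,7.9,0,0,0,0,0,0,0,1.23,1.23
almonds_unroasted,"almonds, unroasted",True,13,5.75,8.68,0.66,5.50,2.14,0.5,3.69,3.76,2.17,0.2,127,47,0,0,8.5,0,0,0,0,0,0,0,1.22,1.22
almonds_roasted,"almonds, roasted",True,12,5.75,8.68,0.66,5.50,2.14,0.5,3.69,3.76,2.17,45,127,47,0,0,8.5,0,0,0,0,0,0,0,1.22,1.22
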