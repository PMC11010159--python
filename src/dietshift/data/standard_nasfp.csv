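nutrient,per100g
energy_kcal,55.0
proteins_g,0.4
fibres_g,1.8
vitamin_b1_mg,0.02
vitamin_b2_mg,0.02
vitamin_b6_mg,0.03
vitamin_b9_ug,4.0
vitamin_b12_ug,0.0
vitamin_c_mg,4.0
vitamin_d_ug,0.0
vitamin_e_mg,0.3
vitamin_a_ug,3.0
calcium_mg,5.0
potassium_mg,90.0
iron_mg,0.2
magnesium_mg,5.0
zinc_mg,0.05
copper_mg,0.04
iodine_ug,0.5
selenium_ug,0.2
linoleic_acid_g,0.03
alpha_linolenic_acid_g,0.01
dha_g,0.0
sfa_g,0.0
free_sugars_g,0.0
added_sugars_g,0.0
sodium_mg,2.0
carbohydrates_g,13.0
total_fat_g,0.2
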