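nutrient,age_group,direction,basis,value,low,high,unit
proteins_g,1-3,floor,absolute_per_day,10,,,g/d
proteins_g,4-6,floor,absolute_per_day,15,,,g/d
proteins_g,7-10,floor,absolute_per_day,21,,,g/d
proteins_g,11-14,floor,absolute_per_day,34,,,g/d
proteins_g,15-17,floor,absolute_per_day,46,,,g/d
fibres_g,1-3,floor,absolute_per_day,10,,,g/d
fibres_g,4-6,floor,absolute_per_day,14,,,g/d
fibres_g,7-10,floor,absolute_per_day,16,,,g/d
fibres_g,11-14,floor,absolute_per_day,19,,,g/d
fibres_g,15-17,floor,absolute_per_day,22,,,g/d
vitamin_b1_mg,1-3,floor,absolute_per_day,0.3,,,mg/d
vitamin_b1_mg,4-6,floor,absolute_per_day,0.5,,,mg/d
vitamin_b1_mg,7-10,floor,absolute_per_day,0.7,,,mg/d
vitamin_b1_mg,11-14,floor,absolute_per_day,1.0,,,mg/d
vitamin_b1_mg,15-17,floor,absolute_per_day,1.2,,,mg/d
vitamin_b2_mg,1-3,floor,absolute_per_day,0.5,,,mg/d
vitamin_b2_mg,4-6,floor,absolute_per_day,0.7,,,mg/d
vitamin_b2_mg,7-10,floor,absolute_per_day,0.9,,,mg/d
vitamin_b2_mg,11-14,floor,absolute_per_day,1.3,,,mg/d
vitamin_b2_mg,15-17,floor,absolute_per_day,1.5,,,mg/d
vitamin_b6_mg,1-3,floor,absolute_per_day,0.5,,,mg/d
vitamin_b6_mg,4-6,floor,absolute_per_day,0.6,,,mg/d
vitamin_b6_mg,7-10,floor,absolute_per_day,0.9,,,mg/d
vitamin_b6_mg,11-14,floor,absolute_per_day,1.2,,,mg/d
vitamin_b6_mg,15-17,floor,absolute_per_day,1.5,,,mg/d
vitamin_b9_ug,1-3,floor,absolute_per_day,100,,,ug/d
vitamin_b9_ug,4-6,floor,absolute_per_day,140,,,ug/d
vitamin_b9_ug,7-10,floor,absolute_per_day,200,,,ug/d
vitamin_b9_ug,11-14,floor,absolute_per_day,270,,,ug/d
vitamin_b9_ug,15-17,floor,absolute_per_day,330,,,ug/d
vitamin_b12_ug,1-3,floor,absolute_per_day,1.5,,,ug/d
vitamin_b12_ug,4-6,floor,absolute_per_day,1.5,,,ug/d
vitamin_b12_ug,7-10,floor,absolute_per_day,2.0,,,ug/d
vitamin_b12_ug,11-14,floor,absolute_per_day,3.0,,,ug/d
vitamin_b12_ug,15-17,floor,absolute_per_day,4.0,,,ug/d
vitamin_c_mg,1-3,floor,absolute_per_day,20,,,mg/d
vitamin_c_mg,4-6,floor,absolute_per_day,30,,,mg/d
vitamin_c_mg,7-10,floor,absolute_per_day,45,,,mg/d
vitamin_c_mg,11-14,floor,absolute_per_day,70,,,mg/d
vitamin_c_mg,15-17,floor,absolute_per_day,100,,,mg/d
vitamin_d_ug,1-3,floor,absolute_per_day,15,,,ug/d
vitamin_d_ug,4-6,floor,absolute_per_day,15,,,ug/d
vitamin_d_ug,7-10,floor,absolute_per_day,15,,,ug/d
vitamin_d_ug,11-14,floor,absolute_per_day,15,,,ug/d
vitamin_d_ug,15-17,floor,absolute_per_day,15,,,ug/d
vitamin_e_mg,1-3,floor,absolute_per_day,5,,,mg/d
vitamin_e_mg,4-6,floor,absolute_per_day,6,,,mg/d
vitamin_e_mg,7-10,floor,absolute_per_day,8,,,mg/d
vitamin_e_mg,11-14,floor,absolute_per_day,10,,,mg/d
vitamin_e_mg,15-17,floor,absolute_per_day,12,,,mg/d
vitamin_a_ug,1-3,floor,absolute_per_day,250,,,ug/d
vitamin_a_ug,4-6,floor,absolute_per_day,300,,,ug/d
vitamin_a_ug,7-10,floor,absolute_per_day,400,,,ug/d
vitamin_a_ug,11-14,floor,absolute_per_day,600,,,ug/d
vitamin_a_ug,15-17,floor,absolute_per_day,750,,,ug/d
calcium_mg,1-3,floor,absolute_per_day,450,,,mg/d
calcium_mg,4-6,floor,absolute_per_day,800,,,mg/d
calcium_mg,7-10,floor,absolute_per_day,800,,,mg/d
calcium_mg,11-14,floor,absolute_per_day,1150,,,mg/d
calcium_mg,15-17,floor,absolute_per_day,1150,,,mg/d
potassium_mg,1-3,floor,absolute_per_day,800,,,mg/d
potassium_mg,4-6,floor,absolute_per_day,1100,,,mg/d
potassium_mg,7-10,floor,absolute_per_day,1800,,,mg/d
potassium_mg,11-14,floor,absolute_per_day,2300,,,mg/d
potassium_mg,15-17,floor,absolute_per_day,3100,,,mg/d
iron_mg,1-3,floor,absolute_per_day,5,,,mg/d
iron_mg,4-6,floor,absolute_per_day,4,,,mg/d
iron_mg,7-10,floor,absolute_per_day,6,,,mg/d
iron_mg,11-14,floor,absolute_per_day,11,,,mg/d
iron_mg,15-17,floor,absolute_per_day,13,,,mg/d
magnesium_mg,1-3,floor,absolute_per_day,80,,,mg/d
magnesium_mg,4-6,floor,absolute_per_day,120,,,mg/d
magnesium_mg,7-10,floor,absolute_per_day,200,,,mg/d
magnesium_mg,11-14,floor,absolute_per_day,280,,,mg/d
magnesium_mg,15-17,floor,absolute_per_day,340,,,mg/d
zinc_mg,1-3,floor,absolute_per_day,4,,,mg/d
zinc_mg,4-6,floor,absolute_per_day,5,,,mg/d
zinc_mg,7-10,floor,absolute_per_day,7,,,mg/d
zinc_mg,11-14,floor,absolute_per_day,10,,,mg/d
zinc_mg,15-17,floor,absolute_per_day,11,,,mg/d
copper_mg,1-3,floor,absolute_per_day,0.3,,,mg/d
copper_mg,4-6,floor,absolute_per_day,0.6,,,mg/d
copper_mg,7-10,floor,absolute_per_day,0.7,,,mg/d
copper_mg,11-14,floor,absolute_per_day,1.1,,,mg/d
copper_mg,15-17,floor,absolute_per_day,1.3,,,mg/d
iodine_ug,1-3,floor,absolute_per_day,90,,,ug/d
iodine_ug,4-6,floor,absolute_per_day,90,,,ug/d
iodine_ug,7-10,floor,absolute_per_day,120,,,ug/d
iodine_ug,11-14,floor,absolute_per_day,150,,,ug/d
iodine_ug,15-17,floor,absolute_per_day,150,,,ug/d
selenium_ug,1-3,floor,absolute_per_day,20,,,ug/d
selenium_ug,4-6,floor,absolute_per_day,30,,,ug/d
selenium_ug,7-10,floor,absolute_per_day,45,,,ug/d
selenium_ug,11-14,floor,absolute_per_day,55,,,ug/d
selenium_ug,15-17,floor,absolute_per_day,70,,,ug/d
linoleic_acid_g,1-3,floor,absolute_per_day,2.7,,,g/d
linoleic_acid_g,4-6,floor,absolute_per_day,4.4,,,g/d
linoleic_acid_g,7-10,floor,absolute_per_day,5.5,,,g/d
linoleic_acid_g,11-14,floor,absolute_per_day,6.7,,,g/d
linoleic_acid_g,15-17,floor,absolute_per_day,8.0,,,g/d
alpha_linolenic_acid_g,1-3,floor,absolute_per_day,0.7,,,g/d
alpha_linolenic_acid_g,4-6,floor,absolute_per_day,1.1,,,g/d
alpha_linolenic_acid_g,7-10,floor,absolute_per_day,1.4,,,g/d
alpha_linolenic_acid_g,11-14,floor,absolute_per_day,1.7,,,g/d
alpha_linolenic_acid_g,15-17,floor,absolute_per_day,2.0,,,g/d
dha_g,1-3,floor,absolute_per_day,0.1,,,g/d
dha_g,4-6,floor,absolute_per_day,0.125,,,g/d
dha_g,7-10,floor,absolute_per_day,0.125,,,g/d
dha_g,11-14,floor,absolute_per_day,0.25,,,g/d
dha_g,15-17,floor,absolute_per_day,0.25,,,g/d
sfa_g,1-3,ceiling,percent_of_energy,12,,,%E
free_sugars_g,1-3,ceiling,percent_of_energy,10,,,%E
carbohydrates_g,1-3,range,percent_of_energy,,40,55,%E
sfa_g,4-6,ceiling,percent_of_energy,12,,,%E
free_sugars_g,4-6,ceiling,percent_of_energy,10,,,%E
carbohydrates_g,4-6,range,percent_of_energy,,40,55,%E
sfa_g,7-10,ceiling,percent_of_energy,12,,,%E
free_sugars_g,7-10,ceiling,percent_of_energy,10,,,%E
carbohydrates_g,7-10,range,percent_of_energy,,40,55,%E
sfa_g,11-14,ceiling,percent_of_energy,12,,,%E
free_sugars_g,11-14,ceiling,percent_of_energy,10,,,%E
carbohydrates_g,11-14,range,percent_of_energy,,40,55,%E
sfa_g,15-17,ceiling,percent_of_energy,12,,,%E
free_sugars_g,15-17,ceiling,percent_of_energy,10,,,%E
carbohydrates_g,15-17,range,percent_of_energy,,40,55,%E
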