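nutrient,age_lo,age_hi,sex,ear,ul,amdr_lo,amdr_hi,eer,rni,conversion_factor,ear_basis
energy_kcal,5,5,M,,,,,1360,,,
energy_kcal,6,6,M,,,,,1467,,,
energy_kcal,7,7,M,,,,,1573,,,
energy_kcal,8,8,M,,,,,1692,,,
energy_kcal,9,9,M,,,,,1830,,,
energy_kcal,5,5,F,,,,,1241,,,
energy_kcal,6,6,F,,,,,1330,,,
energy_kcal,7,7,F,,,,,1428,,,
energy_kcal,8,8,F,,,,,1554,,,
energy_kcal,9,9,F,,,,,1698,,,
protein_g,5,8,any,0.76,,10,30,,,,per_kg
protein_g,9,9,any,0.76,,10,30,,,,per_kg
carbohydrate_g,5,8,any,100,,45,65,,,,absolute
carbohydrate_g,9,9,any,100,,45,65,,,,absolute
fat_g,5,8,any,,,25,35,,,,
fat_g,9,9,any,,,25,35,,,,
calcium_mg,5,8,any,800,2500,,,,,,absolute
calcium_mg,9,9,any,1100,3000,,,,,,absolute
phosphorus_mg,5,8,any,405,3000,,,,,,absolute
phosphorus_mg,9,9,any,1055,4000,,,,,,absolute
iron_mg,5,6,any,,40,,,,12.6,,
iron_mg,7,9,any,,40,,,,17.8,,
zinc_mg,5,6,any,8.0,12,,,,9.6,1.2,absolute
zinc_mg,7,9,any,9.3,23,,,,11.2,1.2,absolute
vitamin_a_ug_rae,5,8,any,275,900,,,,,,absolute
vitamin_a_ug_rae,9,9,F,420,1700,,,,,,absolute
vitamin_a_ug_rae,9,9,M,445,1700,,,,,,absolute
vitamin_d_ug,5,8,any,10,75,,,,,,absolute
vitamin_d_ug,9,9,any,10,100,,,,,,absolute
vitamin_c_mg,5,8,any,22,650,,,,,,absolute
vitamin_c_mg,9,9,any,39,1200,,,,,,absolute
thiamin_mg,5,8,any,0.5,,,,,,,absolute
thiamin_mg,9,9,any,0.7,,,,,,,absolute
riboflavin_mg,5,8,any,0.5,,,,,,,absolute
riboflavin_mg,9,9,any,0.8,,,,,,,absolute
niacin_mg,5,8,any,6,15,,,,,,absolute
niacin_mg,9,9,any,9,20,,,,,,absolute
vitamin_b6_mg,5,8,any,0.5,40,,,,,,absolute
vitamin_b6_mg,9,9,any,0.8,60,,,,,,absolute
folate_ug_dfe,5,8,any,160,400,,,,,,absolute
folate_ug_dfe,9,9,any,250,600,,,,,,absolute
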